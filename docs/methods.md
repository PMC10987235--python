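# Methods

`telovar` implements a hierarchical covariance analysis of four traits
measured on wild ungulates caught once per year: relative leucocyte telomere
length (RLTL, a qPCR T/S ratio), strongyle faecal egg count (FEC, eggs per
gram), helminth-specific IgG antibody level (IgG-Tc, a blank-corrected
optical-density ratio) and binary overwinter survival.  This note records
the model, the estimation machinery, the synthetic-data generator's
assumptions and the numerical choices, in enough detail to reproduce or
criticise them.

## The model

For record *i* (individual `ind(i)`, year `yr(i)`) and trait *k* the latent
value is

    l_ik = x_ik' beta_k + u_{ind(i),k} + v_{yr(i),k} + a_ik + e_ik

with

* `u_j ~ N(0, Sigma_ind)` and `v_t ~ N(0, Sigma_yr)`: unstructured K x K
  covariance matrices shared across traits at the among-individual and
  among-year levels;
* `a_ik`: scalar assay-batch intercepts — qPCR plate and qPCR
  row-within-plate for RLTL, ELISA plate for IgG-Tc — each with its own
  variance;
* `e_i ~ N(0, Sigma_res)`: the unstructured residual ("within-individual")
  covariance.

Observation families:

* Gaussian traits (RLTL, IgG-Tc) are observed directly: `y_ik = l_ik`.
* FEC is an overdispersed count with a log link: `y ~ Poisson(exp(l))`.
  Because `l` carries the Gaussian residual, the marginal distribution is
  Poisson-lognormal — the residual level *is* the overdispersion channel,
  which is what lets residual covariances involving FEC live on a Gaussian
  latent scale.  A fixed extra negative-binomial dispersion
  (`count_dispersion = theta`) is available when conditional noise beyond
  Poisson is wanted; the default is none.
* Survival is binary on a latent liability.  Default link is logit
  (`P(y=1) = inv-logit(l)`, the Gaussian residual acting as extra-logistic
  heterogeneity); the probit alternative uses the threshold convention
  `y = 1 iff l > 0`, in which the residual *is* the liability noise.  In
  both cases the survival residual variance is fixed at 1 — it is not
  identified from binary data — and all survival covariances are reported
  on the latent scale.

Fixed effects are drawn from a small vocabulary (intercept, age, age²,
sex, age-class, FEC, IgG-Tc, and the sex interactions), validated for
marginality.  Defaults per trait: age for RLTL; age + age² + sex for FEC;
age + sex for IgG-Tc; when survival is modelled, every trait additionally
carries the two-level age-class factor and survival gets
intercept + age-class + age (the survival sub-model's exact fixed-effect
menu is configurable).

## Estimation

Estimation is block Gibbs MCMC, written from scratch in `telovar._gibbs`:

* **Fixed effects**: one joint conjugate Gaussian draw across all traits
  (the residual precision couples traits within a record), prior
  `N(0, 10^8)` per coefficient.
* **Random effects**: parameter expansion at every level.  Effects are
  `u_jk = alpha_k * utilde_jk` with working effects
  `utilde ~ N(0, Psi_L)` and redundant multipliers
  `alpha_L ~ N(0, 1000 I)`; `Psi_L ~ IW(I, dim_L)`.  Both `utilde` (batched
  per-group conjugate Gaussian) and `alpha` (a conjugate Gaussian
  "regression" on the working effects) have closed-form updates, and the
  reported level covariance is `diag(alpha) Psi diag(alpha)`.  Expansion
  markedly improves mixing for variance components near zero.
* **Residual covariance**: conjugate inverse-Wishart, default prior
  `IW(I_K, K + 1)` (a proper, weak choice; configurable).  When a binary
  trait fixes a diagonal entry, the update draws from the *conditional*
  inverse-Wishart with that block held fixed, using the Bartlett block
  decomposition of the Wishart precision: `W_11.2 = Sigma_11^{-1}` is
  independent of `(W_12, W_22)`, so it is replaced by the required value
  while the other blocks are drawn unconditionally.  The scheme was
  validated against accept-reject conditioning of unconstrained
  inverse-Wishart draws (`tests/test_constrained_wishart.py`).
* **Latent values**: count-trait latent residuals are updated by a
  vectorised random-walk Metropolis step whose scale adapts toward 44%
  acceptance during warmup only (so the stored chain is a fixed-kernel
  Markov chain); probit binary latents are drawn exactly from their
  truncated-normal full conditional; logit binary latents use the
  Metropolis step.  When an individual-level random effect is present,
  the probit liabilities are drawn with that level's trait component
  *integrated out* (the within-individual joint is
  `v_c I + V 11'`, whose record-wise conditionals follow by
  Sherman–Morrison; records of one individual are swept in rounds) and the
  effect is then redrawn from its exact conditional — jointly a single
  blocked draw of (liabilities, effects).  Without this collapse the
  two-block liability/effect alternation mixes far too slowly for the
  weakly-identified binary among-individual variance.  An additional exact
  "interweaving" move translates each group effect of a non-Gaussian trait
  against its records' latent residuals (likelihood-invariant, conjugate
  Gaussian), further decorrelating effects from latents.
* **Initialisation**: trait-wise OLS on observed / crudely-initialised
  latent values for the fixed effects; `0.1 x identity` covariances;
  `log(y + 0.5)` count latents; `±0.5` binary latents.
* **Seeding**: one integer seed drives a single `numpy` Generator for the
  whole chain; reruns are bit-identical on one platform.

Chain defaults mirror the full-scale analysis (495,000 iterations, 95,000
warmup, thinning 400, 1,000 stored draws); every experiment in the test
suite and the acceptance script scales these down (20,000–52,000
iterations, thinning 15–40, always 1,000 stored draws), sizes chosen as the
smallest at which the recovery experiments stabilise.

Point estimates are posterior modes of a Gaussian KDE (Silverman bandwidth,
2,048-point grid over the draw range); intervals are 95% highest posterior
density (shortest contiguous window over sorted draws); a quantity is
called significant when its HPD excludes zero strictly.  The KDE-argmax
mode is itself a noisy statistic (sampling SD ≈ 0.08 for 10⁴ independent
standard-normal draws), which sets a floor on how tightly any recovery
experiment can be judged.  Lag-1 autocorrelation of each stored chain is
reported, with 0.1 as the conventional acceptability bound.

## Derived quantities

All derived quantities are computed per stored draw and then summarised,
so posterior uncertainty propagates exactly:

* level-specific correlations `cov_ij / sqrt(var_i var_j)`;
* repeatability of a trait: among-individual variance over
  (among-individual + among-year + residual).  Assay-batch variances are
  excluded from the denominator by default — they are measurement noise,
  not phenotype — with inclusion available as a switch;
* partial regression coefficients of survival on the other traits at each
  level: `beta = Sigma_pp^{-1} sigma_ps` from that level's matrix,
  i.e. each trait's association with survival after accounting for
  covariance among the traits at that level.  Singular draws are skipped
  and counted, never regularised silently.

## The synthetic-data generator

`telovar.synth` simulates the longitudinal study itself: individuals enter
as lambs (age 0) in annual cohorts, survive winters according to their
latent survival trait (so trait–survival covariances arise only through
the configured covariance matrices), and are captured each August with a
fixed probability; captured records receive assay-batch effects, MCAR
per-trait missingness, and McMaster-granular FEC (a count draw times 100).
Default parameters emulate the study population the package models:
19 cohort years, ~2,700 individuals born, ~50% capture, survival around
0.7–0.9 giving roughly 1,300–1,450 observed individuals with ~1.9–2.1
complete-case samples each and ~45% of individuals sampled more than once;
variance shares place the repeatabilities of RLTL / FEC / IgG-Tc at
0.254 / 0.375 / 0.595 of their non-assay totals, with a residual RLTL–FEC
correlation of 0.190, an among-individual RLTL–survival latent correlation
of 0.318, a residual FEC–survival latent correlation of −0.461, an
among-year FEC–survival latent correlation of −0.732 and a residual
IgG-survival latent correlation of 0.181; all other cross-trait
covariances are zero.  RLTL is generated on the T/S scale (mean ≈ 1.05,
SD ≈ 0.15) and IgG-Tc on the OD-ratio scale (mean ≈ 0.5), so the raw-assay
simulators can invert the qPCR and ELISA formulas; variance *shares* and
correlations are invariant to the z-scoring applied before model fitting.

What the generator does **not** emulate: age- or sex-biased trapping,
maternal and genetic effects, density dependence, spatial structure,
non-MCAR missingness, and any direct feedback of traits on capture.
Passing recovery tests therefore demonstrate that the estimator recovers
the generating structure under the stated design — not that real data are
free of those complications.

### Recovery presets and survivor selection

`telovar.presets` fixes three ready-made designs used by the tests and the
acceptance script: an adult repeat-measures trivariate design (~570
individuals with records at ages ≥ 3, ~1,350 observations), a reduced
whole-population quadrivariate design (~650 individuals, ~1,500
observations spanning lambs and adults), and a lamb cohort design (831
age-0 records with a direct RLTL-on-FEC slope of 3.36 × 10⁻⁵ per egg/g).
Missingness is zero in the presets: they emulate the complete-case
analysis subsets directly.

One design decision deserves emphasis.  With partial capture, an
individual observed at a later age has silently survived unobserved
interim winters; the complete-case likelihood has no term for those years,
and the records observed at each age come from a population truncated
toward high survival liability.  Stepwise isolation experiments showed
this survivor selection collapses the among-individual survival variance
posterior toward zero while leaving residual-level quantities nearly
unaffected.  The quadrivariate recovery preset therefore observes every
alive-year (capture probability 1, with the span shortened to 8 cohort
years to hold the observation count at the reduced scale), which makes the
fitted likelihood exactly match the generative process — record sequences
end at an observed death, a valid stopping time.  The preset also uses the
probit link on both the generation and fitting sides, pairing with the
sampler's exact threshold augmentation.  The default whole-population
configuration keeps partial capture, so the selection phenomenon remains
available for study; it is a real feature of capture-based field designs,
not an artefact of this package.

## Known limitations

* The among-individual survival covariance is weakly identified at the
  reduced scale (≈650 individuals averaging ~2.3 binary records): its
  posterior is wide, and although the collapsed sampler explores it well,
  the recovered mode still varies across simulated datasets.  FEC
  repeatability is similarly the noisiest repeatability to recover — its
  among-year share is the largest, and the realized variance of 19 annual
  draws fluctuates between datasets.
* Logit binary latents rely on random-walk Metropolis and mix much more
  slowly than the probit augmentation; for serious binary-trait work use
  the probit link.
* One chain per fit; convergence checking is limited to the lag-1
  autocorrelation criterion (multiple-chain diagnostics are out of scope).
* The count family's extra negative-binomial dispersion is fixed, not
  estimated.
* Complete-case analysis throughout; no imputation.
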