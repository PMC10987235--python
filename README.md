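# telovar

Hierarchical covariance analysis of leucocyte telomere length, helminth
infection burden, anti-helminth antibody levels and overwinter survival in
longitudinal wild-population data.

## The problem

In long-term individual-based field studies (the motivating system is a
free-living sheep population sampled every August for two decades), each
capture yields a relative leucocyte telomere length (**RLTL**, a qPCR T/S
ratio), a strongyle faecal egg count (**FEC**, eggs per gram by the McMaster
method), a *Teladorsagia circumcincta*-specific IgG level (**IgG-Tc**, a
blank-corrected ELISA optical-density ratio), and whether the animal
survived the following winter.  The scientific questions — does infection
or immune investment cost telomere length? does telomere length mediate the
infection–survival association? — hinge on *where* trait covariance lives:
among individuals, among years, or within individuals between years.

`telovar` provides the full pipeline for this analysis:

* **`telovar.assays`** — raw assay processing: the qPCR T/S formula
  `E_TEL^(Cq_cal - Cq_sample) / E_B2M^(Cq_cal - Cq_sample)` with the 5%
  triplicate-COV exclusion, ELISA OD ratios
  `(OD - blank) / (positive - blank)` with duplicate-COV (0.2) and
  plate-pair correlation (0.8) gates, McMaster FEC (count × 100), and the
  model-scale transform (z-scored RLTL / IgG-Tc / age, FEC back to counts).
* **`telovar.mcmc`** — Bayesian mixed models written from scratch:
  univariate Gaussian LMMs with crossed random intercepts, and multivariate
  GLMMs of 2–4 traits (Gaussian, overdispersed count with log link, binary
  with logit/probit link) with unstructured covariance matrices
  **Σ_individual**, **Σ_year**, **Σ_residual**, assay-batch effects, and
  parameter-expanded priors, estimated by block Gibbs MCMC.  Point
  estimates are posterior KDE modes with 95% highest-posterior-density
  intervals.
* **`telovar.decomp`** — derived posteriors computed draw-wise:
  level-specific correlations `cov/(sd·sd)`, trait repeatabilities
  `V_ind / (V_ind + V_year + V_residual)`, and partial regressions of
  survival on the other traits at each level,
  `β = Σ_pp⁻¹ σ_ps`.
* **`telovar.synth`** — a generative simulator of the longitudinal study
  (cohort entry, latent-scale trait construction, survival-driven
  disappearance, capture, assay batches, missingness) with known ground
  truth, plus raw qPCR/ELISA plate generators that invert the assay
  formulas exactly.
* **`telovar` CLI / `telovar.pipeline`** — staged runs
  (simulate → qc → prepare → fit → derive → report) with full config and
  row-count capture.

The samplers are sklearn-style estimators (`UnivariateLMM`,
`MultiTraitGLMM`) with `fit`, `get_params`/`set_params` and fitted
`draws_` / `summary_` attributes.

## Worked example

```python
from telovar import MultiTraitGLMM, prepare_model_traits, records_to_frame
from telovar.decomp import correlation_from_cov, repeatability_from_draws
from telovar.presets import trivariate_recovery_config
from telovar.summaries import posterior_mode, hpd_interval
from telovar.synth import simulate_population

cfg = trivariate_recovery_config(seed=3)          # adult repeat-measures design
records, truth = simulate_population(cfg)
df = records_to_frame(records)
adults, scalers = prepare_model_traits(df[df["age"] >= 3])

model = MultiTraitGLMM(traits=("rltl", "fec", "igg_tc"),
                       n_iter=24_000, warmup=6_000, thin=18, seed=12)
model.fit(adults)
print(model.n_obs_, model.n_individuals_)

r = correlation_from_cov(model.draws_.covariances["residual"], 0, 1)
print("within-individual RLTL-FEC corr:",
      round(posterior_mode(r), 3), [round(x, 3) for x in hpd_interval(r)])
for trait in ("rltl", "fec", "igg_tc"):
    print(trait, "repeatability:",
          round(posterior_mode(repeatability_from_draws(model.draws_, trait)), 3))
```

Output from this exact script:

```
1561 577
within-individual RLTL-FEC corr: 0.146 [0.068, 0.221]
rltl repeatability: 0.269
fec repeatability: 0.326
igg_tc repeatability: 0.607
```

The dataset was generated with a within-individual RLTL–FEC correlation of
0.190 and repeatabilities of 0.254 / 0.375 / 0.595, so the fitted modes
recover the generating structure to within posterior uncertainty: a small
positive within-year association between telomere length and parasite
burden, and moderate-to-high consistent among-individual differences in
all three traits.

From the shell, the same staged analysis is:

```bash
telovar fit --dataset adults_ge3 --model adult-trivariate \
        --seed 3 --outdir runs/tri
telovar report --rundir runs/tri
```

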