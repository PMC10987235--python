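"""Bayesian univariate LMMs and multivariate GLMMs over capture records.

Two sklearn-style estimators wrap the block Gibbs engine in
:mod:`telovar._gibbs`:

* :class:`UnivariateLMM` — a Gaussian response with crossed random
  intercepts (year, qPCR plate, qPCR row-within-plate, optionally individual
  for adult repeat-measures models) and configurable fixed effects, used for
  the lamb and sex-interaction models.
* :class:`MultiTraitGLMM` — two to four traits (Gaussian RLTL and IgG-Tc,
  log-link overdispersed-count FEC, logit/probit binary survival) with
  unstructured covariance matrices at the individual, year and residual
  levels, scalar assay-batch effects, and parameter-expanded priors on all
  variance components.

Fitted chains are returned as :class:`PosteriorDraws` (labelled draws for
every fixed effect, covariance element and assay variance) and summarised by
posterior mode + 95% HPD interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._gibbs import GibbsPriors, LevelDef, TraitDef, run_gibbs
from .summaries import summarize_draws

DEFAULT_FAMILIES = {"rltl": "gaussian", "igg_tc": "gaussian",
                    "fec": "count", "survival": "binary"}
ASSAY_LEVELS = {"qpcr_plate": "rltl", "qpcr_row": "rltl", "elisa_plate": "igg_tc"}

_INTERACTION_PARENTS = {"sex:fec": ("sex", "fec"), "sex:igg_tc": ("sex", "igg_tc"),
                        "age2": ("age",)}
_TERM_COLUMNS = {"age": "age", "age2": "age", "sex": "sex", "age_class": "age_class",
                 "fec": "fec", "igg_tc": "igg_tc",
                 "sex:fec": ("sex", "fec"), "sex:igg_tc": ("sex", "igg_tc")}


def _term_column(term: str, df: pd.DataFrame) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(df))
    if term == "age":
        return df["age"].to_numpy(dtype=float)
    if term == "age2":
        return df["age"].to_numpy(dtype=float) ** 2
    if term == "sex":
        return (df["sex"].to_numpy() == "M").astype(float)
    if term == "age_class":
        return (df["age_class"].to_numpy() == "adult").astype(float)
    if term in ("fec", "igg_tc"):
        return df[term].to_numpy(dtype=float)
    if term in ("sex:fec", "sex:igg_tc"):
        return _term_column("sex", df) * _term_column(term.split(":")[1], df)
    raise ValueError(f"unknown fixed-effect term {term!r}")


def check_marginality(terms) -> None:
    """Interactions (and the quadratic age term) require their main effects."""
    terms = tuple(terms)
    for t in terms:
        for parent in _INTERACTION_PARENTS.get(t, ()):
            if parent not in terms:
                raise ValueError(f"term {t!r} requires main effect {parent!r} "
                                 "(principle of marginality)")


def build_design(df: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    check_marginality(terms)
    cols = [_term_column(t, df) for t in terms]
    return np.column_stack(cols), list(terms)


@dataclass
class PriorSpec:
    """Parameter-expanded variance priors + inverse-Wishart residual prior."""

    px_variance: float = 1.0
    px_mean: float = 0.0
    px_alpha_variance: float = 1000.0
    residual_scale: np.ndarray | None = None
    residual_df: float | None = None
    beta_variance: float = 1e8

    def to_gibbs(self) -> GibbsPriors:
        return GibbsPriors(beta_variance=self.beta_variance,
                           px_psi_scale=self.px_variance,
                           px_alpha_mean=self.px_mean,
                           px_alpha_variance=self.px_alpha_variance,
                           residual_scale=self.residual_scale,
                           residual_df=self.residual_df)


@dataclass
class ModelSpec:
    """Declarative model description (traits, families, terms, chain, priors)."""

    traits: tuple[str, ...]
    families: dict[str, str] = field(default_factory=dict)
    fixed_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    random_levels: tuple[str, ...] = ("individual", "year")
    assay_effects: dict[str, str] = field(default_factory=dict)
    iterations: int = 495_000
    warmup: int = 95_000
    thin: int = 400
    seed: int = 0
    priors: PriorSpec = field(default_factory=PriorSpec)
    binary_link: str = "logit"
    count_dispersion: float | None = None

    def __post_init__(self):
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("traits may be listed at most once")
        if not self.families:
            self.families = {t: DEFAULT_FAMILIES.get(t, "gaussian") for t in self.traits}
        if not self.fixed_terms:
            self.fixed_terms = default_fixed_terms(self.traits)
        if not self.assay_effects:
            self.assay_effects = {lvl: tr for lvl, tr in ASSAY_LEVELS.items()
                                  if tr in self.traits}
        for t in self.traits:
            check_marginality(self.fixed_terms[t])


def default_fixed_terms(traits) -> dict[str, tuple[str, ...]]:
    """Fixed-effect menus: age for RLTL, age + age^2 + sex for FEC, age + sex
    for IgG-Tc; when survival is modelled (whole-population data spanning
    lambs and adults) every trait additionally carries the age-class factor."""
    base = {"rltl": ("intercept", "age"),
            "fec": ("intercept", "age", "age2", "sex"),
            "igg_tc": ("intercept", "age", "sex"),
            "survival": ("intercept", "age_class", "age")}
    out = {t: base[t] for t in traits}
    if "survival" in traits:
        for t in traits:
            if "age_class" not in out[t]:
                out[t] = ("intercept", "age_class") + out[t][1:]
    return out


@dataclass
class PosteriorDraws:
    """Labelled stored MCMC draws for one fitted model."""

    traits: tuple[str, ...]
    beta: pd.DataFrame                       # columns "trait:term"
    covariances: dict[str, np.ndarray]       # level -> (S, kL, kL), incl "residual"
    level_traits: dict[str, tuple[str, ...]]
    meta: dict = field(default_factory=dict)

    @property
    def n_store(self) -> int:
        return len(self.beta)

    def _idx(self, level: str, trait: str) -> int:
        return self.level_traits[level].index(trait)

    def variance(self, level: str, trait: str) -> np.ndarray:
        i = self._idx(level, trait)
        return self.covariances[level][:, i, i]

    def covariance(self, level: str, t1: str, t2: str) -> np.ndarray:
        return self.covariances[level][:, self._idx(level, t1), self._idx(level, t2)]

    def to_frame(self) -> pd.DataFrame:
        """All scalar chains as one columnar DataFrame."""
        cols = {f"beta:{c}": self.beta[c].to_numpy() for c in self.beta.columns}
        for level, mats in self.covariances.items():
            names = self.level_traits[level]
            for i, ti in enumerate(names):
                cols[f"{level}:var({ti})"] = mats[:, i, i]
                for j in range(i + 1, len(names)):
                    cols[f"{level}:cov({ti},{names[j]})"] = mats[:, i, j]
        return pd.DataFrame(cols)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        return summarize_draws(self.to_frame(), mass=mass)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "draws.csv", index=False)
        meta = dict(self.meta)
        meta["traits"] = list(self.traits)
        meta["level_traits"] = {k: list(v) for k, v in self.level_traits.items()}
        with open(outdir / "draws_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def load_draws(rundir) -> PosteriorDraws:
    """Reload a :class:`PosteriorDraws` bundle saved with :meth:`PosteriorDraws.save`."""
    rundir = Path(rundir)
    df = pd.read_csv(rundir / "draws.csv")
    with open(rundir / "draws_meta.json") as fh:
        meta = json.load(fh)
    traits = tuple(meta.pop("traits"))
    level_traits = {k: tuple(v) for k, v in meta.pop("level_traits").items()}
    beta = df[[c for c in df.columns if c.startswith("beta:")]].rename(
        columns=lambda c: c[len("beta:"):])
    covs = {}
    n = len(df)
    for level, names in level_traits.items():
        k = len(names)
        mats = np.empty((n, k, k))
        for i, ti in enumerate(names):
            mats[:, i, i] = df[f"{level}:var({ti})"]
            for j in range(i + 1, k):
                mats[:, i, j] = mats[:, j, i] = df[f"{level}:cov({ti},{names[j]})"]
        covs[level] = mats
    return PosteriorDraws(traits=traits, beta=beta, covariances=covs,
                          level_traits=level_traits, meta=meta)


def _codes(values: np.ndarray) -> tuple[np.ndarray, int]:
    uniq = np.unique(values)
    return np.searchsorted(uniq, values), len(uniq)


def _complete_cases(records: pd.DataFrame, columns) -> pd.DataFrame:
    df = records
    mask = np.ones(len(df), dtype=bool)
    for c in columns:
        col = df[c]
        if col.dtype.kind in "fc":
            mask &= np.isfinite(col.to_numpy(dtype=float))
        else:
            mask &= col.notna().to_numpy()
    return df[mask]


class MultiTraitGLMM(BaseEstimator):
    """Multivariate GLMM with unstructured level covariances, fit by Gibbs MCMC.

    Parameters mirror :class:`ModelSpec`; records are expected on the model
    scale (see :func:`telovar.assays.prepare_model_traits`: RLTL, IgG-Tc and
    age z-scored, FEC in slide-count units).  ``fit`` selects complete cases
    for the requested traits and covariates, runs the chain and exposes

    - ``draws_`` : :class:`PosteriorDraws`
    - ``summary_`` : mode / 95% HPD / significance / lag-1 autocorrelation
    - ``n_obs_``, ``n_individuals_``, ``accept_``
    """

    def __init__(self, traits=("rltl", "fec", "igg_tc"), families=None,
                 fixed_terms=None, random_levels=("individual", "year"),
                 assay_effects=None, n_iter=495_000, warmup=95_000, thin=400,
                 seed=0, priors=None, binary_link="logit", count_dispersion=None,
                 px=True):
        self.traits = traits
        self.families = families
        self.fixed_terms = fixed_terms
        self.random_levels = random_levels
        self.assay_effects = assay_effects
        self.n_iter = n_iter
        self.warmup = warmup
        self.thin = thin
        self.seed = seed
        self.priors = priors
        self.binary_link = binary_link
        self.count_dispersion = count_dispersion
        self.px = px

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "MultiTraitGLMM":
        return cls(traits=spec.traits, families=spec.families,
                   fixed_terms=spec.fixed_terms, random_levels=spec.random_levels,
                   assay_effects=spec.assay_effects, n_iter=spec.iterations,
                   warmup=spec.warmup, thin=spec.thin, seed=spec.seed,
                   priors=spec.priors, binary_link=spec.binary_link,
                   count_dispersion=spec.count_dispersion)

    def _resolved(self):
        traits = tuple(self.traits)
        families = self.families or {t: DEFAULT_FAMILIES.get(t, "gaussian") for t in traits}
        fixed_terms = self.fixed_terms or default_fixed_terms(traits)
        assay = self.assay_effects
        if assay is None:
            assay = {lvl: tr for lvl, tr in ASSAY_LEVELS.items() if tr in traits}
        priors = self.priors or PriorSpec()
        return traits, families, fixed_terms, assay, priors

    def fit(self, records: pd.DataFrame, y=None):
        traits, families, fixed_terms, assay, priors = self._resolved()
        needed_cols = set()
        for t in traits:
            needed_cols.add(t)
            for term in fixed_terms[t]:
                col = _TERM_COLUMNS.get(term)
                if isinstance(col, tuple):
                    needed_cols.update(col)
                elif col:
                    needed_cols.add(col)
        level_cols = {"individual": "individual_id", "year": "year"}
        for lvl in self.random_levels:
            needed_cols.add(level_cols[lvl])
        for lvl in assay:
            needed_cols.add(lvl)
        df = _complete_cases(records, sorted(needed_cols)).reset_index(drop=True)
        if df.empty:
            raise ValueError("no complete-case records for the requested model")

        trait_defs, X_list, beta_names = [], [], []
        for t in traits:
            fam = families[t]
            trait_defs.append(TraitDef(
                name=t, family=fam,
                link=self.binary_link if fam == "binary" else "",
                dispersion=self.count_dispersion if fam == "count" else None))
            X, names = build_design(df, fixed_terms[t])
            X_list.append(X)
            beta_names.extend(f"{t}:{n}" for n in names)
        y_mat = np.column_stack([
            np.round(df[t].to_numpy(dtype=float)) if families[t] in ("count", "binary")
            else df[t].to_numpy(dtype=float) for t in traits])

        levels = []
        all_idx = np.arange(len(traits))
        for lvl in self.random_levels:
            codes, n_groups = _codes(df[level_cols[lvl]].to_numpy())
            levels.append(LevelDef(lvl, codes, n_groups, all_idx, px=self.px))
        for lvl, tr in assay.items():
            codes, n_groups = _codes(df[lvl].to_numpy())
            levels.append(LevelDef(lvl, codes, n_groups,
                                   np.array([traits.index(tr)]), px=self.px))

        res = run_gibbs(y_mat, X_list, trait_defs, levels, priors.to_gibbs(),
                        self.n_iter, self.warmup, self.thin, self.seed,
                        collapse_level="individual"
                        if "individual" in self.random_levels else None)

        level_traits = {lvl: traits for lvl in self.random_levels}
        level_traits.update({lvl: (tr,) for lvl, tr in assay.items()})
        level_traits["residual"] = traits
        covs = dict(res["levels"])
        covs["residual"] = res["residual"]
        self.draws_ = PosteriorDraws(
            traits=traits,
            beta=pd.DataFrame(res["beta"], columns=beta_names),
            covariances=covs, level_traits=level_traits,
            meta={"n_obs": len(df), "iterations": self.n_iter, "warmup": self.warmup,
                  "thin": self.thin, "seed": self.seed, "families": dict(families),
                  "accept": res["accept"]})
        self.summary_ = self.draws_.summary()
        self.n_obs_ = len(df)
        self.n_individuals_ = int(df["individual_id"].nunique()) \
            if "individual_id" in df.columns else None
        self.accept_ = res["accept"]
        return self


class UnivariateLMM(BaseEstimator):
    """Gaussian LMM with crossed random intercepts, fit by Gibbs MCMC.

    ``fix_variances`` (level name or ``"residual"`` -> value) holds variance
    components fixed, which reduces every update to its conjugate Gaussian
    step — used to validate the sampler against the closed-form GLS solution.
    """

    def __init__(self, response="rltl",
                 fixed_terms=("intercept", "fec", "sex"),
                 random_levels=("year", "qpcr_plate", "qpcr_row"),
                 n_iter=50_000, warmup=10_000, thin=40, seed=0, priors=None,
                 px=True, fix_variances=None):
        self.response = response
        self.fixed_terms = fixed_terms
        self.random_levels = random_levels
        self.n_iter = n_iter
        self.warmup = warmup
        self.thin = thin
        self.seed = seed
        self.priors = priors
        self.px = px
        self.fix_variances = fix_variances

    def fit(self, records: pd.DataFrame, y=None):
        priors = self.priors or PriorSpec()
        level_cols = {"individual": "individual_id", "year": "year",
                      "qpcr_plate": "qpcr_plate", "qpcr_row": "qpcr_row",
                      "elisa_plate": "elisa_plate"}
        needed = {self.response}
        for term in self.fixed_terms:
            col = _TERM_COLUMNS.get(term)
            if isinstance(col, tuple):
                needed.update(col)
            elif col:
                needed.add(col)
        needed.update(level_cols[lvl] for lvl in self.random_levels)
        df = _complete_cases(records, sorted(needed)).reset_index(drop=True)
        if df.empty:
            raise ValueError("no complete-case records for the requested model")

        X, names = build_design(df, self.fixed_terms)
        y_mat = df[self.response].to_numpy(dtype=float)[:, None]
        levels = []
        for lvl in self.random_levels:
            codes, n_groups = _codes(df[level_cols[lvl]].to_numpy())
            levels.append(LevelDef(lvl, codes, n_groups, np.array([0]), px=self.px))
        fix = None
        if self.fix_variances:
            fix = {k: np.atleast_2d(np.asarray(v, dtype=float))
                   for k, v in self.fix_variances.items()}
        res = run_gibbs(y_mat, [X], [TraitDef(self.response, "gaussian")], levels,
                        priors.to_gibbs(), self.n_iter, self.warmup, self.thin,
                        self.seed, fix_variances=fix)
        level_traits = {lvl: (self.response,) for lvl in self.random_levels}
        level_traits["residual"] = (self.response,)
        covs = dict(res["levels"])
        covs["residual"] = res["residual"]
        self.draws_ = PosteriorDraws(
            traits=(self.response,),
            beta=pd.DataFrame(res["beta"], columns=[f"{self.response}:{n}" for n in names]),
            covariances=covs, level_traits=level_traits,
            meta={"n_obs": len(df), "iterations": self.n_iter, "warmup": self.warmup,
                  "thin": self.thin, "seed": self.seed})
        self.summary_ = self.draws_.summary()
        self.n_obs_ = len(df)
        return self


def fit_univariate_lmm(records: pd.DataFrame, spec: ModelSpec,
                       response: str | None = None, **kwargs) -> PosteriorDraws:
    """Fit a univariate Gaussian LMM described by ``spec`` and return its draws."""
    resp = response or spec.traits[0]
    if spec.families.get(resp, "gaussian") != "gaussian":
        raise ValueError("univariate LMM requires a Gaussian response")
    levels = tuple(spec.random_levels) + tuple(
        lvl for lvl, tr in spec.assay_effects.items() if tr == resp)
    est = UnivariateLMM(response=resp, fixed_terms=spec.fixed_terms[resp],
                        random_levels=levels, n_iter=spec.iterations,
                        warmup=spec.warmup, thin=spec.thin, seed=spec.seed,
                        priors=spec.priors, **kwargs)
    est.fit(records)
    return est.draws_


def fit_multivariate_glmm(records: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Fit the multivariate GLMM described by ``spec`` and return its draws."""
    est = MultiTraitGLMM.from_spec(spec)
    est.fit(records)
    return est.draws_
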