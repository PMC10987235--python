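"""Derived quantities from posterior covariance draws.

Level-specific trait correlations, per-trait repeatabilities and partial
regression coefficients of survival on the other traits are computed *per
stored draw* and then summarised (posterior mode + 95% HPD), so posterior
uncertainty propagates into every derived quantity.

The partial regression of survival on the predictors at a hierarchical level
uses only that level's covariance matrix: beta = Sigma_pp^-1 sigma_ps, i.e.
the effect of each predictor on survival after accounting for the covariance
among the predictors at that level.

Repeatability of a trait is its among-individual variance divided by the sum
of among-individual, among-year and residual variances; assay-batch
variances are treated as measurement noise and excluded from the denominator
by default (inclusion is a switch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws
from .summaries import hpd_interval, posterior_mode

logger = logging.getLogger(__name__)


def correlation_from_cov(matrices: np.ndarray, i: int, j: int) -> np.ndarray:
    """Per-draw correlation cov_ij / (sd_i * sd_j) from (S, K, K) draws."""
    m = np.asarray(matrices, dtype=float)
    vi, vj = m[:, i, i], m[:, j, j]
    if np.any(vi <= 0) or np.any(vj <= 0):
        raise ValueError("correlation undefined: zero variance in a draw")
    return m[:, i, j] / np.sqrt(vi * vj)


def repeatability(v_individual: np.ndarray, v_year: np.ndarray,
                  v_residual: np.ndarray, v_assay: np.ndarray | None = None,
                  include_assay: bool = False) -> np.ndarray:
    """Per-draw among-individual variance share of a trait."""
    arrs = [np.asarray(a, dtype=float) for a in (v_individual, v_year, v_residual)]
    if any(np.any(a < 0) for a in arrs):
        raise ValueError("variance draws must be non-negative")
    denom = arrs[0] + arrs[1] + arrs[2]
    if include_assay and v_assay is not None:
        v_assay = np.asarray(v_assay, dtype=float)
        if np.any(v_assay < 0):
            raise ValueError("variance draws must be non-negative")
        denom = denom + v_assay
    return arrs[0] / denom


def repeatability_from_draws(draws: PosteriorDraws, trait: str,
                             include_assay: bool = False) -> np.ndarray:
    """Repeatability chain for one trait of a fitted multi-level model."""
    v_assay = None
    if include_assay:
        v_assay = np.zeros(draws.n_store)
        for level, traits in draws.level_traits.items():
            if level in ("individual", "year", "residual"):
                continue
            if trait in traits:
                v_assay = v_assay + draws.variance(level, trait)
    return repeatability(draws.variance("individual", trait),
                         draws.variance("year", trait),
                         draws.variance("residual", trait),
                         v_assay=v_assay, include_assay=include_assay)


def partial_regression_on_survival(matrices: np.ndarray, predictor_idx,
                                   survival_idx: int) -> tuple[np.ndarray, int]:
    """Per-draw partial coefficients beta = Sigma_pp^-1 sigma_ps.

    Singular predictor sub-matrices are skipped (and counted), never
    regularised silently.  Returns (draws x predictors array, n_skipped).
    """
    m = np.asarray(matrices, dtype=float)
    p_idx = np.asarray(predictor_idx, dtype=int)
    betas, n_skipped = [], 0
    for s in range(m.shape[0]):
        spp = m[s][np.ix_(p_idx, p_idx)]
        sps = m[s][p_idx, survival_idx]
        try:
            betas.append(np.linalg.solve(spp, sps))
        except np.linalg.LinAlgError:
            n_skipped += 1
    if n_skipped:
        logger.warning("partial regression: skipped %d singular draws", n_skipped)
    return np.asarray(betas), n_skipped


@dataclass
class DerivedQuantity:
    quantity: str
    level: str
    chain: np.ndarray

    def summary_row(self, mass: float = 0.95) -> dict:
        lo, hi = hpd_interval(self.chain, mass)
        return {"quantity": self.quantity, "level": self.level,
                "mode": posterior_mode(self.chain), "hpd_lo": lo, "hpd_hi": hi,
                "significant": bool(lo > 0 or hi < 0)}


def significance_flags(summary: pd.DataFrame, lo_col: str = "hpd_lo",
                       hi_col: str = "hpd_hi") -> pd.DataFrame:
    """Flag rows whose 95% HPD interval strictly excludes 0."""
    out = summary.copy()
    out["significant"] = (out[lo_col] > 0) | (out[hi_col] < 0)
    return out


def derive_all(draws: PosteriorDraws, survival_trait: str = "survival",
               include_assay: bool = False, mass: float = 0.95) -> pd.DataFrame:
    """Tidy table of every derived quantity for a fitted multivariate model:
    pairwise correlations per level, per-trait repeatabilities and (when
    survival is modelled) partial regressions of survival on the other
    traits at each level."""
    quantities: list[DerivedQuantity] = []
    traits = draws.traits
    for level in ("individual", "year", "residual"):
        if level not in draws.covariances:
            continue
        mats = draws.covariances[level]
        names = draws.level_traits[level]
        for i, ti in enumerate(names):
            for j in range(i + 1, len(names)):
                quantities.append(DerivedQuantity(
                    f"corr({ti},{names[j]})", level,
                    correlation_from_cov(mats, i, j)))
    if {"individual", "year", "residual"} <= set(draws.covariances):
        for t in traits:
            if t == survival_trait:
                continue
            quantities.append(DerivedQuantity(
                f"repeatability({t})", "individual",
                repeatability_from_draws(draws, t, include_assay=include_assay)))
    if survival_trait in traits:
        predictors = [t for t in traits if t != survival_trait]
        for level in ("individual", "year", "residual"):
            if level not in draws.covariances:
                continue
            names = draws.level_traits[level]
            p_idx = [names.index(t) for t in predictors]
            betas, _ = partial_regression_on_survival(
                draws.covariances[level], p_idx, names.index(survival_trait))
            for col, t in enumerate(predictors):
                quantities.append(DerivedQuantity(
                    f"beta_survival({t})", level, betas[:, col]))
    return pd.DataFrame([q.summary_row(mass) for q in quantities])
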