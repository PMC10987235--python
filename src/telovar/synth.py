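"""Synthetic longitudinal wild-population datasets with known ground truth.

This module generates individual-by-year capture records that mimic the
statistical structure of a long-term study of a free-living sheep population:
four traits per capture — relative leucocyte telomere length (RLTL, a
dimensionless qPCR T/S ratio), strongyle faecal egg count (FEC, eggs per gram,
McMaster-granular multiples of 100), helminth-specific IgG antibody level
(IgG-Tc, a blank-corrected optical-density ratio) and binary overwinter
survival — with correlated random effects at the among-individual, among-year
and residual (within-individual) levels, plus scalar assay-batch effects
(qPCR plate, qPCR row-within-plate, ELISA plate).

All four traits are built additively on a latent Gaussian scale:

    l_itk = x_itk' beta_k + u_ik + v_tk + e_itk

with u_i ~ N(0, Sigma_individual), v_t ~ N(0, Sigma_year) and
e_it ~ N(0, Sigma_residual) (4x4 unstructured covariance matrices).  Gaussian
traits are observed as their latent value plus assay-batch effects; FEC is an
overdispersed count with a log link (exp(latent) is the conditional mean of a
Poisson or negative-binomial draw, times 100 for eggs-per-gram units); survival
is Bernoulli through a logit (default) or probit link with its latent residual
variance fixed at 1 for identifiability.  Individuals enter as lambs (age 0)
and persist by annual survival draws, so trait-survival covariances are
induced purely through the configured covariance matrices.

Raw assay plates (qPCR triplicate Cq tables and ELISA duplicate OD tables)
can additionally be generated by inverting the assay formulas, so that the
`assays` module recovers each record's trait value exactly when no replicate
noise is injected.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TRAITS = ("rltl", "fec", "igg_tc", "survival")
FIXED_TERMS = ("intercept", "age", "age2", "sex_m", "adult")

RECORD_COLUMNS = [
    "individual_id", "year", "age", "sex", "age_class",
    "rltl", "fec", "igg_tc", "survival",
    "qpcr_plate", "qpcr_row", "elisa_plate",
]


def _default_fixed_effects() -> dict[str, dict[str, float]]:
    """Per-trait latent-scale fixed effects (intercept, age, age^2, sex, age-class).

    RLTL is on the T/S-ratio scale (population mean ~1, declining slightly with
    age); FEC on the log count scale (counts are eggs-per-gram / 100, high in
    lambs and declining with age); IgG-Tc on the OD-ratio scale (rising into
    adulthood, declining slowly with age thereafter); survival on the logit
    scale (lambs survive their first winter less often than prime-age adults,
    with actuarial senescence).
    """
    return {
        "rltl": {"intercept": 1.05, "age": -0.008},
        "fec": {"intercept": 1.95, "age": -0.25, "age2": 0.012, "sex_m": 0.2},
        "igg_tc": {"intercept": 0.38, "adult": 0.22, "age": -0.010, "sex_m": -0.04},
        "survival": {"intercept": 0.3, "adult": 2.4, "age": -0.05},
    }


def variance_components(total: float, ind_share: float, year_share: float) -> tuple[float, float, float]:
    """Split a total latent variance into (individual, year, residual) parts.

    ``ind_share`` is the among-individual fraction of the non-assay variance
    (the trait's repeatability under the default denominator), ``year_share``
    the among-year fraction; the remainder is residual.
    """
    if not 0 <= ind_share + year_share <= 1:
        raise ValueError("variance shares must sum to at most 1")
    return total * ind_share, total * year_share, total * (1 - ind_share - year_share)


def _default_sigmas() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Default 4x4 level covariance matrices over (rltl, fec, igg_tc, survival).

    Diagonals place the among-individual variance shares of RLTL, FEC and
    IgG-Tc at 0.254, 0.375 and 0.595 of their non-assay totals.  Off-diagonals
    encode the level-specific trait correlations the generator emulates by
    default: residual RLTL-FEC 0.190, among-individual RLTL-survival 0.318,
    residual FEC-survival -0.461, among-year FEC-survival -0.732 and residual
    IgG-survival 0.181; every other cross-trait covariance is zero.
    """
    # totals: rltl on T/S scale (sd 0.15), fec on log-count scale,
    # igg on OD-ratio scale (sd 0.15), survival latent (residual fixed at 1)
    v_r = variance_components(0.0225, 0.254, 0.05)
    v_f = variance_components(1.2, 0.375, 0.125)
    v_g = variance_components(0.0225, 0.595, 0.05)
    v_s = (0.5, 0.3, 1.0)

    ind = np.diag([v_r[0], v_f[0], v_g[0], v_s[0]])
    yr = np.diag([v_r[1], v_f[1], v_g[1], v_s[1]])
    res = np.diag([v_r[2], v_f[2], v_g[2], v_s[2]])

    ind[0, 3] = ind[3, 0] = 0.318 * math.sqrt(v_r[0] * v_s[0])
    yr[1, 3] = yr[3, 1] = -0.732 * math.sqrt(v_f[1] * v_s[1])
    res[0, 1] = res[1, 0] = 0.190 * math.sqrt(v_r[2] * v_f[2])
    res[1, 3] = res[3, 1] = -0.461 * math.sqrt(v_f[2] * v_s[2])
    res[2, 3] = res[3, 2] = 0.181 * math.sqrt(v_g[2] * v_s[2])
    return ind, yr, res


def _default_assay_sds() -> dict[str, float]:
    return {"qpcr_plate": 0.04, "qpcr_row": 0.03, "elisa_plate": 0.03}


def _default_missingness() -> dict[str, float]:
    return {"rltl": 0.12, "fec": 0.18, "igg_tc": 0.22, "survival": 0.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic longitudinal study.

    Parameters
    ----------
    n_individuals
        Number of individuals born into the study (across all cohorts).  Only
        individuals captured at least once appear in the output records.
    n_years
        Number of annual cohorts / study years.
    capture_prob
        Probability an alive individual is caught (and assayed) in a given
        August; treated as a single Bernoulli parameter with no age or sex
        selectivity.
    max_age
        Oldest age simulated; individuals reaching it leave the study.
    sex_ratio
        Probability an individual is female.
    fixed_effects
        Per-trait mapping of term name (``intercept``, ``age``, ``age2``,
        ``sex_m``, ``adult``) to latent-scale coefficient.
    sigma_individual, sigma_year, sigma_residual
        Symmetric positive semi-definite 4x4 covariance matrices over the
        traits ``(rltl, fec, igg_tc, survival)`` at each hierarchical level.
    assay_sds
        Standard deviations of the scalar qPCR-plate, qPCR-row and ELISA-plate
        batch effects (added to RLTL and IgG-Tc respectively).
    fec_dispersion
        Negative-binomial size parameter for the count draw given the latent
        mean; ``inf`` (default) gives a Poisson draw, so all overdispersion
        beyond Poisson comes from the latent lognormal structure.
    survival_link
        ``"logit"`` (default) or ``"probit"``.
    rltl_fec_slope
        Optional direct dependence of RLTL on realized FEC (per raw egg/g),
        added to the RLTL latent value after the count draw.  Zero by default.
    missingness
        Per-trait independent (MCAR) missing probability per record.
    qpcr_triplicate_sd, elisa_duplicate_sd
        Replicate noise injected when raw assay plates are generated.
    seed
        Seed for all randomness; identical configs reproduce byte-identical
        outputs.
    """

    n_individuals: int = 2700
    n_years: int = 19
    start_year: int = 1998
    capture_prob: float = 0.5
    max_age: int = 12
    sex_ratio: float = 0.5
    fixed_effects: Mapping[str, Mapping[str, float]] = field(default_factory=_default_fixed_effects)
    sigma_individual: np.ndarray = field(default_factory=lambda: _default_sigmas()[0])
    sigma_year: np.ndarray = field(default_factory=lambda: _default_sigmas()[1])
    sigma_residual: np.ndarray = field(default_factory=lambda: _default_sigmas()[2])
    assay_sds: Mapping[str, float] = field(default_factory=_default_assay_sds)
    fec_dispersion: float = math.inf
    survival_link: str = "logit"
    rltl_fec_slope: float = 0.0
    missingness: Mapping[str, float] = field(default_factory=_default_missingness)
    qpcr_plate_size: int = 24
    elisa_plate_size: int = 40
    qpcr_loading_sd: float = 0.3
    qpcr_triplicate_sd: float = 0.0
    elisa_duplicate_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_years <= 0 or self.max_age <= 0:
            raise ValueError("counts must be positive")
        for name, p in (("capture_prob", self.capture_prob), ("sex_ratio", self.sex_ratio)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for p in self.missingness.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must be in [0, 1]")
        if self.survival_link not in ("logit", "probit"):
            raise ValueError("survival_link must be 'logit' or 'probit'")
        if not (self.fec_dispersion > 0):
            raise ValueError("fec_dispersion must be positive (inf for Poisson)")
        for name in ("sigma_individual", "sigma_year", "sigma_residual"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4 over traits {TRAITS}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-9:
                raise ValueError(f"{name} must be positive semi-definite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("sigma_individual", "sigma_year", "sigma_residual"):
            d[name] = np.asarray(d[name]).tolist()
        d["fec_dispersion"] = None if math.isinf(self.fec_dispersion) else self.fec_dispersion
        return d


@dataclass
class CaptureRecord:
    """One individual-by-year capture with traits, covariates and batch labels."""

    individual_id: str
    year: int
    age: int
    sex: str                # "F" | "M"
    age_class: str          # "lamb" iff age == 0 else "adult"
    rltl: float             # T/S ratio; NaN if missing
    fec: float              # eggs per gram (multiple of 100); NaN if missing
    igg_tc: float           # OD ratio; NaN if missing
    survival: float         # 0/1 overwinter; NaN if missing
    qpcr_plate: str
    qpcr_row: str
    elisa_plate: str


@dataclass
class SimulationTruth:
    """Realized configuration plus every drawn latent effect."""

    config: SimulationConfig
    individual_effects: pd.DataFrame   # index individual_id, columns u_<trait>
    year_effects: pd.DataFrame         # index year, columns v_<trait>
    batch_effects: dict[str, dict[str, float]]
    residuals: pd.DataFrame            # per captured record, columns e_<trait>
    n_records: int

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "individual_effects": self.individual_effects.reset_index().to_dict(orient="list"),
            "year_effects": self.year_effects.reset_index().to_dict(orient="list"),
            "batch_effects": self.batch_effects,
            "n_records": self.n_records,
        }
        return json.dumps(payload, indent=1)


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Matrix square root of a PSD matrix (eigendecomposition; handles rank deficiency)."""
    w, v = np.linalg.eigh(np.asarray(mat, dtype=float))
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _survival_draw(latent: float, link: str, rng) -> bool:
    """Overwinter survival from the latent liability.

    Under the logit link the latent residual is extra-logistic heterogeneity
    and survival is Bernoulli(inv-logit(latent)); under the probit link the
    Gaussian residual already *is* the liability threshold noise, so survival
    is the deterministic indicator latent > 0 (the standard liability-model
    convention, matching the fitted probit augmentation exactly).
    """
    if link == "logit":
        return rng.random() < 1.0 / (1.0 + math.exp(-latent))
    return latent > 0.0


def _fixed_row(cfg: SimulationConfig, age: int, sex: str) -> np.ndarray:
    vals = {"intercept": 1.0, "age": float(age), "age2": float(age) ** 2,
            "sex_m": 1.0 if sex == "M" else 0.0, "adult": 1.0 if age > 0 else 0.0}
    out = np.zeros(4)
    for k, trait in enumerate(TRAITS):
        coefs = cfg.fixed_effects.get(trait, {})
        out[k] = sum(c * vals[t] for t, c in coefs.items())
    return out


def simulate_population(config: SimulationConfig) -> tuple[list[CaptureRecord], SimulationTruth]:
    """Simulate the longitudinal study defined by ``config``.

    Returns the captured records (individuals never captured do not appear)
    and a :class:`SimulationTruth` holding the drawn individual, year, batch
    and residual effects.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    birth = rng.integers(0, config.n_years, size=n)
    sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    ids = [f"I{i:05d}" for i in range(n)]

    L_ind = _psd_sqrt(config.sigma_individual)
    L_yr = _psd_sqrt(config.sigma_year)
    L_res = _psd_sqrt(config.sigma_residual)
    U = rng.standard_normal((n, 4)) @ L_ind.T
    V = rng.standard_normal((config.n_years, 4)) @ L_yr.T

    theta = config.fec_dispersion
    rows: list[dict] = []
    resid_rows: list[dict] = []
    for i in range(n):
        age = 0
        year = int(birth[i])
        while year < config.n_years and age <= config.max_age:
            e = L_res @ rng.standard_normal(4)
            latent = _fixed_row(config, age, sexes[i]) + U[i] + V[year] + e

            survived = _survival_draw(latent[3], config.survival_link, rng)

            captured = rng.random() < config.capture_prob
            mu_fec = math.exp(min(latent[1], 30.0))
            if math.isinf(theta):
                count = int(rng.poisson(mu_fec))
            else:
                count = int(rng.negative_binomial(theta, theta / (theta + mu_fec)))
            if captured:
                rows.append({
                    "individual_id": ids[i], "year": config.start_year + year,
                    "age": age, "sex": sexes[i],
                    "age_class": "lamb" if age == 0 else "adult",
                    "rltl_base": latent[0] + config.rltl_fec_slope * 100.0 * count,
                    "fec": 100.0 * count,
                    "igg_base": latent[2],
                    "survival": 1.0 if survived else 0.0,
                })
                resid_rows.append({
                    "individual_id": ids[i], "year": config.start_year + year,
                    "e_rltl": e[0], "e_fec": e[1], "e_igg_tc": e[2], "e_survival": e[3],
                })
            if not survived:
                break
            age += 1
            year += 1

    # assay batches: captures are assigned to plates in randomized order
    # (plates deliberately mix years, as in the lab design, so plate effects
    # are not confounded with year effects)
    qpcr_plate = {}
    qpcr_row = {}
    elisa_plate = {}
    for pos, r in enumerate(rng.permutation(len(rows))):
        p = pos // config.qpcr_plate_size
        qpcr_plate[int(r)] = f"QP{p:04d}"
        qpcr_row[int(r)] = f"QP{p:04d}:R{(pos % config.qpcr_plate_size) % 8 + 1}"
    for pos, r in enumerate(rng.permutation(len(rows))):
        elisa_plate[int(r)] = f"EP{pos // config.elisa_plate_size:04d}"

    sds = config.assay_sds
    batch_effects: dict[str, dict[str, float]] = {}
    for name, labels in (("qpcr_plate", qpcr_plate), ("qpcr_row", qpcr_row),
                         ("elisa_plate", elisa_plate)):
        uniq = sorted(set(labels.values()))
        draws = rng.normal(0.0, sds.get(name, 0.0), size=len(uniq))
        batch_effects[name] = dict(zip(uniq, draws.tolist()))

    miss = config.missingness
    miss_draws = rng.random((len(rows), 4))
    records: list[CaptureRecord] = []
    for r, row in enumerate(rows):
        rltl = row["rltl_base"] + batch_effects["qpcr_plate"][qpcr_plate[r]] \
            + batch_effects["qpcr_row"][qpcr_row[r]]
        igg = row["igg_base"] + batch_effects["elisa_plate"][elisa_plate[r]]
        vals = {"rltl": rltl, "fec": row["fec"], "igg_tc": igg, "survival": row["survival"]}
        for k, trait in enumerate(TRAITS):
            if miss_draws[r, k] < miss.get(trait, 0.0):
                vals[trait] = math.nan
        records.append(CaptureRecord(
            individual_id=row["individual_id"], year=row["year"], age=row["age"],
            sex=row["sex"], age_class=row["age_class"],
            rltl=vals["rltl"], fec=vals["fec"], igg_tc=vals["igg_tc"],
            survival=vals["survival"],
            qpcr_plate=qpcr_plate[r], qpcr_row=qpcr_row[r], elisa_plate=elisa_plate[r],
        ))

    truth = SimulationTruth(
        config=config,
        individual_effects=pd.DataFrame(U, index=pd.Index(ids, name="individual_id"),
                                        columns=[f"u_{t}" for t in TRAITS]),
        year_effects=pd.DataFrame(V, index=pd.Index(
            [config.start_year + y for y in range(config.n_years)], name="year"),
            columns=[f"v_{t}" for t in TRAITS]),
        batch_effects=batch_effects,
        residuals=pd.DataFrame(resid_rows) if resid_rows else pd.DataFrame(
            columns=["individual_id", "year", "e_rltl", "e_fec", "e_igg_tc", "e_survival"]),
        n_records=len(records),
    )
    return records, truth


def records_to_frame(records: list[CaptureRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[CaptureRecord]:
    return [CaptureRecord(**{c: row[c] for c in RECORD_COLUMNS}) for _, row in df.iterrows()]


def write_records(records: list[CaptureRecord] | pd.DataFrame, path) -> None:
    """Write capture records as CSV (one row per individual x year capture)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "qpcr_plate": str,
                                  "qpcr_row": str, "elisa_plate": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record table missing columns: {sorted(missing)}")
    return df


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


# ---------------------------------------------------------------------------
# raw assay plate generation (inverse of the assays-module formulas)
# ---------------------------------------------------------------------------

def simulate_qpcr_wells(records, config: SimulationConfig) -> pd.DataFrame:
    """Generate a well-level qPCR table whose processing reproduces each
    record's RLTL up to the injected triplicate noise.

    One row per well with columns (plate, row, sample, amplicon, cq,
    efficiency, role); every plate carries 8 calibrator wells and 2
    non-template controls per amplicon.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[np.isfinite(df["rltl"].to_numpy(dtype=float))]
    rng = np.random.default_rng((int(config.seed), 1))
    wells = []
    for plate, grp in df.groupby("qpcr_plate", sort=True):
        eff = {"TEL": float(np.clip(rng.normal(1.90, 0.02), 1.7, 2.1)),
               "B2M": float(np.clip(rng.normal(1.85, 0.02), 1.7, 2.1))}
        cal_base = {"TEL": rng.normal(24.0, 0.5), "B2M": rng.normal(21.0, 0.5)}
        cal_cq = {a: cal_base[a] + rng.normal(0.0, 0.05, size=8) for a in ("TEL", "B2M")}
        cal_mean = {a: float(np.mean(cal_cq[a])) for a in ("TEL", "B2M")}
        for a in ("TEL", "B2M"):
            for w in range(8):
                wells.append({"plate": plate, "row": "CAL", "sample": f"cal{w+1}",
                              "amplicon": a, "cq": cal_cq[a][w],
                              "efficiency": eff[a], "role": "calibrator"})
            for w in range(2):
                wells.append({"plate": plate, "row": "NTC", "sample": f"ntc{w+1}",
                              "amplicon": a, "cq": np.nan,
                              "efficiency": eff[a], "role": "NTC"})
        for _, rec in grp.iterrows():
            target = float(rec["rltl"])
            if target <= 0:
                raise ValueError("RLTL targets must be positive to invert the qPCR formula")
            # sample loading offset on the reference amplicon, then solve the
            # telomere Cq so the T/S ratio formula returns `target` exactly
            delta_b = rng.normal(0.0, config.qpcr_loading_sd) if config.qpcr_loading_sd > 0 else 0.0
            mean_b = cal_mean["B2M"] - delta_b
            delta_t = (math.log(target) + delta_b * math.log(eff["B2M"])) / math.log(eff["TEL"])
            mean_t = cal_mean["TEL"] - delta_t
            for a, m in (("TEL", mean_t), ("B2M", mean_b)):
                noise = rng.normal(0.0, config.qpcr_triplicate_sd, size=3) \
                    if config.qpcr_triplicate_sd > 0 else np.zeros(3)
                for w in range(3):
                    wells.append({"plate": plate, "row": rec["qpcr_row"],
                                  "sample": rec["individual_id"] + "@" + str(rec["year"]),
                                  "amplicon": a, "cq": m + noise[w],
                                  "efficiency": eff[a], "role": "sample"})
    return pd.DataFrame(wells)


def simulate_qpcr_plates(records, config: SimulationConfig):
    """Return the per-sample :class:`~telovar.assays.QpcrSampleSet` list for
    the generated well table (see :func:`simulate_qpcr_wells`)."""
    from .assays import qpcr_sample_sets_from_wells

    return qpcr_sample_sets_from_wells(simulate_qpcr_wells(records, config))


def simulate_elisa_wells(records, config: SimulationConfig) -> pd.DataFrame:
    """Generate a well-level ELISA table (duplicate sample ODs plus blank and
    positive-control wells per plate, each plate run in duplicate)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[np.isfinite(df["igg_tc"].to_numpy(dtype=float))]
    rng = np.random.default_rng((int(config.seed), 2))
    wells = []
    for plate, grp in df.groupby("elisa_plate", sort=True):
        for rep, suffix in ((0, "a"), (1, "b")):
            plate_id = f"{plate}{suffix}"
            blank = float(rng.normal(0.05, 0.005))
            positive = float(rng.normal(1.05, 0.02))
            for role, od in (("blank", blank), ("blank", blank),
                             ("positive", positive), ("positive", positive)):
                wells.append({"plate": plate_id, "pair": plate, "replicate": suffix,
                              "sample": role, "od": od, "role": role})
            for _, rec in grp.iterrows():
                target = float(rec["igg_tc"])
                mean_od = blank + target * (positive - blank)
                noise = rng.normal(0.0, config.elisa_duplicate_sd, size=2) \
                    if config.elisa_duplicate_sd > 0 else np.zeros(2)
                for w in range(2):
                    wells.append({"plate": plate_id, "pair": plate, "replicate": suffix,
                                  "sample": rec["individual_id"] + "@" + str(rec["year"]),
                                  "od": mean_od + noise[w], "role": "sample"})
    return pd.DataFrame(wells)


def simulate_elisa_plates(records, config: SimulationConfig):
    """Return :class:`~telovar.assays.ElisaPlateData` objects for the
    generated ELISA wells (each physical plate appears as a duplicate pair)."""
    from .assays import elisa_plates_from_wells

    return elisa_plates_from_wells(simulate_elisa_wells(records, config))
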