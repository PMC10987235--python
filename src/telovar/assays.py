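"""Raw assay measurements -> analysis traits, with replicate QC.

Three traits are computed here:

* **RLTL** — relative leucocyte telomere length from qPCR triplicates,
  ``E_TEL^(Cq_TEL[cal] - Cq_TEL[sample]) / E_B2M^(Cq_B2M[cal] - Cq_B2M[sample])``,
  where efficiencies are per-plate amplicon means and calibrator Cqs are plate
  means over 8 calibrator wells.  Samples are excluded when either amplicon's
  triplicate coefficient of variation exceeds 5% or an efficiency falls
  outside a validity window.
* **IgG-Tc** — blank-corrected optical-density ratio
  ``(sample OD - blank OD) / (positive OD - blank OD)`` from ELISA duplicates,
  with duplicates removed at COV > 0.2 and duplicate plate pairs failing a
  Pearson-correlation gate of 0.8 flagged for rerun.
* **FEC** — McMaster slide egg count x 100 eggs per gram.

Threshold comparisons are strict as written (> 0.05, > 0.2, < 0.8); boundary
values pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COV_THRESHOLD_QPCR = 0.05
COV_THRESHOLD_ELISA = 0.2
PLATE_PAIR_CORR_THRESHOLD = 0.8
EFFICIENCY_WINDOW = (1.6, 2.2)
FEC_MULTIPLIER = 100.0


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by mean (replicate-QC statistic)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need at least two finite values")
    m = x.mean()
    if m == 0:
        raise ValueError("COV undefined for zero mean")
    return float(x.std(ddof=1) / m)


@dataclass
class QpcrSampleSet:
    """Triplicate Cqs and plate efficiencies for one sample on one plate."""

    sample_id: str
    plate_id: str
    row_id: str
    cq_tel: np.ndarray          # 3 cycle values, telomere amplicon
    cq_b2m: np.ndarray          # 3 cycle values, reference amplicon
    efficiency_tel: float       # per-plate mean amplification efficiency
    efficiency_b2m: float
    cq_tel_calibrator: float    # plate mean over 8 calibrator wells
    cq_b2m_calibrator: float

    def validate(self) -> None:
        if self.efficiency_tel <= 1 or self.efficiency_b2m <= 1:
            raise ValueError("amplification efficiencies must exceed 1")
        for cq in (self.cq_tel, self.cq_b2m):
            if len(cq) != 3 or np.any(np.asarray(cq, dtype=float) <= 0):
                raise ValueError("triplicate Cq values must be 3 positive cycles")


@dataclass
class RltlResult:
    value: float | None
    excluded: bool = False
    reason: str | None = None


def compute_rltl(s: QpcrSampleSet, cov_threshold: float = COV_THRESHOLD_QPCR,
                 efficiency_window: tuple[float, float] = EFFICIENCY_WINDOW) -> RltlResult:
    """T/S ratio for one sample, or an excluded flag with the failing rule."""
    s.validate()
    lo, hi = efficiency_window
    for name, e in (("TEL", s.efficiency_tel), ("B2M", s.efficiency_b2m)):
        if not lo <= e <= hi:
            return RltlResult(None, True, f"efficiency_{name}")
    for name, cq in (("TEL", s.cq_tel), ("B2M", s.cq_b2m)):
        if coefficient_of_variation(cq) > cov_threshold:
            return RltlResult(None, True, f"triplicate_cov_{name}")
    d_tel = s.cq_tel_calibrator - float(np.mean(s.cq_tel))
    d_b2m = s.cq_b2m_calibrator - float(np.mean(s.cq_b2m))
    value = s.efficiency_tel ** d_tel / s.efficiency_b2m ** d_b2m
    return RltlResult(float(value))


def od_ratio(sample_od: float, blank_od: float, positive_od: float) -> float:
    """Blank-corrected OD relative to the plate positive control."""
    if positive_od <= blank_od:
        raise ValueError("degenerate plate: positive control OD must exceed blank OD")
    return (sample_od - blank_od) / (positive_od - blank_od)


@dataclass
class ElisaPlateData:
    """Duplicate sample ODs plus control wells for one ELISA plate."""

    plate_id: str
    sample_ids: list[str]
    od_a: np.ndarray
    od_b: np.ndarray
    blank_od: float
    positive_od: float
    duplicate_plate_id: str | None = None

    def validate(self) -> None:
        if self.positive_od <= self.blank_od:
            raise ValueError("positive control OD must exceed blank OD")
        if not (len(self.sample_ids) == len(self.od_a) == len(self.od_b)):
            raise ValueError("duplicate OD arrays must align with sample ids")


@dataclass
class ElisaQcResult:
    plate_id: str
    kept: pd.DataFrame          # sample_id, od_mean, od_ratio
    excluded_ids: list[str] = field(default_factory=list)


def filter_elisa_duplicates(plate: ElisaPlateData,
                            cov_threshold: float = COV_THRESHOLD_ELISA) -> ElisaQcResult:
    """Drop samples whose duplicate COV exceeds the threshold; survivors carry
    the duplicate mean OD and its blank-corrected ratio."""
    plate.validate()
    kept_rows, excluded = [], []
    for sid, a, b in zip(plate.sample_ids, plate.od_a, plate.od_b):
        if coefficient_of_variation([a, b]) > cov_threshold:
            excluded.append(sid)
            continue
        mean_od = (a + b) / 2.0
        kept_rows.append({"sample_id": sid, "od_mean": mean_od,
                          "od_ratio": od_ratio(mean_od, plate.blank_od, plate.positive_od)})
    kept = pd.DataFrame(kept_rows, columns=["sample_id", "od_mean", "od_ratio"])
    return ElisaQcResult(plate.plate_id, kept, excluded)


@dataclass
class PlatePairCheck:
    correlation: float
    passed: bool
    n_shared: int


def check_plate_pair(plate_a: ElisaPlateData, plate_b: ElisaPlateData,
                     threshold: float = PLATE_PAIR_CORR_THRESHOLD) -> PlatePairCheck:
    """Pearson correlation of mean ODs over shared samples; fail iff < threshold."""
    a = dict(zip(plate_a.sample_ids, (np.asarray(plate_a.od_a) + np.asarray(plate_a.od_b)) / 2))
    b = dict(zip(plate_b.sample_ids, (np.asarray(plate_b.od_a) + np.asarray(plate_b.od_b)) / 2))
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples to correlate duplicate plates")
    r = float(stats.pearsonr([a[s] for s in shared], [b[s] for s in shared]).statistic)
    return PlatePairCheck(r, passed=not r < threshold, n_shared=len(shared))


def fec_from_count(egg_count: int) -> float:
    """Eggs per gram from a McMaster slide count (count x 100)."""
    if egg_count < 0:
        raise ValueError("egg count cannot be negative")
    return float(egg_count) * FEC_MULTIPLIER


@dataclass
class TraitScalers:
    """Standardization constants, kept so model estimates can be back-transformed."""

    means: dict[str, float]
    sds: dict[str, float]


def prepare_model_traits(records: pd.DataFrame,
                         zscore: tuple[str, ...] = ("rltl", "igg_tc", "age"),
                         fec_col: str = "fec") -> tuple[pd.DataFrame, TraitScalers]:
    """Model-scale transform of an already-selected analysis subset.

    RLTL, IgG-Tc and age are z-scored over the subset; FEC is rounded to the
    nearest whole number and divided by 100 (back to slide-count units).
    """
    df = records.copy()
    means, sds = {}, {}
    for col in zscore:
        x = df[col].to_numpy(dtype=float)
        m = float(np.nanmean(x))
        s = float(np.nanstd(x, ddof=1))
        if not s > 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
        df[col] = (x - m) / s
        means[col], sds[col] = m, s
    if fec_col in df.columns:
        df[fec_col] = np.round(df[fec_col].to_numpy(dtype=float)) / 100.0
    return df, TraitScalers(means, sds)


# ---------------------------------------------------------------------------
# well-table IO
# ---------------------------------------------------------------------------

def qpcr_sample_sets_from_wells(wells: pd.DataFrame) -> list[QpcrSampleSet]:
    """Aggregate a well-level qPCR table (plate, row, sample, amplicon, cq,
    efficiency, role) into per-sample triplicate sets.  NTC wells are checked
    for non-amplification but not used numerically."""
    out = []
    for plate, grp in wells.groupby("plate", sort=True):
        ntc = grp[grp["role"] == "NTC"]
        if np.isfinite(ntc["cq"].to_numpy(dtype=float)).any():
            raise ValueError(f"plate {plate}: non-template control amplified")
        eff = {a: float(g["efficiency"].mean())
               for a, g in grp[grp["role"] == "sample"].groupby("amplicon")}
        cal = {a: float(g["cq"].mean())
               for a, g in grp[grp["role"] == "calibrator"].groupby("amplicon")}
        samples = grp[grp["role"] == "sample"]
        for sid, sg in samples.groupby("sample", sort=True):
            tel = sg[sg["amplicon"] == "TEL"]["cq"].to_numpy(dtype=float)
            b2m = sg[sg["amplicon"] == "B2M"]["cq"].to_numpy(dtype=float)
            row = sg["row"].iloc[0]
            out.append(QpcrSampleSet(
                sample_id=str(sid), plate_id=str(plate), row_id=str(row),
                cq_tel=tel, cq_b2m=b2m,
                efficiency_tel=eff["TEL"], efficiency_b2m=eff["B2M"],
                cq_tel_calibrator=cal["TEL"], cq_b2m_calibrator=cal["B2M"]))
    return out


def elisa_plates_from_wells(wells: pd.DataFrame) -> list[ElisaPlateData]:
    """Aggregate a well-level ELISA table into per-plate duplicate data."""
    out = []
    pair_col = "pair" if "pair" in wells.columns else None
    for plate, grp in wells.groupby("plate", sort=True):
        blank = float(grp[grp["role"] == "blank"]["od"].mean())
        positive = float(grp[grp["role"] == "positive"]["od"].mean())
        samples = grp[grp["role"] == "sample"]
        ids, od_a, od_b = [], [], []
        for sid, sg in samples.groupby("sample", sort=True):
            ods = sg["od"].to_numpy(dtype=float)
            if len(ods) != 2:
                raise ValueError(f"sample {sid} on plate {plate}: expected duplicate wells")
            ids.append(str(sid))
            od_a.append(ods[0])
            od_b.append(ods[1])
        dup = None
        if pair_col is not None:
            pair = grp[pair_col].iloc[0]
            siblings = wells[(wells[pair_col] == pair) & (wells["plate"] != plate)]["plate"]
            dup = str(siblings.iloc[0]) if len(siblings) else None
        out.append(ElisaPlateData(str(plate), ids, np.array(od_a), np.array(od_b),
                                  blank, positive, duplicate_plate_id=dup))
    return out


def process_qpcr_wells(wells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compute RLTL for every sample in a well table.

    Returns (table with sample, plate, row, rltl, excluded, reason) and a QC
    report counting exclusions per rule.
    """
    rows = []
    for s in qpcr_sample_sets_from_wells(wells):
        res = compute_rltl(s)
        rows.append({"sample": s.sample_id, "plate": s.plate_id, "row": s.row_id,
                     "rltl": math.nan if res.value is None else res.value,
                     "excluded": res.excluded, "reason": res.reason})
    df = pd.DataFrame(rows)
    report = {"n_samples": len(df), "n_excluded": int(df["excluded"].sum()),
              "by_rule": df[df["excluded"]]["reason"].value_counts().to_dict()}
    return df, report


def process_elisa_wells(wells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Compute IgG-Tc OD ratios from a duplicate-plate well table, applying
    the duplicate-COV filter and the cross-plate correlation gate."""
    plates = {p.plate_id: p for p in elisa_plates_from_wells(wells)}
    failed_pairs, checked = [], set()
    for pid, plate in plates.items():
        dup = plate.duplicate_plate_id
        if dup and dup in plates and (dup, pid) not in checked:
            checked.add((pid, dup))
            if not check_plate_pair(plate, plates[dup]).passed:
                failed_pairs.append((pid, dup))
    rows, n_cov_excluded = [], 0
    for pid, plate in plates.items():
        qc = filter_elisa_duplicates(plate)
        n_cov_excluded += len(qc.excluded_ids)
        for _, r in qc.kept.iterrows():
            rows.append({"sample": r["sample_id"], "plate": pid, "igg_tc": r["od_ratio"]})
    df = pd.DataFrame(rows)
    report = {"n_samples": len(df), "n_duplicate_cov_excluded": n_cov_excluded,
              "failed_plate_pairs": failed_pairs}
    return df, report


def write_qc_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
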