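"""End-to-end orchestration: simulate -> assay QC -> subset -> fit -> derive.

An :class:`AnalysisPlan` names a dataset selector (lambs, adults >=3, adults
>=1, whole population) and a model-menu entry, and :func:`run_plan` executes
the staged pipeline, writing each stage's resolved configuration, seed, row
counts per filter and a software version stamp into the output directory so
any stage can be re-run from its persisted intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .assays import prepare_model_traits
from .decomp import derive_all
from .mcmc import ModelSpec, MultiTraitGLMM, UnivariateLMM
from .synth import SimulationConfig, records_to_frame, simulate_population, write_truth

logger = logging.getLogger(__name__)

SELECTORS = {
    "lambs": lambda df: df["age"] == 0,
    "adults_ge3": lambda df: df["age"] >= 3,
    "adults_ge1": lambda df: df["age"] >= 1,
    "population": lambda df: df["age"] >= 0,
}

#: model menu: entry -> (kind, required traits, compatible selectors, settings)
MODEL_MENU: dict[str, dict] = {
    "lamb-fec": dict(kind="univariate", traits=("rltl", "fec"),
                     selectors=("lambs",),
                     fixed_terms=("intercept", "fec"),
                     random_levels=("year", "qpcr_plate", "qpcr_row")),
    "lamb-igg": dict(kind="univariate", traits=("rltl", "igg_tc"),
                     selectors=("lambs",),
                     fixed_terms=("intercept", "igg_tc"),
                     random_levels=("year", "qpcr_plate", "qpcr_row")),
    "lamb-combined": dict(kind="univariate", traits=("rltl", "fec", "igg_tc"),
                          selectors=("lambs",),
                          fixed_terms=("intercept", "fec", "igg_tc"),
                          random_levels=("year", "qpcr_plate", "qpcr_row")),
    "lamb-sex-fec": dict(kind="univariate", traits=("rltl", "fec"),
                         selectors=("lambs",),
                         fixed_terms=("intercept", "fec", "sex", "sex:fec"),
                         random_levels=("year", "qpcr_plate", "qpcr_row")),
    "lamb-sex-igg": dict(kind="univariate", traits=("rltl", "igg_tc"),
                         selectors=("lambs",),
                         fixed_terms=("intercept", "igg_tc", "sex", "sex:igg_tc"),
                         random_levels=("year", "qpcr_plate", "qpcr_row")),
    "adult-sex-fec": dict(kind="univariate", traits=("rltl", "fec"),
                          selectors=("adults_ge3", "adults_ge1"),
                          fixed_terms=("intercept", "age", "fec", "sex", "sex:fec"),
                          random_levels=("individual", "year", "qpcr_plate", "qpcr_row")),
    "adult-sex-igg": dict(kind="univariate", traits=("rltl", "igg_tc"),
                          selectors=("adults_ge3", "adults_ge1"),
                          fixed_terms=("intercept", "age", "igg_tc", "sex", "sex:igg_tc"),
                          random_levels=("individual", "year", "qpcr_plate", "qpcr_row")),
    "adult-trivariate": dict(kind="multivariate", traits=("rltl", "fec", "igg_tc"),
                             selectors=("adults_ge3", "adults_ge1"), prepare=True),
    "adult-trivariate-no-age": dict(
        kind="multivariate", traits=("rltl", "fec", "igg_tc"),
        selectors=("adults_ge3", "adults_ge1"), prepare=True,
        fixed_terms={"rltl": ("intercept",), "fec": ("intercept", "sex"),
                     "igg_tc": ("intercept", "sex")}),
    "population-quadrivariate": dict(
        kind="multivariate", traits=("rltl", "fec", "igg_tc", "survival"),
        selectors=("population",), prepare=True),
}


@dataclass
class AnalysisPlan:
    """One staged run: dataset selector + model entry + paths + seed."""

    dataset: str
    model: str
    outdir: str
    seed: int = 0
    iterations: int | None = None
    warmup: int | None = None
    thin: int | None = None

    def validate(self) -> None:
        if self.dataset not in SELECTORS:
            raise ValueError(f"unknown dataset selector {self.dataset!r}")
        if self.model not in MODEL_MENU:
            raise ValueError(f"unknown model {self.model!r}")
        entry = MODEL_MENU[self.model]
        if self.dataset not in entry["selectors"]:
            raise ValueError(f"model {self.model!r} is incompatible with "
                             f"dataset selector {self.dataset!r}")


def subset_records(records: pd.DataFrame, selector: str,
                   required_traits=()) -> tuple[pd.DataFrame, dict]:
    """Filter records by age selector and complete-case trait availability.

    Never drops rows silently: the returned log satisfies
    ``n_input == n_age_filtered + n_incomplete + n_kept``.
    """
    if selector not in SELECTORS:
        raise ValueError(f"unknown dataset selector {selector!r}")
    mask_age = SELECTORS[selector](records).to_numpy()
    selected = records[mask_age]
    complete = selected
    for t in required_traits:
        complete = complete[complete[t].notna()]
    log = {
        "selector": selector,
        "n_input": int(len(records)),
        "n_age_filtered": int(len(records) - len(selected)),
        "n_incomplete": int(len(selected) - len(complete)),
        "n_kept": int(len(complete)),
        "n_individuals": int(complete["individual_id"].nunique()) if len(complete) else 0,
    }
    if len(complete) == 0:
        raise ValueError(f"selector {selector!r} left an empty subset")
    return complete.reset_index(drop=True), log


def run_plan(plan: AnalysisPlan, records: pd.DataFrame | None = None,
             sim_config: SimulationConfig | None = None) -> dict:
    """Execute the staged pipeline and write a reproducible report bundle."""
    plan.validate()
    outdir = Path(plan.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry = MODEL_MENU[plan.model]

    if records is None:
        sim_config = sim_config or SimulationConfig(seed=plan.seed)
        recs, truth = simulate_population(sim_config)
        records = records_to_frame(recs)
        records.to_csv(outdir / "records.csv", index=False)
        write_truth(truth, outdir / "truth.json")

    subset, counts = subset_records(records, plan.dataset, entry["traits"])
    logger.info("subset %s: %s", plan.dataset, counts)

    scalers = None
    if entry.get("prepare"):
        subset, scalers = prepare_model_traits(subset)

    chain = {"n_iter": plan.iterations or 50_000,
             "warmup": plan.warmup or 10_000,
             "thin": plan.thin or 40}
    if entry["kind"] == "univariate":
        est = UnivariateLMM(response="rltl", fixed_terms=entry["fixed_terms"],
                            random_levels=entry["random_levels"],
                            seed=plan.seed, **chain)
    else:
        est = MultiTraitGLMM(traits=entry["traits"],
                             fixed_terms=entry.get("fixed_terms"),
                             seed=plan.seed, **chain)
    est.fit(subset)

    est.draws_.save(outdir)
    est.summary_.to_csv(outdir / "summary.csv")
    derived = None
    if entry["kind"] == "multivariate":
        derived = derive_all(est.draws_)
        derived.to_csv(outdir / "derived.csv", index=False)

    bundle = {
        "plan": dataclasses.asdict(plan),
        "counts": counts,
        "chain": chain,
        "scalers": None if scalers is None else
        {"means": scalers.means, "sds": scalers.sds},
        "version": __version__,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(bundle, fh, indent=1)
    bundle["summary"] = est.summary_
    bundle["derived"] = derived
    bundle["draws"] = est.draws_
    return bundle
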