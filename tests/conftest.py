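import numpy as np
import pandas as pd
import pytest


def gaussian_mixed_frame(n_ind=120, obs_per_ind=3, n_years=8, v_ind=0.4,
                         v_year=0.2, v_res=0.6, cov_ind=0.0, beta_age=0.0,
                         seed=0, traits=("rltl", "igg_tc")):
    """Hand-rolled two-trait Gaussian repeat-measures data (independent of the
    synth module) for validating the samplers against analytic oracles."""
    rng = np.random.default_rng(seed)
    k = len(traits)
    s_ind = np.full((k, k), cov_ind) + np.eye(k) * (v_ind - cov_ind)
    u = rng.multivariate_normal(np.zeros(k), s_ind, size=n_ind)
    yr_eff = rng.normal(0, np.sqrt(v_year), size=(n_years, k))
    rows = []
    for i in range(n_ind):
        years = rng.choice(n_years, size=obs_per_ind, replace=False)
        for t in years:
            e = rng.normal(0, np.sqrt(v_res), size=k)
            age = float(3 + t % 5)
            vals = u[i] + yr_eff[t] + e + beta_age * age
            row = {"individual_id": f"I{i:04d}", "year": 2000 + int(t),
                   "age": age, "sex": "F" if i % 2 else "M", "age_class": "adult",
                   "qpcr_plate": f"P{i % 10}", "qpcr_row": f"P{i % 10}:R{i % 4}",
                   "elisa_plate": f"E{i % 8}"}
            row.update({tr: vals[j] for j, tr in enumerate(traits)})
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_trivariate_fit():
    """One short trivariate fit on a small synthetic adult dataset, shared by
    structural tests (PSD draws, labelling, derived quantities)."""
    from telovar.assays import prepare_model_traits
    from telovar.mcmc import MultiTraitGLMM
    from telovar.presets import trivariate_recovery_config
    from telovar.synth import records_to_frame, simulate_population

    cfg = trivariate_recovery_config(seed=7)
    cfg.n_individuals = 320
    records, _ = simulate_population(cfg)
    df = records_to_frame(records)
    prep, _ = prepare_model_traits(df[df["age"] >= 3])
    est = MultiTraitGLMM(traits=("rltl", "fec", "igg_tc"),
                         n_iter=3200, warmup=1000, thin=2, seed=5)
    est.fit(prep)
    return est
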