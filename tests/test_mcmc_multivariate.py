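"""Multivariate GLMM sampler: oracles, invariants, non-Gaussian families."""

import numpy as np
import pandas as pd
import pytest

from telovar.mcmc import MultiTraitGLMM
from telovar.summaries import hpd_interval

from conftest import gaussian_mixed_frame


def fit_bivariate(df, seed=1, n_iter=4000, warmup=1000, thin=3, **kw):
    est = MultiTraitGLMM(traits=("rltl", "igg_tc"),
                         fixed_terms={"rltl": ("intercept",),
                                      "igg_tc": ("intercept",)},
                         random_levels=("individual", "year"), assay_effects={},
                         n_iter=n_iter, warmup=warmup, thin=thin, seed=seed, **kw)
    return est.fit(df)


class TestGaussianOracles:
    def test_variances_match_reml_oracle(self):
        """Trait-wise variance components agree with an independent REML fit
        (statsmodels MixedLM, one grouping level) on individual-only data."""
        sm = pytest.importorskip("statsmodels.api")
        df = gaussian_mixed_frame(n_ind=250, obs_per_ind=3, v_ind=0.5,
                                  v_year=0.0, v_res=0.8, seed=10)
        est = MultiTraitGLMM(traits=("rltl", "igg_tc"),
                             fixed_terms={"rltl": ("intercept",),
                                          "igg_tc": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             n_iter=6000, warmup=1500, thin=3, seed=2).fit(df)
        for trait in ("rltl", "igg_tc"):
            md = sm.MixedLM.from_formula(f"{trait} ~ 1", groups="individual_id",
                                         data=df).fit(reml=True)
            v_ind_reml = float(md.cov_re.iloc[0, 0])
            v_res_reml = float(md.scale)
            post_ind = est.draws_.variance("individual", trait)
            post_res = est.draws_.variance("residual", trait)
            assert abs(post_ind.mean() - v_ind_reml) < 4 * post_ind.std()
            assert abs(post_res.mean() - v_res_reml) < 4 * post_res.std()

    def test_null_covariances_covered(self):
        """Two Gaussian traits generated independently: every cross-trait HPD
        covers zero."""
        df = gaussian_mixed_frame(n_ind=200, obs_per_ind=3, v_ind=0.4,
                                  v_year=0.15, v_res=0.6, cov_ind=0.0, seed=11)
        est = fit_bivariate(df, seed=3)
        for level in ("individual", "year", "residual"):
            chain = est.draws_.covariance(level, "rltl", "igg_tc")
            lo, hi = hpd_interval(chain)
            assert lo <= 0.0 <= hi, level

    def test_agrees_with_univariate_sampler(self):
        """On independent Gaussian traits the multivariate sampler matches the
        univariate sampler applied to one trait (sub-model equivalence)."""
        from telovar.mcmc import UnivariateLMM

        df = gaussian_mixed_frame(n_ind=200, obs_per_ind=3, v_ind=0.5,
                                  v_year=0.1, v_res=0.7, seed=12)
        multi = fit_bivariate(df, seed=4, n_iter=6000, warmup=1500, thin=3)
        uni = UnivariateLMM(response="rltl", fixed_terms=("intercept",),
                            random_levels=("individual", "year"),
                            n_iter=6000, warmup=1500, thin=3, seed=5).fit(df)
        for level in ("individual", "residual"):
            a = multi.draws_.variance(level, "rltl")
            b = uni.draws_.variance(level, "rltl")
            tol = 4 * np.sqrt(a.std() ** 2 + b.std() ** 2) / np.sqrt(50)
            assert abs(a.mean() - b.mean()) < max(tol, 0.08), level


class TestStructuralInvariants:
    def test_covariance_draws_symmetric_psd(self, small_trivariate_fit):
        for level, mats in small_trivariate_fit.draws_.covariances.items():
            assert np.allclose(mats, np.swapaxes(mats, 1, 2)), level
            eig = np.linalg.eigvalsh(mats)
            assert eig.min() > -1e-8, level

    def test_derived_correlations_bounded(self, small_trivariate_fit):
        from telovar.decomp import correlation_from_cov

        mats = small_trivariate_fit.draws_.covariances["residual"]
        for i in range(3):
            for j in range(i + 1, 3):
                r = correlation_from_cov(mats, i, j)
                assert np.all(np.abs(r) <= 1.0)

    def test_record_order_invariance(self):
        """Permuting record order changes posterior means only within
        Monte-Carlo noise."""
        df = gaussian_mixed_frame(n_ind=150, obs_per_ind=3, v_ind=0.4,
                                  v_year=0.1, v_res=0.6, seed=13)
        perm = df.sample(frac=1.0, random_state=42).reset_index(drop=True)
        a = fit_bivariate(df, seed=6).draws_
        b = fit_bivariate(perm, seed=7).draws_
        for level in ("individual", "residual"):
            va, vb = a.variance(level, "rltl"), b.variance(level, "rltl")
            assert abs(va.mean() - vb.mean()) < 4 * np.hypot(va.std(), vb.std()) / 3

    def test_seed_determinism(self):
        df = gaussian_mixed_frame(n_ind=60, obs_per_ind=2, seed=14)
        a = fit_bivariate(df, seed=8, n_iter=900, warmup=300, thin=3).draws_
        b = fit_bivariate(df, seed=8, n_iter=900, warmup=300, thin=3).draws_
        assert a.beta.equals(b.beta)
        assert np.array_equal(a.covariances["residual"], b.covariances["residual"])


class TestCountFamily:
    def make_count_frame(self, theta=None, seed=20, n_ind=250):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, np.sqrt(0.3), n_ind)
        rows = []
        for i in range(n_ind):
            for t in range(2):
                lat = np.log(5.0) + u[i] + rng.normal(0, np.sqrt(0.4))
                mu = np.exp(lat)
                y = rng.poisson(mu) if theta is None else \
                    rng.negative_binomial(theta, theta / (theta + mu))
                rows.append({"individual_id": f"I{i:04d}", "year": 2000 + t,
                             "fec": float(y)})
        return pd.DataFrame(rows)

    def test_posterior_predictive_overdispersion(self):
        """Overdispersed counts: posterior-predictive variance/mean ratio > 1."""
        df = self.make_count_frame()
        est = MultiTraitGLMM(traits=("fec",),
                             fixed_terms={"fec": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             n_iter=6000, warmup=2000, thin=4, seed=9).fit(df)
        rng = np.random.default_rng(0)
        d = est.draws_
        b0 = d.beta["fec:intercept"].to_numpy()
        v_ind = d.variance("individual", "fec")
        v_res = d.variance("residual", "fec")
        ratios = []
        for s in range(0, d.n_store, 10):
            lat = (b0[s] + rng.normal(0, np.sqrt(v_ind[s]), 400)
                   + rng.normal(0, np.sqrt(v_res[s]), 400))
            y_rep = rng.poisson(np.exp(lat))
            ratios.append(y_rep.var() / y_rep.mean())
        assert np.median(ratios) > 1.0

    def test_latent_variance_recovery(self):
        """Poisson-lognormal fit recovers the latent residual variance."""
        df = self.make_count_frame(seed=21, n_ind=400)
        est = MultiTraitGLMM(traits=("fec",),
                             fixed_terms={"fec": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             n_iter=8000, warmup=2000, thin=6, seed=10).fit(df)
        v_res = est.draws_.variance("residual", "fec")
        lo, hi = hpd_interval(v_res)
        assert lo < 0.4 < hi

    def test_mh_acceptance_in_healthy_range(self):
        df = self.make_count_frame(seed=22, n_ind=150)
        est = MultiTraitGLMM(traits=("fec",),
                             fixed_terms={"fec": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             n_iter=2500, warmup=1000, thin=3, seed=11).fit(df)
        assert 0.2 < est.accept_["fec"] < 0.7


class TestBinaryFamily:
    def test_probit_survival_rate_recovered(self):
        """Probit threshold model: the fitted intercept reproduces the
        observed survival proportion on the liability scale."""
        from scipy.special import ndtr

        rng = np.random.default_rng(30)
        n_ind = 400
        u = rng.normal(0, np.sqrt(0.3), n_ind)
        rows = []
        for i in range(n_ind):
            for t in range(2):
                lat = 0.6 + u[i] + rng.standard_normal()
                rows.append({"individual_id": f"I{i:04d}", "year": 2000 + t,
                             "survival": float(lat > 0)})
        df = pd.DataFrame(rows)
        est = MultiTraitGLMM(traits=("survival",),
                             fixed_terms={"survival": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             binary_link="probit",
                             n_iter=6000, warmup=2000, thin=4, seed=12).fit(df)
        b0 = est.draws_.beta["survival:intercept"].to_numpy()
        v_ind = est.draws_.variance("individual", "survival")
        implied = ndtr(b0 / np.sqrt(1.0 + v_ind)).mean()
        assert implied == pytest.approx(df["survival"].mean(), abs=0.05)

    def test_residual_variance_pinned(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({
            "individual_id": [f"I{i:03d}" for i in range(200) for _ in range(2)],
            "year": [2000 + t for _ in range(200) for t in range(2)],
            "survival": rng.integers(0, 2, 400).astype(float)})
        est = MultiTraitGLMM(traits=("survival",),
                             fixed_terms={"survival": ("intercept",)},
                             random_levels=("individual",), assay_effects={},
                             binary_link="probit",
                             n_iter=1200, warmup=400, thin=2, seed=13).fit(df)
        assert np.allclose(est.draws_.variance("residual", "survival"), 1.0)
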