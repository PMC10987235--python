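"""Block Gibbs sampler for multi-trait generalized linear mixed models.

The model for record *i* and trait *k* (K traits, complete cases) is

    l_ik = x_ik' beta_k + sum_L (alpha_Lk * u~_{L, g_L(i), k}) + e_ik

with e_i ~ N(0, Sigma_res) (unstructured K x K), and each random level L
(individual, year, assay batches) parameter-expanded: working effects
u~ ~ N(0, Psi_L) with redundant multipliers alpha_L ~ N(0, c I); the
effective level covariance is Sigma_L = diag(alpha) Psi diag(alpha).
Gaussian traits are observed directly (l = y); count traits link the latent
value to the observation through a log link (Poisson, or negative binomial
with fixed dispersion); binary traits through a logit (default) or probit
link with their residual latent variance fixed for identifiability.

Updates: fixed effects and working random effects by conjugate Gaussian
blocks; alpha multipliers as conjugate Gaussian "regressions" on their own
working effects; Psi and Sigma_res by (conditional) inverse-Wishart steps —
the residual step conditions on fixed diagonal blocks via the Wishart
Bartlett-block reparameterisation; count-trait latent residuals by
vectorised random-walk Metropolis with Robbins-Monro step adaptation during
warmup; probit binary latents by exact truncated-normal threshold
augmentation (logit binary latents fall back to the Metropolis update).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
import math

from scipy.special import ndtr, ndtri
from scipy.stats import invwishart, wishart


@dataclass
class TraitDef:
    name: str
    family: str = "gaussian"            # gaussian | count | binary
    link: str = ""                      # derived if empty
    dispersion: float | None = None     # NB size for count; None = Poisson
    fix_residual_var: float | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "count", "binary"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.link:
            self.link = {"gaussian": "identity", "count": "log", "binary": "logit"}[self.family]
        if self.family == "binary" and self.fix_residual_var is None:
            self.fix_residual_var = 1.0


@dataclass
class LevelDef:
    name: str
    codes: np.ndarray                   # (n,) integer group codes
    n_groups: int
    trait_idx: np.ndarray               # trait indices this level affects
    px: bool = True


@dataclass
class GibbsPriors:
    beta_variance: float = 1e8
    px_psi_scale: float = 1.0           # Psi_L ~ IW(scale * I, dim_L)
    px_alpha_mean: float = 0.0
    px_alpha_variance: float = 1000.0
    residual_scale: np.ndarray | None = None   # default identity
    residual_df: float | None = None           # default K + 1

    def validate(self, k: int) -> None:
        df = k + 1.0 if self.residual_df is None else float(self.residual_df)
        if df < k:
            raise ValueError("residual inverse-Wishart df must be >= trait dimension")


def _chol_sample(prec: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1)."""
    c, low = sla.cho_factor(prec, lower=True)
    mean = sla.cho_solve((c, low), lin)
    z = rng.standard_normal(len(lin))
    return mean + sla.solve_triangular(c, z, lower=low, trans="T")


def sample_conditional_invwishart(df: float, scale: np.ndarray, fixed_idx: np.ndarray,
                                  fixed_block: np.ndarray, rng) -> np.ndarray:
    """Draw Sigma ~ IW(df, scale) conditioned on Sigma[fixed, fixed] = fixed_block.

    Uses the Bartlett block decomposition of the Wishart precision
    W = Sigma^-1 ~ W(df, scale^-1): with the fixed indices as block 1,
    W_11.2 = Sigma_11^-1 is independent of (W_12, W_22), so it is replaced by
    the required value while W_22 and W_12 | W_22 are drawn from their
    unconditional distributions.
    """
    p = scale.shape[0]
    fixed_idx = np.asarray(fixed_idx, dtype=int)
    free_idx = np.array([i for i in range(p) if i not in set(fixed_idx.tolist())], dtype=int)
    if free_idx.size == 0:
        return np.asarray(fixed_block, dtype=float).copy()
    perm = np.concatenate([fixed_idx, free_idx])
    A = np.linalg.inv(scale)[np.ix_(perm, perm)]
    p1 = fixed_idx.size
    A11, A12, A22 = A[:p1, :p1], A[:p1, p1:], A[p1:, p1:]
    A11_2 = A11 - A12 @ np.linalg.solve(A22, A12.T)

    W22 = np.atleast_2d(wishart.rvs(df=df, scale=A22, random_state=rng))
    M = A12 @ np.linalg.solve(A22, W22)
    Lr = np.linalg.cholesky(A11_2)
    Lc = np.linalg.cholesky(W22)
    W12 = M + Lr @ rng.standard_normal((p1, p - p1)) @ Lc.T
    W11 = np.linalg.inv(np.atleast_2d(fixed_block)) + W12 @ np.linalg.solve(W22, W12.T)
    W = np.block([[W11, W12], [W12.T, W22]])
    sigma_perm = np.linalg.inv(W)
    # exact restoration of the fixed block (kill inversion round-off)
    sigma_perm[:p1, :p1] = fixed_block
    inv_perm = np.empty(p, dtype=int)
    inv_perm[perm] = np.arange(p)
    sigma = sigma_perm[np.ix_(inv_perm, inv_perm)]
    return (sigma + sigma.T) / 2.0


def _obs_loglik(trait: TraitDef, y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    eta = np.clip(eta, -30.0, 30.0)
    if trait.family == "count":
        if trait.dispersion is None:
            return y * eta - np.exp(eta)
        th = trait.dispersion
        return y * eta - (y + th) * np.log(th + np.exp(eta))
    if trait.family == "binary":
        # logit only: probit binary latents use the exact threshold update
        return y * eta - np.logaddexp(0.0, eta)
    raise AssertionError("no observation likelihood for gaussian traits")


def _init_latent(trait: TraitDef, y: np.ndarray) -> np.ndarray:
    if trait.family == "gaussian":
        return y.astype(float).copy()
    if trait.family == "count":
        return np.log(y + 0.5)
    return np.where(y > 0.5, 0.5, -0.5)


def _collapsed_probit_update(st: dict, k: int, kk: int, y: np.ndarray,
                             latent: np.ndarray, fixed: np.ndarray,
                             total_random: np.ndarray, mu_c: np.ndarray,
                             v_c: float, rng) -> None:
    """Blocked draw of (probit liabilities, one level's working effects).

    The liabilities of trait ``k`` are drawn with the level's trait-``k``
    working effects integrated out (their joint within-group covariance is
    ``v_c I + V 11'``; each record's conditional follows by Sherman-Morrison,
    swept in rounds so no two records of one group update together), then the
    working effects are redrawn from their exact conditional given the new
    liabilities.  Jointly this is one draw from the (liability, effect) block,
    which breaks the slow two-block coupling that otherwise throttles mixing
    of weakly-identified binary variance components.
    """
    L: LevelDef = st["def"]
    codes = L.codes
    n_groups = L.n_groups
    a_k = st["alpha"][kk]
    psi = st["psi"]
    kl = psi.shape[0]
    if kl == 1:
        m_u = np.zeros(n_groups)
        s2_u = psi[0, 0]
    else:
        oth = [a for a in range(kl) if a != kk]
        w_u = np.linalg.solve(psi[np.ix_(oth, oth)], psi[oth, kk])
        m_u = st["u"][:, oth] @ w_u
        s2_u = psi[kk, kk] - psi[kk, oth] @ w_u
    s2_u = max(s2_u, 1e-12)
    v_eff = a_k ** 2 * s2_u

    eta_minus = fixed[:, k] + total_random[:, k] - st["contrib"][:, k]
    base = eta_minus + mu_c
    m = base + (a_k * m_u)[codes]
    nj = st["counts"]
    gamma = v_eff / (v_c * (v_c + nj * v_eff))
    var_c = 1.0 / (1.0 / v_c - gamma)

    liab = latent[:, k].copy()
    resid = liab - m
    group_sum = np.zeros(n_groups)
    np.add.at(group_sum, codes, resid)
    for r in range(int(st["round_idx"].max()) + 1):
        idx = np.nonzero(st["round_idx"] == r)[0]
        if idx.size == 0:
            break
        g = codes[idx]
        other = group_sum[g] - resid[idx]
        mean_c = m[idx] + gamma[g] * var_c[g] * other
        sd = np.sqrt(var_c[g])
        lower = ndtr((0.0 - mean_c) / sd)
        u01 = rng.random(idx.size)
        u01 = np.where(y[idx, k] > 0.5, lower + u01 * (1.0 - lower), u01 * lower)
        u01 = np.clip(u01, 1e-12, 1.0 - 1e-12)
        new_liab = mean_c + sd * ndtri(u01)
        group_sum[g] += new_liab - m[idx] - resid[idx]
        resid[idx] = new_liab - m[idx]
        liab[idx] = new_liab
    latent[:, k] = liab

    t_sum = np.zeros(n_groups)
    np.add.at(t_sum, codes, liab - base)
    prec = 1.0 / s2_u + nj * a_k ** 2 / v_c
    lin = m_u / s2_u + a_k * t_sum / v_c
    new_u = lin / prec + rng.standard_normal(n_groups) / np.sqrt(prec)
    shift = a_k * (new_u - st["u"][:, kk])[codes]
    st["u"][:, kk] = new_u
    total_random[:, k] += shift
    st["contrib"][:, k] = st["contrib"][:, k] + shift


def run_gibbs(y: np.ndarray, X_list: list[np.ndarray], traits: list[TraitDef],
              levels: list[LevelDef], priors: GibbsPriors, n_iter: int, warmup: int,
              thin: int, seed: int, fix_variances: dict[str, np.ndarray] | None = None,
              collapse_level: str | None = None,
              ) -> dict:
    """Run the sampler; returns stored draws and chain metadata.

    ``fix_variances`` maps a level name (or ``"residual"``) to a covariance
    matrix held fixed throughout (its inverse-Wishart / expansion updates are
    skipped) — used for conjugate-oracle validation.  ``collapse_level``
    names a random level whose working effects are integrated out of the
    probit liability draws (see :func:`_collapsed_probit_update`).
    """
    y = np.asarray(y, dtype=float)
    n, K = y.shape
    if len(traits) != K or len(X_list) != K:
        raise ValueError("y columns, trait definitions and design matrices must align")
    if not np.all(np.isfinite(y)):
        raise ValueError("complete cases required: y contains non-finite values")
    if n_iter <= warmup or thin <= 0 or (n_iter - warmup) % thin:
        raise ValueError("need n_iter > warmup and thin dividing (n_iter - warmup)")
    priors.validate(K)
    fix_variances = dict(fix_variances or {})
    rng = np.random.default_rng(seed)

    p_list = [X.shape[1] for X in X_list]
    P = int(np.sum(p_list))
    offs = np.concatenate([[0], np.cumsum(p_list)])
    # cross products X_k' X_j, computed once
    C = [[X_list[k].T @ X_list[j] for j in range(K)] for k in range(K)]

    # ---- state ----
    latent = np.column_stack([_init_latent(t, y[:, k]) for k, t in enumerate(traits)])
    beta = [np.linalg.lstsq(X_list[k], latent[:, k], rcond=None)[0] for k in range(K)]
    fixed = np.column_stack([X_list[k] @ beta[k] for k in range(K)])

    fixed_res_idx = np.array([k for k, t in enumerate(traits)
                              if t.fix_residual_var is not None], dtype=int)
    V0 = np.eye(K) if priors.residual_scale is None else np.asarray(priors.residual_scale, float)
    nu0 = K + 1.0 if priors.residual_df is None else float(priors.residual_df)
    if "residual" in fix_variances:
        sigma_res = np.asarray(fix_variances["residual"], dtype=float)
    else:
        sigma_res = np.eye(K) * 0.5
        for k in fixed_res_idx:
            sigma_res[k, k] = traits[k].fix_residual_var
    W = np.linalg.inv(sigma_res)

    lev_state = []
    contrib = np.zeros((n, K))
    total_random = np.zeros((n, K))
    for L in levels:
        kL = len(L.trait_idx)
        counts = np.bincount(L.codes, minlength=L.n_groups).astype(float)
        st = {
            "def": L,
            "counts": counts,
            "u": np.zeros((L.n_groups, kL)),
            "alpha": np.ones(kL),
            "psi": np.asarray(fix_variances[L.name], dtype=float).copy()
            if L.name in fix_variances else np.eye(kL) * 0.1,
            "fixed": L.name in fix_variances,
            "contrib": np.zeros((n, K)),
        }
        if L.name == collapse_level:
            idx_sorted = np.argsort(L.codes, kind="stable")
            offsets = np.concatenate([[0], np.cumsum(counts.astype(int))])
            pos = np.empty(n, dtype=int)
            pos[idx_sorted] = np.arange(n) - np.repeat(
                offsets[:-1], counts.astype(int))
            st["round_idx"] = pos
        lev_state.append(st)

    nongauss = [k for k, t in enumerate(traits) if t.family != "gaussian"]
    step = {k: 0.8 for k in nongauss}
    acc_n = {k: 0 for k in nongauss}
    acc_d = {k: 0 for k in nongauss}

    n_store = (n_iter - warmup) // thin
    out_beta = np.empty((n_store, P))
    out_levels = {L.name: np.empty((n_store, len(L.trait_idx), len(L.trait_idx)))
                  for L in levels}
    out_res = np.empty((n_store, K, K))

    beta_prior_prec = np.eye(P) / priors.beta_variance
    alpha_prior_prec = 1.0 / priors.px_alpha_variance

    s_idx = 0
    for it in range(n_iter):
        # ---- fixed effects ----
        r0 = latent - total_random
        s0 = r0 @ W
        A = np.empty((P, P))
        b = np.empty(P)
        for k in range(K):
            b[offs[k]:offs[k + 1]] = X_list[k].T @ s0[:, k]
            for j in range(K):
                A[offs[k]:offs[k + 1], offs[j]:offs[j + 1]] = W[k, j] * C[k][j]
        flat = _chol_sample(A + beta_prior_prec, b, rng)
        for k in range(K):
            beta[k] = flat[offs[k]:offs[k + 1]]
        fixed = np.column_stack([X_list[k] @ beta[k] for k in range(K)])

        # ---- random levels ----
        for st in lev_state:
            L: LevelDef = st["def"]
            S = L.trait_idx
            kL = len(S)
            r_tilde = latent - fixed - (total_random - st["contrib"])
            s = r_tilde @ W
            t_sum = np.zeros((L.n_groups, kL))
            np.add.at(t_sum, L.codes, s[:, S])

            W_SS = W[np.ix_(S, S)]
            psi_inv = np.linalg.inv(st["psi"])
            a = st["alpha"]
            M0 = np.outer(a, a) * W_SS
            prec = st["counts"][:, None, None] * M0 + psi_inv
            cov = np.linalg.inv(prec)
            lin = a * t_sum
            mean = np.einsum("jab,jb->ja", cov, lin)
            Lc = np.linalg.cholesky(cov)
            st["u"] = mean + np.einsum("jab,jb->ja", Lc,
                                       rng.standard_normal((L.n_groups, kL)))

            if L.px and not st["fixed"]:
                G = st["u"][L.codes]
                A_a = (G.T @ G) * W_SS + np.eye(kL) * alpha_prior_prec
                b_a = (G * s[:, S]).sum(axis=0) + priors.px_alpha_mean * alpha_prior_prec
                st["alpha"] = _chol_sample(A_a, b_a, rng)

            new_contrib = np.zeros((n, K))
            new_contrib[:, S] = (st["u"] * st["alpha"])[L.codes]
            total_random += new_contrib - st["contrib"]
            st["contrib"] = new_contrib

            if not st["fixed"]:
                scale = priors.px_psi_scale * np.eye(kL) + st["u"].T @ st["u"]
                st["psi"] = np.atleast_2d(invwishart.rvs(
                    df=kL + L.n_groups, scale=scale, random_state=rng))

        # ---- residual covariance ----
        if "residual" not in fix_variances:
            E = latent - fixed - total_random
            v_post = V0 + E.T @ E
            nu_post = nu0 + n
            if fixed_res_idx.size:
                fixed_block = np.diag([traits[k].fix_residual_var for k in fixed_res_idx])
                sigma_res = sample_conditional_invwishart(
                    nu_post, v_post, fixed_res_idx, fixed_block, rng)
            else:
                sigma_res = np.atleast_2d(invwishart.rvs(
                    df=nu_post, scale=v_post, random_state=rng))
            W = np.linalg.inv(sigma_res)

        # ---- latent residuals of non-Gaussian traits ----
        for k in nongauss:
            trait = traits[k]
            eta_k = fixed[:, k] + total_random[:, k]
            E = latent - fixed - total_random
            other = [j for j in range(K) if j != k]
            if other:
                w_vec = np.linalg.solve(sigma_res[np.ix_(other, other)],
                                        sigma_res[other, k])
                mu_c = E[:, other] @ w_vec
                v_c = sigma_res[k, k] - sigma_res[k, other] @ w_vec
            else:
                mu_c = np.zeros(n)
                v_c = sigma_res[k, k]
            v_c = max(v_c, 1e-12)
            if trait.family == "binary" and trait.link == "probit":
                coll = next((st for st in lev_state
                             if st["def"].name == collapse_level
                             and k in st["def"].trait_idx), None)
                if coll is not None:
                    kk = list(coll["def"].trait_idx).index(k)
                    _collapsed_probit_update(coll, k, kk, y, latent, fixed,
                                             total_random, mu_c, v_c, rng)
                    continue
                # exact truncated-normal conditional (threshold augmentation):
                # y = 1 iff eta + e > 0, e | rest ~ N(mu_c, v_c)
                sd = math.sqrt(v_c)
                a = ndtr((-eta_k - mu_c) / sd)      # P(e < -eta | rest)
                u = rng.random(n)
                u = np.where(y[:, k] > 0.5, a + u * (1.0 - a), u * a)
                u = np.clip(u, 1e-12, 1.0 - 1e-12)
                latent[:, k] = eta_k + mu_c + sd * ndtri(u)
                continue
            e_cur = latent[:, k] - eta_k
            e_prop = e_cur + step[k] * rng.standard_normal(n)
            ll_cur = _obs_loglik(trait, y[:, k], eta_k + e_cur)
            ll_prop = _obs_loglik(trait, y[:, k], eta_k + e_prop)
            log_acc = (ll_prop - ll_cur
                       - (e_prop - mu_c) ** 2 / (2 * v_c)
                       + (e_cur - mu_c) ** 2 / (2 * v_c))
            accept = np.log(rng.random(n)) < log_acc
            e_cur = np.where(accept, e_prop, e_cur)
            latent[:, k] = eta_k + e_cur
            rate = accept.mean()
            if it < warmup:
                step[k] = float(np.clip(
                    step[k] * np.exp((rate - 0.44) / (1 + it / 50.0) ** 0.6),
                    1e-3, 50.0))
            else:
                acc_n[k] += int(accept.sum())
                acc_d[k] += n

        # ---- interweaving shift for non-Gaussian traits ----
        # For a non-Gaussian trait the latent value, not the residual, is the
        # sufficient quantity: translating a group's working effect by d while
        # shifting its records' latent residuals by -alpha*d leaves every
        # likelihood term unchanged, so d has an exact Gaussian conditional
        # (prior of the working effect x residual density).  This breaks the
        # strong anticorrelation between group effects and latent residuals
        # that otherwise makes the binary/count variance components mix slowly.
        for st in lev_state:
            L = st["def"]
            S = list(L.trait_idx)
            for k in nongauss:
                if k not in S:
                    continue
                kk = S.index(k)
                kL = len(S)
                psi = st["psi"]
                if kL == 1:
                    m_u = np.zeros(L.n_groups)
                    s2_u = psi[0, 0]
                else:
                    oth = [a for a in range(kL) if a != kk]
                    w_u = np.linalg.solve(psi[np.ix_(oth, oth)], psi[oth, kk])
                    m_u = st["u"][:, oth] @ w_u
                    s2_u = psi[kk, kk] - psi[kk, oth] @ w_u
                s2_u = max(s2_u, 1e-12)
                other = [j for j in range(K) if j != k]
                E = latent - fixed - total_random
                if other:
                    w_vec = np.linalg.solve(sigma_res[np.ix_(other, other)],
                                            sigma_res[other, k])
                    mu_c = E[:, other] @ w_vec
                    v_c = sigma_res[k, k] - sigma_res[k, other] @ w_vec
                else:
                    mu_c = np.zeros(n)
                    v_c = sigma_res[k, k]
                v_c = max(v_c, 1e-12)
                a_k = st["alpha"][kk]
                t_j = np.zeros(L.n_groups)
                np.add.at(t_j, L.codes, E[:, k] - mu_c)
                prec = 1.0 / s2_u + st["counts"] * a_k ** 2 / v_c
                lin = (m_u - st["u"][:, kk]) / s2_u + a_k * t_j / v_c
                d = lin / prec + rng.standard_normal(L.n_groups) / np.sqrt(prec)
                st["u"][:, kk] += d
                shift = np.zeros((n, K))
                shift[:, k] = a_k * d[L.codes]
                total_random += shift
                st["contrib"] = st["contrib"] + shift

        # ---- store ----
        if it >= warmup and (it - warmup) % thin == thin - 1:
            out_beta[s_idx] = np.concatenate(beta)
            for st in lev_state:
                a = st["alpha"]
                out_levels[st["def"].name][s_idx] = np.outer(a, a) * st["psi"]
            out_res[s_idx] = sigma_res
            s_idx += 1

    assert s_idx == n_store
    return {
        "beta": out_beta,
        "levels": out_levels,
        "residual": out_res,
        "accept": {traits[k].name: (acc_n[k] / acc_d[k] if acc_d[k] else float("nan"))
                   for k in nongauss},
        "mh_steps": {traits[k].name: step[k] for k in nongauss},
        "n_store": n_store,
    }
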