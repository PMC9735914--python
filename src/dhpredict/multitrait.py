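"""Bayesian multi-trait genomic mixed models fitted by Gibbs sampling.

The model is the standard multi-trait animal model

    Y = 1 b' + U + E,   vec(U) ~ N(0, G0 (x) K),   rows of E iid N(0, R0)

over an n x t matrix of line-level phenotypes Y (traits may equally be
trait-x-environment or trait-x-population combinations). Selectable
covariance structures:

* genetic G0: ``D`` (diagonal), ``UN`` (unstructured, inverse-Wishart
  updates) or ``FA(k)`` (factor-analytic: G0 = Lambda Lambda' + diag(psi));
* residual R0: ``D`` or ``UN``.

Missing cells (and cells masked for cross-validation) are handled by data
augmentation — they are sampled from their conditional normal each sweep —
so held-out-cell prediction is a by-product of fitting.

Computation: one eigendecomposition of K diagonalizes the line dimension;
a generalized eigendecomposition of (G0, R0) diagonalizes the trait
dimension each sweep, so the genetic-effect update is a fully vectorized
n x t scalar draw.

:func:`fit_factor_model` is a separate high-dimensional sampler for many
traits: Y = 1 mu' + F Lambda' + Ug + E with per-factor genetic fractions on
a discrete grid and a multiplicative-gamma (column-ordered, increasing)
shrinkage prior on the loadings. It is a deliberately simplified
factor-analytic regression of the MegaLMM kind: qualitative behavior, not a
re-implementation of that package's priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CovStructureSpec",
    "MultiTraitFit",
    "FactorModelFit",
    "fit_multitrait",
    "fit_bivariate_dh_hap",
    "fit_factor_model",
    "predict_masked",
]


@dataclass
class CovStructureSpec:
    """Genetic/residual covariance structure choice, e.g. UN-UN or FA(2)-D."""

    genetic: str = "UN"
    residual: str = "UN"
    k: int = 1

    def __post_init__(self):
        if self.genetic not in ("D", "UN", "FA"):
            raise ValueError("genetic structure must be D, UN or FA")
        if self.residual not in ("D", "UN"):
            raise ValueError("residual structure must be D or UN")
        if self.genetic == "FA" and self.k < 1:
            raise ValueError("FA requires k >= 1")

    @classmethod
    def parse(cls, s: str) -> "CovStructureSpec":
        g, r = s.upper().split("-")
        k = 1
        if g.startswith("FA"):
            if "(" in g:
                k = int(g[g.index("(") + 1 : g.index(")")])
            g = "FA"
        return cls(genetic=g, residual=r, k=k)

    def __str__(self):
        g = f"FA({self.k})" if self.genetic == "FA" else self.genetic
        return f"{g}-{self.residual}"


@dataclass
class MultiTraitFit:
    B_hat: np.ndarray
    U_hat: pd.DataFrame
    G0_hat: np.ndarray
    R0_hat: np.ndarray
    G0_samples: np.ndarray
    R0_samples: np.ndarray
    predictions: pd.DataFrame  # posterior mean of 1 b' + U (all cells)
    missing: np.ndarray  # cells that were augmented (NaN or masked)
    line_ids: list
    trait_names: list
    spec: CovStructureSpec
    _refit: object = field(default=None, repr=False)


def _chol_psd(M):
    w, Q = np.linalg.eigh(np.asarray(M, dtype=float))
    return Q * np.sqrt(np.clip(w, 0.0, None))


def _pattern_groups(missing):
    """Group row indices by identical missing patterns (excluding complete rows)."""
    groups = []
    pats, inv = np.unique(missing, axis=0, return_inverse=True)
    for p in range(pats.shape[0]):
        if pats[p].any():
            groups.append((pats[p], np.where(inv == p)[0]))
    return groups


def _augment_missing(Yc, Mu, R0, groups, rng):
    """Sample augmented values for missing cells row-block-wise."""
    for pat, rows in groups:
        mis = np.where(pat)[0]
        obs = np.where(~pat)[0]
        mu_m = Mu[np.ix_(rows, mis)]
        if obs.size == 0:
            L = _chol_psd(R0[np.ix_(mis, mis)])
            Yc[np.ix_(rows, mis)] = mu_m + rng.standard_normal((rows.size, mis.size)) @ L.T
            continue
        Roo = R0[np.ix_(obs, obs)]
        Rmo = R0[np.ix_(mis, obs)]
        A = np.linalg.solve(Roo, Rmo.T).T
        cond_cov = R0[np.ix_(mis, mis)] - A @ Rmo.T
        L = _chol_psd(cond_cov)
        resid_o = Yc[np.ix_(rows, obs)] - Mu[np.ix_(rows, obs)]
        Yc[np.ix_(rows, mis)] = (
            mu_m + resid_o @ A.T + rng.standard_normal((rows.size, mis.size)) @ L.T
        )


def _scaled_invchi2(rng, df, scale_sum):
    return scale_sum / rng.chisquare(df)


def _invwishart_rvs(df, S, rng):
    """One inverse-Wishart(df, S) draw via the Bartlett decomposition.

    Equivalent to scipy.stats.invwishart.rvs but without its per-call
    overhead, which dominates short-chain fits on small trait counts.
    """
    t = S.shape[0]
    L = np.linalg.cholesky(S)
    T = np.zeros((t, t))
    T[np.diag_indices(t)] = np.sqrt(rng.chisquare(df - np.arange(t)))
    if t > 1:
        T[np.tril_indices(t, -1)] = rng.standard_normal(t * (t - 1) // 2)
    M = np.linalg.solve(L.T, T)  # M M' ~ Wishart(df, S^{-1})
    W = M @ M.T
    X = np.linalg.inv(W)
    return (X + X.T) / 2.0


def fit_multitrait(
    Y,
    K,
    spec: CovStructureSpec | str = "UN-UN",
    burn_in: int = 5000,
    n_iter: int = 20000,
    thin: int = 5,
    seed: int = 0,
    line_ids=None,
    trait_names=None,
    mask=None,
) -> MultiTraitFit:
    """Gibbs sampler for the multi-trait genomic mixed model.

    Parameters
    ----------
    Y
        n x t phenotype matrix (NaN = missing) or DataFrame (index = lines).
    K
        n x n genomic relationship matrix (or GRM object).
    spec
        Covariance structure, e.g. ``"UN-UN"``, ``"D-D"``, ``"FA(2)-D"``.
    mask
        Optional boolean n x t matrix; True cells are treated as missing
        regardless of their observed values (cross-validation masking).

    Priors (weakly informative): inverse-Wishart(t + 2, 0.5 * diag(var(Y)))
    for UN blocks, scaled-inv-chi2(df = 5, mode ~ half the trait variance)
    for diagonal variances, flat on the intercept.
    """
    if isinstance(spec, str):
        spec = CovStructureSpec.parse(spec)
    if isinstance(Y, pd.DataFrame):
        if line_ids is None:
            line_ids = list(Y.index)
        if trait_names is None:
            trait_names = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    Y = np.array(Y, dtype=float)
    n, t = Y.shape
    if t < 2:
        raise ValueError("need >= 2 traits; use fit_gblup for a single trait")
    if spec.genetic == "FA" and spec.k >= t:
        raise ValueError("FA requires k < number of traits")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if hasattr(K, "matrix"):
        if line_ids is None:
            line_ids = list(K.line_ids)
        K = K.matrix
    K = np.asarray(K, dtype=float)
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n)]
    if trait_names is None:
        trait_names = [f"T{j + 1}" for j in range(t)]

    missing = ~np.isfinite(Y)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        missing = missing | mask
    if (np.sum(~missing, axis=0) < 3).any():
        raise ValueError("every trait must be observed on >= 3 lines")

    rng = substream(seed, "multitrait")
    d, Q = np.linalg.eigh(K)
    d = np.maximum(d, 1e-8)

    col_var = np.nanvar(np.where(missing, np.nan, Y), axis=0)
    col_var = np.where(col_var > 0, col_var, 1.0)
    col_mean = np.nanmean(np.where(missing, np.nan, Y), axis=0)
    Yc = Y.copy()
    Yc[missing] = np.broadcast_to(col_mean, Y.shape)[missing]

    # priors
    nu0 = t + 2.0
    S0 = 0.5 * np.diag(col_var)
    df0 = 5.0
    s0 = 0.5 * col_var * (df0 - 2.0) / df0  # scaled-inv-chi2 scale (mean 0.5 var)

    b = col_mean.copy()
    U = np.zeros((n, t))
    G0 = 0.5 * np.diag(col_var)
    R0 = 0.5 * np.diag(col_var)
    if spec.genetic == "FA":
        k = spec.k
        Lam = 0.1 * rng.standard_normal((t, k))
        psi_g = 0.5 * col_var
        Ft = np.zeros((n, k))
        # idiosyncratic genetic variance: small prior scale — the factors are
        # expected to absorb shared genetic structure
        s0_fa = 0.1 * col_var * (df0 - 2.0) / df0

    groups = _pattern_groups(missing)
    n_keep = (n_iter - burn_in) // thin
    G0_samples = np.empty((n_keep, t, t))
    R0_samples = np.empty((n_keep, t, t))
    U_sum = np.zeros((n, t))
    b_sum = np.zeros(t)
    pred_sum = np.zeros((n, t))
    kept = 0

    inv_d = 1.0 / d

    for it in range(n_iter):
        # --- intercept (flat prior)
        M = Yc - U
        Lr0 = np.linalg.cholesky(R0 + 1e-10 * np.eye(t))
        b = M.mean(axis=0) + (Lr0 / np.sqrt(n)) @ rng.standard_normal(t)

        # --- genetic effects: diagonalize traits via (G0, R0)
        M = Yc - b
        Mt = Q.T @ M
        Lr = Lr0
        Lr_inv = np.linalg.inv(Lr)
        A = Lr_inv @ G0 @ Lr_inv.T
        phi, S = np.linalg.eigh((A + A.T) / 2.0)
        phi = np.clip(phi, 1e-12, None)
        P = Lr @ S
        P_inv = S.T @ Lr_inv
        Mo = Mt @ P_inv.T
        dphi = np.outer(d, phi)
        v = dphi / (1.0 + dphi)
        Uo = v * Mo + np.sqrt(v) * rng.standard_normal((n, t))
        Ut = Uo @ P.T
        U = Q @ Ut

        # --- genetic covariance
        if spec.genetic == "UN":
            scale = S0 + Ut.T @ (Ut * inv_d[:, None])
            G0 = _invwishart_rvs(nu0 + n, scale, rng)
        elif spec.genetic == "D":
            ss = np.sum(Ut * Ut * inv_d[:, None], axis=0)
            G0 = np.diag(
                [_scaled_invchi2(rng, df0 + n, df0 * s0[j] + ss[j]) for j in range(t)]
            )
        else:  # FA
            # factor scores given U (rotated space): mean free of d_i
            Pg = Lam.T @ (Lam / psi_g[:, None]) + np.eye(k)
            Pg_chol = np.linalg.cholesky(Pg)
            rhs = Ut @ (Lam / psi_g[:, None])
            mean_F = np.linalg.solve(Pg, rhs.T).T
            z = rng.standard_normal((n, k))
            noise = np.linalg.solve(Pg_chol.T, z.T).T * np.sqrt(d)[:, None]
            Ft = mean_F + noise
            # loadings row-wise (prior N(0, 1))
            FtW = Ft * inv_d[:, None]
            G_f = Ft.T @ FtW
            for j in range(t):
                prec = G_f / psi_g[j] + np.eye(k)
                mu_l = np.linalg.solve(prec, FtW.T @ Ut[:, j] / psi_g[j])
                Lc = np.linalg.cholesky(prec)
                Lam[j] = mu_l + np.linalg.solve(Lc.T, rng.standard_normal(k))
            resid = Ut - Ft @ Lam.T
            ssg = np.sum(resid * resid * inv_d[:, None], axis=0)
            psi_g = np.array(
                [_scaled_invchi2(rng, df0 + n, df0 * s0_fa[j] + ssg[j]) for j in range(t)]
            )
            G0 = Lam @ Lam.T + np.diag(psi_g)

        # --- residual covariance
        E = Yc - b - U
        if spec.residual == "UN":
            scale = S0 + E.T @ E
            R0 = _invwishart_rvs(nu0 + n, scale, rng)
        else:
            ss = np.sum(E * E, axis=0)
            R0 = np.diag(
                [_scaled_invchi2(rng, df0 + n, df0 * s0[j] + ss[j]) for j in range(t)]
            )

        # --- data augmentation for missing / masked cells
        Mu = b + U
        if groups:
            _augment_missing(Yc, Mu, R0, groups, rng)

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            G0_samples[kept] = G0
            R0_samples[kept] = R0
            U_sum += U
            b_sum += b
            pred_sum += Mu
            kept += 1

    U_hat = U_sum / kept
    b_hat = b_sum / kept
    fit = MultiTraitFit(
        B_hat=b_hat,
        U_hat=pd.DataFrame(U_hat, index=line_ids, columns=trait_names),
        G0_hat=G0_samples[:kept].mean(axis=0),
        R0_hat=R0_samples[:kept].mean(axis=0),
        G0_samples=G0_samples[:kept],
        R0_samples=R0_samples[:kept],
        predictions=pd.DataFrame(pred_sum / kept, index=line_ids, columns=trait_names),
        missing=missing,
        line_ids=list(line_ids),
        trait_names=list(trait_names),
        spec=spec,
    )
    fit._refit = lambda new_mask: fit_multitrait(
        Y, K, spec, burn_in, n_iter, thin, seed,
        line_ids=line_ids, trait_names=trait_names, mask=new_mask,
    )
    return fit


# ---------------------------------------------------------------------------
# bivariate DH / haploid model
# ---------------------------------------------------------------------------

@dataclass
class BivariateDHHapResult:
    fit: MultiTraitFit
    var_comps: "object"  # gencor.VarCompPair
    rG: float
    rP: float


def fit_bivariate_dh_hap(
    y_D,
    y_H,
    K,
    burn_in: int = 5000,
    n_iter: int = 20000,
    thin: int = 5,
    seed: int = 0,
    line_ids=None,
) -> BivariateDHHapResult:
    """Bivariate genomic model of one trait in the DH and haploid populations.

    The DH and haploid phenotypes of the same genotypes are modeled as two
    correlated traits sharing K; the 2 x 2 genetic and residual covariance
    matrices are unstructured. Missing values are median-substituted before
    fitting so every genotype contributes a complete pair; the genetic and
    phenotypic correlations are computed from the posterior-mean covariance
    components (plug-in).
    """
    from .gencor import VarCompPair, genetic_correlation, phenotypic_correlation

    y_D = np.asarray(y_D, dtype=float).copy()
    y_H = np.asarray(y_H, dtype=float).copy()
    n_complete = int(np.sum(np.isfinite(y_D) & np.isfinite(y_H)))
    if n_complete < 30:
        warnings.warn("fewer than 30 complete DH/haploid pairs: rG estimate unstable")
    for y in (y_D, y_H):
        med = np.nanmedian(y)
        y[~np.isfinite(y)] = med
    Y = np.column_stack([y_D, y_H])
    fit = fit_multitrait(
        Y, K, "UN-UN", burn_in, n_iter, thin, seed,
        line_ids=line_ids, trait_names=["DH", "HAP"],
    )
    G0, R0 = fit.G0_hat, fit.R0_hat
    vc = VarCompPair(
        sigma_G_DH=float(G0[0, 1]),
        sigma2_G_D=float(G0[0, 0]),
        sigma2_G_H=float(G0[1, 1]),
        sigma2_e_D=float(R0[0, 0]),
        sigma2_e_H=float(R0[1, 1]),
        sigma_e_DH=0.0,
    )
    return BivariateDHHapResult(
        fit=fit,
        var_comps=vc,
        rG=genetic_correlation(vc),
        rP=phenotypic_correlation(vc),
    )


# ---------------------------------------------------------------------------
# high-dimensional factor model
# ---------------------------------------------------------------------------

@dataclass
class FactorModelFit:
    mu: np.ndarray
    loadings: np.ndarray  # traits x k, posterior mean
    factor_h2: np.ndarray  # per-factor genetic fraction, posterior mean
    idio_genetic_var: np.ndarray  # per-trait sigma2_g of the trait-specific term
    idio_resid_var: np.ndarray  # per-trait psi_r
    G0_implied: np.ndarray
    R0_implied: np.ndarray
    predictions: pd.DataFrame  # posterior mean of mu + F Lambda' + Ug
    missing: np.ndarray
    line_ids: list
    trait_names: list
    k: int
    _refit: object = field(default=None, repr=False)


def fit_factor_model(
    Y,
    K,
    k: int = 8,
    burn_in: int = 2000,
    n_iter: int = 6000,
    thin: int = 5,
    seed: int = 0,
    line_ids=None,
    trait_names=None,
    mask=None,
    h2_grid=None,
) -> FactorModelFit:
    """Gibbs sampler for a sparse-factor multi-trait genomic model.

    Model: ``Y = 1 mu' + F Lambda' + Ug + E`` with k latent factors whose
    scores split into a K-correlated (genetic) and an iid part through a
    per-factor genetic fraction h_j sampled on a discrete grid; Ug is a
    trait-specific genetic effect (diagonal structure) and E has diagonal
    residual covariance. Loadings carry a multiplicative-gamma shrinkage
    prior whose precision increases with the factor index, so later factors
    are progressively shrunk toward zero and k acts as an upper bound on
    the effective rank.

    Implied covariances: G0 = Lambda diag(h) Lambda' + diag(sigma2_g),
    R0 = Lambda diag(1 - h) Lambda' + diag(psi_r).
    """
    if isinstance(Y, pd.DataFrame):
        if line_ids is None:
            line_ids = list(Y.index)
        if trait_names is None:
            trait_names = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    Y = np.array(Y, dtype=float)
    n, t = Y.shape
    if t < 4:
        raise ValueError("factor model needs >= 4 traits")
    if k > t:
        raise ValueError("k must not exceed the number of traits")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    if hasattr(K, "matrix"):
        if line_ids is None:
            line_ids = list(K.line_ids)
        K = K.matrix
    K = np.asarray(K, dtype=float)
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n)]
    if trait_names is None:
        trait_names = [f"T{j + 1}" for j in range(t)]
    if h2_grid is None:
        h2_grid = np.concatenate([np.arange(0.0, 1.0, 0.1), [0.99]])

    missing = ~np.isfinite(Y)
    if mask is not None:
        missing = missing | np.asarray(mask, dtype=bool)

    rng = substream(seed, "factor_model")
    d, Q = np.linalg.eigh(K)
    d = np.maximum(d, 1e-8)

    col_var = np.nanvar(np.where(missing, np.nan, Y), axis=0)
    col_var = np.where(col_var > 0, col_var, 1.0)
    col_mean = np.nanmean(np.where(missing, np.nan, Y), axis=0)
    Yc = Y.copy()
    Yc[missing] = np.broadcast_to(col_mean, Y.shape)[missing]

    df0 = 5.0
    s0r = 0.5 * col_var * (df0 - 2.0) / df0
    s0g = 0.2 * col_var * (df0 - 2.0) / df0

    mu = col_mean.copy()
    Lam = 0.1 * rng.standard_normal((t, k))
    F = np.zeros((n, k))
    h = np.full(k, 0.5)
    Ug = np.zeros((n, t))
    sig2g = 0.2 * col_var
    psi_r = 0.5 * col_var
    # multiplicative gamma process shrinkage state
    a1, a2, nu_local = 2.0, 3.0, 3.0
    delta = np.ones(k)
    phi_loc = np.ones((t, k))

    # precompute factor-prior variances in rotated space: s_ij = h_j d_i + 1 - h_j
    n_keep = (n_iter - burn_in) // thin
    kept = 0
    pred_sum = np.zeros((n, t))
    Lam_sum = np.zeros((t, k))
    h_sum = np.zeros(k)
    sig2g_sum = np.zeros(t)
    psi_sum = np.zeros(t)
    mu_sum = np.zeros(t)
    G0_sum = np.zeros((t, t))
    R0_sum = np.zeros((t, t))

    for it in range(n_iter):
        tau = np.cumprod(delta)

        # --- factor scores (rotated rows)
        M = Yc - mu - Ug
        Mt = Q.T @ M
        s = np.outer(d, h) + (1.0 - h)  # n x k prior variances
        Apart = Lam.T @ (Lam / psi_r[:, None])  # k x k
        Pmat = np.broadcast_to(Apart, (n, k, k)).copy()
        Pmat[:, np.arange(k), np.arange(k)] += 1.0 / s
        rhs = Mt @ (Lam / psi_r[:, None])  # n x k
        Lchol = np.linalg.cholesky(Pmat)
        mean_F = np.linalg.solve(Pmat, rhs[:, :, None])[:, :, 0]
        z = rng.standard_normal((n, k, 1))
        noise = np.linalg.solve(np.transpose(Lchol, (0, 2, 1)), z)[:, :, 0]
        Ft = mean_F + noise
        F = Q @ Ft

        # --- per-factor genetic fraction on the grid
        f2 = Ft * Ft
        for j in range(k):
            sgrid = d[:, None] * h2_grid[None, :] + (1.0 - h2_grid)[None, :]
            ll = -0.5 * np.sum(np.log(sgrid) + f2[:, j : j + 1] / sgrid, axis=0)
            ll -= ll.max()
            w = np.exp(ll)
            h[j] = rng.choice(h2_grid, p=w / w.sum())

        # --- loadings with MGP shrinkage
        C = Yc - mu - Ug
        FtF = F.T @ F
        FtC = F.T @ C
        for j in range(t):
            prec = FtF / psi_r[j] + np.diag(phi_loc[j] * tau)
            mu_l = np.linalg.solve(prec, FtC[:, j] / psi_r[j])
            Lc = np.linalg.cholesky(prec)
            Lam[j] = mu_l + np.linalg.solve(Lc.T, rng.standard_normal(k))

        # --- shrinkage hyperparameters
        lam2 = Lam * Lam
        phi_loc = rng.gamma(
            (nu_local + 1.0) / 2.0, 2.0 / (nu_local + lam2 * tau), size=(t, k)
        )
        for hidx in range(k):
            shape = (a1 if hidx == 0 else a2) + 0.5 * t * (k - hidx)
            rate = 1.0
            for l in range(hidx, k):
                tl = np.prod(delta[:l + 1]) / delta[hidx]
                rate += 0.5 * tl * np.sum(phi_loc[:, l] * lam2[:, l])
            delta[hidx] = rng.gamma(shape, 1.0 / rate)

        # --- trait-specific genetic effects (rotated, diagonal)
        N = Yc - mu - F @ Lam.T
        Nt = Q.T @ N
        prior_v = np.outer(d, sig2g)
        v = 1.0 / (1.0 / np.maximum(prior_v, 1e-12) + 1.0 / psi_r)
        mean_u = v * (Nt / psi_r)
        Ugt = mean_u + np.sqrt(v) * rng.standard_normal((n, t))
        Ug = Q @ Ugt
        ssg = np.sum(Ugt * Ugt / d[:, None], axis=0)
        sig2g = np.array(
            [_scaled_invchi2(rng, df0 + n, df0 * s0g[j] + ssg[j]) for j in range(t)]
        )

        # --- residual variances
        E = Yc - mu - F @ Lam.T - Ug
        sse = np.sum(E * E, axis=0)
        psi_r = np.array(
            [_scaled_invchi2(rng, df0 + n, df0 * s0r[j] + sse[j]) for j in range(t)]
        )

        # --- intercept
        D2 = Yc - F @ Lam.T - Ug
        mu = D2.mean(axis=0) + rng.standard_normal(t) * np.sqrt(psi_r / n)

        # --- missing-cell augmentation (diagonal residual: independent)
        Mu = mu + F @ Lam.T + Ug
        if missing.any():
            noise = rng.standard_normal(Y.shape) * np.sqrt(psi_r)
            Yc[missing] = (Mu + noise)[missing]

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            pred_sum += Mu
            Lam_sum += Lam
            h_sum += h
            sig2g_sum += sig2g
            psi_sum += psi_r
            mu_sum += mu
            G0_sum += (Lam * h) @ Lam.T + np.diag(sig2g)
            R0_sum += (Lam * (1.0 - h)) @ Lam.T + np.diag(psi_r)
            kept += 1

    fit = FactorModelFit(
        mu=mu_sum / kept,
        loadings=Lam_sum / kept,
        factor_h2=h_sum / kept,
        idio_genetic_var=sig2g_sum / kept,
        idio_resid_var=psi_sum / kept,
        G0_implied=G0_sum / kept,
        R0_implied=R0_sum / kept,
        predictions=pd.DataFrame(pred_sum / kept, index=line_ids, columns=trait_names),
        missing=missing,
        line_ids=list(line_ids),
        trait_names=list(trait_names),
        k=k,
    )
    fit._refit = lambda new_mask: fit_factor_model(
        Y, K, k, burn_in, n_iter, thin, seed,
        line_ids=line_ids, trait_names=trait_names, mask=new_mask, h2_grid=h2_grid,
    )
    return fit


# ---------------------------------------------------------------------------
# masked-cell prediction
# ---------------------------------------------------------------------------

def predict_masked(fit, mask) -> pd.DataFrame:
    """Predictions for masked cells of a fitted multi-trait model.

    ``mask`` is a boolean lines x traits matrix (or DataFrame aligned to the
    fit) or an iterable of ``(line_id, trait)`` pairs. Cells that were
    observed during fitting trigger a refit with those cells masked, so the
    returned prediction never conditions on the cell's own observed value.
    """
    line_pos = {l: i for i, l in enumerate(fit.line_ids)}
    trait_pos = {t: j for j, t in enumerate(fit.trait_names)}
    n, t = len(fit.line_ids), len(fit.trait_names)
    M = np.zeros((n, t), dtype=bool)
    if isinstance(mask, pd.DataFrame):
        mask = [(l, c) for l in mask.index for c in mask.columns if mask.loc[l, c]]
    if isinstance(mask, np.ndarray):
        M = mask.astype(bool)
        if M.shape != (n, t):
            raise ValueError("mask shape mismatch")
    else:
        for l, tr in mask:
            if l not in line_pos:
                raise KeyError(f"unknown line {l!r}")
            if tr not in trait_pos:
                raise KeyError(f"unknown trait {tr!r}")
            M[line_pos[l], trait_pos[tr]] = True
    if not M.any():
        return pd.DataFrame(columns=["line_id", "trait", "prediction"])
    if (M & ~fit.missing).any():
        if fit._refit is None:
            raise ValueError("mask includes observed cells and the fit cannot refit")
        fit = fit._refit(M | fit.missing)
    rows = []
    pred = fit.predictions.to_numpy()
    for i, j in zip(*np.where(M)):
        rows.append((fit.line_ids[i], fit.trait_names[j], pred[i, j]))
    return pd.DataFrame(rows, columns=["line_id", "trait", "prediction"])
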