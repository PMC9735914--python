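"""CV2 cross-validation, prediction-accuracy estimators and model comparison.

CV2 masking: test genotypes are observed for some traits (or environments)
and masked for others, so multi-trait models can borrow the observed
columns when predicting the masked ones. Two schemes:

* ``single_env_50_50`` — per repeat, a random half of lines has all focal
  traits masked; secondary traits stay fully observed.
* ``multi_env_20pct`` — per repeat and per environment, an independent 20%
  of lines is masked in that environment.

Accuracy metrics:

* ``accuracy_cor_y`` — Pearson cor(y, a_hat) over masked cells.
* ``accuracy_genetic`` — genetic accuracy for the trait-assisted setting,
  where focal and secondary traits share plot-level environment and plain
  Pearson correlation is biased: treat (y, a_hat) as two traits on the test
  lines, estimate their genetic correlation and the heritability of a_hat,
  and report cor_g(a_hat, y) * sqrt(h2_a_hat). The default route is a
  short-chain bivariate Gibbs fit; a faster REML route on the sum and
  difference of the standardized traits (cov_g = (sigma2_g(sum) -
  sigma2_g(diff)) / 4) is available but less stable on small test sets.

Model comparison uses the corrected resampled t-test: the paired t-test
across CV repeats with variance inflated by (1/J + n_test/n_train) to
account for overlapping training sets across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .lmm import fit_gblup

__all__ = [
    "CVPlan",
    "TTestResult",
    "make_cv2_single_env",
    "make_cv2_multi_env",
    "accuracy_cor_y",
    "accuracy_genetic",
    "corrected_resampled_ttest",
    "naive_resampled_ttest",
    "single_env_cv2_accuracy",
    "multi_env_cv2_accuracy",
    "compare_models",
]


@dataclass
class CVPlan:
    """Repeated CV2 masking plan.

    ``masks`` is a list (one per repeat) of boolean matrices over
    (lines x columns), where columns are the plan's ``columns`` (focal
    traits for the single-environment scheme, environments for the
    multi-environment scheme). True = masked for validation.
    """

    scheme: str
    line_ids: list
    columns: list
    masks: list
    seed: int
    fraction: float

    @property
    def repeats(self) -> int:
        return len(self.masks)

    def test_lines(self, repeat: int):
        """Line indices with any masked cell in this repeat."""
        return np.where(self.masks[repeat].any(axis=1))[0]


def make_cv2_single_env(
    line_ids, focal_traits, secondary_traits, J: int = 20, fraction: float = 0.5, seed: int = 0
) -> CVPlan:
    """CV2 plan for the trait-assisted single-environment scenario.

    Per repeat, a random fraction of lines has *all* focal-trait cells
    masked; secondary traits are never masked.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    focal = list(focal_traits)
    if set(focal) & set(secondary_traits):
        raise ValueError("focal and secondary trait sets must be disjoint")
    n = len(line_ids)
    n_test = int(n * fraction + 0.5)
    rng = substream(seed, "cv2_single")
    masks = []
    for _ in range(J):
        test = rng.choice(n, size=n_test, replace=False)
        m = np.zeros((n, len(focal)), dtype=bool)
        m[test, :] = True
        masks.append(m)
    return CVPlan(
        scheme="single_env_50_50",
        line_ids=list(line_ids),
        columns=focal,
        masks=masks,
        seed=seed,
        fraction=fraction,
    )


def make_cv2_multi_env(line_ids, envs, J: int = 20, fraction: float = 0.2, seed: int = 0) -> CVPlan:
    """CV2 plan masking an independent fraction of lines per environment."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(line_ids)
    envs = list(envs)
    n_test = int(n * fraction + 0.5)
    rng = substream(seed, "cv2_multi")
    masks = []
    for _ in range(J):
        m = np.zeros((n, len(envs)), dtype=bool)
        for e in range(len(envs)):
            m[rng.choice(n, size=n_test, replace=False), e] = True
        masks.append(m)
    return CVPlan(
        scheme="multi_env_20pct",
        line_ids=list(line_ids),
        columns=envs,
        masks=masks,
        seed=seed,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

def accuracy_cor_y(predictions, observed) -> float:
    """Pearson correlation between predictions and observations.

    Returns NaN (flagged, not raised) when either vector has zero variance.
    """
    a = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    ok = np.isfinite(a) & np.isfinite(y)
    a, y = a[ok], y[ok]
    if a.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(a) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(a, y)[0, 1])


def accuracy_genetic(
    predictions,
    observed,
    K_test,
    min_lines: int = 30,
    method: str = "gibbs",
    burn_in: int = 300,
    n_iter: int = 1200,
    seed: int = 0,
) -> float:
    """Genetic accuracy cor_g(a_hat, y) * sqrt(h2_a_hat) on the test lines.

    ``K_test`` is the relationship matrix over the test lines. Predictions
    and observations are standardized, a bivariate genomic model is fitted
    to the pair, and the accuracy is the plug-in genetic correlation times
    the square root of the prediction's heritability — algebraically, the
    correlation between the prediction and the true breeding value.

    ``method="gibbs"`` (default) fits the UN-UN bivariate Gibbs model;
    ``method="sumdiff"`` uses REML on the sum and difference of the two
    standardized traits, which is faster but markedly less stable on small
    test sets. Returns NaN when components degenerate.
    """
    u = np.asarray(predictions, dtype=float)
    y = np.asarray(observed, dtype=float)
    if hasattr(K_test, "matrix"):
        K_test = K_test.matrix
    K_test = np.asarray(K_test, dtype=float)
    ok = np.isfinite(u) & np.isfinite(y)
    if ok.sum() < min_lines:
        raise ValueError(f"need >= {min_lines} test lines for a stable genetic accuracy")
    u, y = u[ok], y[ok]
    Ks = K_test[np.ix_(np.where(ok)[0], np.where(ok)[0])]
    if np.std(u) == 0 or np.std(y) == 0:
        return float("nan")
    us = (u - u.mean()) / u.std()
    ys = (y - y.mean()) / y.std()
    if method == "gibbs":
        from .multitrait import fit_multitrait

        try:
            f = fit_multitrait(
                np.column_stack([us, ys]), Ks, "UN-UN",
                burn_in=burn_in, n_iter=n_iter, thin=3, seed=seed,
            )
        except Exception:
            return float("nan")
        G0, R0 = f.G0_hat, f.R0_hat
        sg_u, sg_y = G0[0, 0], G0[1, 1]
        if sg_u <= 1e-8 or sg_y <= 1e-8:
            return float("nan")
        cor_g = np.clip(G0[0, 1] / np.sqrt(sg_u * sg_y), -1.0, 1.0)
        h2_u = sg_u / (sg_u + R0[0, 0])
        return float(np.clip(cor_g * np.sqrt(h2_u), -1.0, 1.0))
    if method != "sumdiff":
        raise ValueError("method must be 'gibbs' or 'sumdiff'")
    try:
        f_u = fit_gblup(us, Ks, check_psd=False)
        f_y = fit_gblup(ys, Ks, check_psd=False)
        f_sum = fit_gblup(us + ys, Ks, check_psd=False)
        f_dif = fit_gblup(us - ys, Ks, check_psd=False)
    except Exception:
        return float("nan")
    sg_u, sg_y = f_u.sigma2_g, f_y.sigma2_g
    if sg_u <= 1e-8 or sg_y <= 1e-8:
        return float("nan")
    cov_g = (f_sum.sigma2_g - f_dif.sigma2_g) / 4.0
    cor_g = np.clip(cov_g / np.sqrt(sg_u * sg_y), -1.0, 1.0)
    return float(np.clip(cor_g * np.sqrt(f_u.h2), -1.0, 1.0))


# ---------------------------------------------------------------------------
# resampled t-tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    mean_diff: float
    var_diff: float
    J: int
    rho: float  # n_test / n_train
    t_stat: float
    p_value: float
    corrected: bool = True


def _resampled_ttest(diffs, rho) -> TTestResult:
    d = np.asarray(diffs, dtype=float)
    J = d.size
    if J < 2:
        raise ValueError("need >= 2 paired accuracy values")
    dbar = float(d.mean())
    s2 = float(d.var(ddof=1))
    if s2 == 0.0:
        if dbar == 0.0:
            return TTestResult(dbar, 0.0, J, rho, 0.0, 1.0, corrected=rho > 0)
        t = float("inf") if dbar > 0 else float("-inf")
        return TTestResult(dbar, 0.0, J, rho, t, 0.0, corrected=rho > 0)
    denom = np.sqrt((1.0 / J + rho) * s2)
    t = dbar / denom
    p = 2.0 * stats.t.sf(abs(t), df=J - 1)
    return TTestResult(dbar, s2, J, rho, float(t), float(p), corrected=rho > 0)


def corrected_resampled_ttest(acc_model_a, acc_model_b, n_train: int, n_test: int) -> TTestResult:
    """Corrected resampled t-test for paired CV accuracies.

    t = d_bar / sqrt((1/J + n_test/n_train) * s2_d), two-sided p from a t
    distribution with J - 1 df. The n_test/n_train term inflates the
    variance to account for the dependence induced by overlapping training
    sets across repeats.
    """
    a = np.asarray(acc_model_a, dtype=float)
    b = np.asarray(acc_model_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must have equal length")
    if n_train <= 0:
        raise ValueError("n_train must be positive")
    return _resampled_ttest(a - b, n_test / n_train)


def naive_resampled_ttest(acc_model_a, acc_model_b) -> TTestResult:
    """Uncorrected paired t-test across repeats (anti-conservative baseline)."""
    a = np.asarray(acc_model_a, dtype=float)
    b = np.asarray(acc_model_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("accuracy vectors must have equal length")
    res = _resampled_ttest(a - b, 0.0)
    res.corrected = False
    return res


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def single_env_cv2_accuracy(
    Y: pd.DataFrame,
    K,
    plan: CVPlan,
    models=("gblup", "factor"),
    metric: str = "genetic",
    env: str = "E1",
    factor_k: int = 4,
    chain=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the trait-assisted CV2 comparison in one environment.

    ``Y`` is a lines x traits DataFrame of line-level phenotypes containing
    both focal (``plan.columns``) and secondary traits. Univariate models
    see only the focal trait; the factor model sees all traits with the
    focal cells of test lines masked. Returns an accuracy table with one
    row per (model, trait, repeat).
    """
    chain = chain or {}
    if hasattr(K, "matrix"):
        Kmat = K.matrix
    else:
        Kmat = np.asarray(K, dtype=float)
    lines = list(Y.index)
    focal = list(plan.columns)
    col_pos = {c: j for j, c in enumerate(Y.columns)}
    rows = []
    for rep, m in enumerate(plan.masks):
        test_idx = plan.test_lines(rep)
        full_mask = np.zeros(Y.shape, dtype=bool)
        for j, c in enumerate(focal):
            full_mask[:, col_pos[c]] = m[:, j]
        K_test = Kmat[np.ix_(test_idx, test_idx)]

        fits = {}
        if "factor" in models:
            from .multitrait import fit_factor_model

            fits["factor"] = fit_factor_model(
                Y, Kmat, k=factor_k, mask=full_mask, seed=seed * 1000 + rep,
                line_ids=lines, trait_names=list(Y.columns), **chain,
            )
        for j, c in enumerate(focal):
            y_all = Y[c].to_numpy(dtype=float)
            y_obs_test = y_all[test_idx]
            y_train = y_all.copy()
            y_train[m[:, j]] = np.nan
            for model in models:
                if model == "gblup":
                    fit = fit_gblup(y_train, Kmat, check_psd=False)
                    pred = fit.u_hat.to_numpy()[test_idx]
                elif model == "bayesb":
                    raise NotImplementedError(
                        "BayesB in the CV2 runner requires a genotype matrix; "
                        "use fit_bayesb directly"
                    )
                elif model == "factor":
                    pred = fits["factor"].predictions[c].to_numpy()[test_idx]
                else:
                    raise ValueError(f"unknown model {model!r}")
                if metric == "genetic":
                    acc = accuracy_genetic(
                        pred, y_obs_test, K_test, seed=seed * 7919 + rep * 37 + j
                    )
                else:
                    acc = accuracy_cor_y(pred, y_obs_test)
                rows.append((model, c, env, rep, acc, f"{'genetic' if metric=='genetic' else 'cor_y_ahat'}"))
    return pd.DataFrame(rows, columns=["model", "trait", "env", "repeat", "accuracy", "metric"])


def multi_env_cv2_accuracy(
    Y_env: pd.DataFrame,
    K,
    plan: CVPlan,
    structures=("D-D", "UN-D", "UN-UN"),
    chain=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Multi-environment CV2: environments as traits, accuracy pooled.

    ``Y_env`` is lines x environments for a single trait. For every
    covariance structure the same plan masks are reused, and accuracy is
    Pearson cor(y, a_hat) over masked cells pooled across environments.
    """
    from .multitrait import fit_multitrait

    chain = chain or {}
    if hasattr(K, "matrix"):
        K = K.matrix
    rows = []
    for rep, m in enumerate(plan.masks):
        for struct in structures:
            fit = fit_multitrait(
                Y_env, K, struct, mask=m, seed=seed * 1000 + rep, **chain
            )
            pred = fit.predictions.to_numpy()[m]
            obs = Y_env.to_numpy()[m]
            rows.append((struct, "trait", "pooled", rep, accuracy_cor_y(pred, obs), "cor_y_ahat"))
    return pd.DataFrame(rows, columns=["model", "trait", "env", "repeat", "accuracy", "metric"])


def compare_models(acc_table: pd.DataFrame, model_a: str, model_b: str, n_train: int, n_test: int) -> pd.DataFrame:
    """Per-trait corrected resampled t-tests between two models."""
    rows = []
    for trait, grp in acc_table.groupby("trait"):
        a = grp[grp["model"] == model_a].sort_values("repeat")["accuracy"].to_numpy()
        b = grp[grp["model"] == model_b].sort_values("repeat")["accuracy"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            continue
        res = corrected_resampled_ttest(a[ok], b[ok], n_train, n_test)
        rows.append(
            {
                "trait": trait,
                "model_a": model_a,
                "model_b": model_b,
                "mean_diff": res.mean_diff,
                "t_stat": res.t_stat,
                "p_value": res.p_value,
                "J": res.J,
            }
        )
    return pd.DataFrame(rows)
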