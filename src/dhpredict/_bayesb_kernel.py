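"""Numba kernel for the BayesB Gibbs sampler.

Kept separate from :mod:`dhpredict.lmm` so the jit compilation cost is paid
only when BayesB is actually used. The sampler integrates the marker effect
out of the inclusion-indicator update (so the spike/slab move mixes without
Metropolis steps) and uses the residual-update trick: the running residual
always excludes the marker currently being updated.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["bayesb_gibbs"]


@njit(cache=True)
def bayesb_gibbs(y, X, burn_in, n_iter, pi, df_b, S_b, df_e, S_e, seed):
    np.random.seed(seed)
    n, m = X.shape
    b = np.zeros(m)
    s2 = np.full(m, df_b * S_b / max(df_b - 2.0, 1.0))
    mu = y.mean()
    resid = y - mu
    se2 = np.var(y) * 0.5 + 1e-12
    xx = np.empty(m)
    for j in range(m):
        xx[j] = np.dot(X[:, j], X[:, j])

    b_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    n_keep = n_iter - burn_in
    se2_chain = np.empty(n_keep)

    for it in range(n_iter):
        # intercept
        rbar = resid.mean() + mu
        mu_new = rbar + np.random.standard_normal() * np.sqrt(se2 / n)
        resid += mu - mu_new
        mu = mu_new

        for j in range(m):
            if b[j] != 0.0:
                for i in range(n):
                    resid[i] += X[i, j] * b[j]
            rhs = np.dot(X[:, j], resid)
            if xx[j] <= 0.0:
                b[j] = 0.0
                continue
            # marginal log Bayes factor for inclusion (effect integrated out)
            c = xx[j] + se2 / s2[j]
            log_bf = -0.5 * np.log(1.0 + xx[j] * s2[j] / se2) + 0.5 * rhs * rhs / (se2 * c)
            if pi <= 0.0:
                p1 = 1.0
            else:
                # odds = (1-pi)/pi * BF, guarded against overflow
                log_odds = np.log((1.0 - pi) / pi) + log_bf
                if log_odds > 35.0:
                    p1 = 1.0
                elif log_odds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p1:
                post_var = se2 / c
                b[j] = rhs / c + np.random.standard_normal() * np.sqrt(post_var)
                for i in range(n):
                    resid[i] -= X[i, j] * b[j]
                s2[j] = (df_b * S_b + b[j] * b[j]) / np.random.chisquare(df_b + 1.0)
                if it >= burn_in:
                    incl_sum[j] += 1.0
            else:
                b[j] = 0.0
                s2[j] = df_b * S_b / np.random.chisquare(df_b)

        sse = np.dot(resid, resid)
        se2 = (sse + df_e * S_e) / np.random.chisquare(n + df_e)

        if it >= burn_in:
            b_sum += b
            mu_sum += mu
            se2_chain[it - burn_in] = se2

    return b_sum / n_keep, incl_sum / n_keep, mu_sum / n_keep, se2_chain
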