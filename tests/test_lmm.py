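"""Univariate mixed models: plot model, GBLUP REML and BayesB."""

import numpy as np
import pandas as pd
import pytest

from dhpredict._rng import substream
from dhpredict.lmm import (
    fit_bayesb,
    fit_gblup,
    fit_plot_model,
    reml_profile_loglik,
)
from dhpredict.markers import compute_grm
from dhpredict.simpop import SimConfig, simulate_biparental_dh


def _balanced_records(y_by_line_block):
    rows = []
    for line, blocks in y_by_line_block.items():
        for b, v in enumerate(blocks, start=1):
            rows.append({"line_id": line, "block": b, "value": v})
    return pd.DataFrame(rows)


class TestPlotModel:
    def test_pure_noise_shrinks_to_zero(self):
        rng = substream(1, "noise")
        recs = _balanced_records(
            {f"L{i}": rng.normal(5.0, 1.0, 2) for i in range(80)}
        )
        fit = fit_plot_model(recs)
        assert fit.sigma2_G < 0.15
        assert np.abs(fit.blups).max() < 0.6

    def test_balanced_design_matches_closed_form_shrinkage(self):
        rng = substream(2, "bal")
        g = rng.normal(0, 1.0, 40)
        recs = _balanced_records(
            {f"L{i:02d}": g[i] + rng.normal(0, 0.8, 3) for i in range(40)}
        )
        fit = fit_plot_model(recs)
        df = recs.copy()
        r = 3
        ybar = df.groupby("line_id")["value"].mean()
        shrink = fit.sigma2_G / (fit.sigma2_G + fit.sigma2_e / r)
        expected = shrink * (ybar - ybar.mean())
        assert np.allclose(fit.blups.sort_index(), expected.sort_index(), atol=1e-8)

    def test_variance_ratio_recovery(self):
        # sigma2_G = sigma2_e = 1; median ratio estimate within 10%
        ratios = []
        for s in range(20):
            rng = substream(s, "vc")
            g = rng.normal(0, 1.0, 150)
            recs = _balanced_records(
                {f"L{i}": g[i] + rng.normal(0, 1.0, 2) for i in range(150)}
            )
            fit = fit_plot_model(recs)
            ratios.append(fit.sigma2_G / fit.sigma2_e)
        assert abs(np.median(ratios) - 1.0) < 0.10

    def test_single_block_rejected(self):
        recs = _balanced_records({"A": [1.0], "B": [2.0]})
        with pytest.raises(ValueError, match="block"):
            fit_plot_model(recs)


def _grid_reml_oracle(y, K, ngrid=120):
    """Dense 2-D grid search of the restricted likelihood (independent path)."""
    n = len(y)
    X = np.ones((n, 1))
    best, best_ll = None, -np.inf
    vy = np.var(y)
    for sg in np.linspace(1e-4, 4 * vy, ngrid):
        for se in np.linspace(1e-4, 4 * vy, ngrid):
            V = sg * K + se * np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            ll = -0.5 * (
                np.linalg.slogdet(V)[1]
                + np.linalg.slogdet(XtViX)[1]
                + float(r @ Vi @ r)
            )
            if ll > best_ll:
                best_ll, best = ll, (sg, se)
    return best


class TestGblup:
    def test_identity_K_matches_iid_closed_form(self):
        rng = substream(3, "iid")
        y = rng.normal(2.0, 1.0, 40)
        fit = fit_gblup(y, np.eye(40))
        shrink = fit.sigma2_g / (fit.sigma2_g + fit.sigma2_e)
        expected = shrink * (y - y.mean())
        assert fit.mu == pytest.approx(y.mean(), abs=1e-8)
        assert np.allclose(fit.u_hat.to_numpy(), expected, atol=1e-8)

    def test_six_line_toy_matches_grid_oracle(self):
        rng = substream(4, "toy")
        A = rng.normal(0, 1, (6, 8))
        K = A @ A.T / 8 + 0.5 * np.eye(6)
        y = np.linalg.cholesky(K) @ rng.normal(0, 1, 6) + rng.normal(0, 0.5, 6)
        fit = fit_gblup(y, K)
        assert fit.sigma2_g > 0
        sg, se = _grid_reml_oracle(y, K)
        assert fit.sigma2_g == pytest.approx(sg, rel=0.05, abs=0.02)
        assert fit.sigma2_e == pytest.approx(se, rel=0.05, abs=0.02)
        # likelihood at the fit is >= oracle grid maximum
        d, Q = np.linalg.eigh(K)
        ys, Xs = Q.T @ y, Q.T @ np.ones((6, 1))
        ll_fit = reml_profile_loglik(np.log(fit.sigma2_g / fit.sigma2_e), ys, Xs, d)[0]
        ll_grid = reml_profile_loglik(np.log(sg / se), ys, Xs, d)[0]
        assert ll_fit >= ll_grid - 1e-6

    def test_local_optimality_against_random_ratios(self, midsize_panel):
        _, _, grm = midsize_panel
        rng = substream(5, "opt")
        n = grm.matrix.shape[0]
        L = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(n))
        y = L @ rng.normal(0, 0.6, n) + rng.normal(0, 0.8, n)
        fit = fit_gblup(y, grm)
        d, Q = np.linalg.eigh(grm.matrix)
        d = np.clip(d, 0, None)
        ys, Xs = Q.T @ y, Q.T @ np.ones((n, 1))
        ll_opt = reml_profile_loglik(
            np.log(max(fit.sigma2_g, 1e-8) / fit.sigma2_e), ys, Xs, d
        )[0]
        for lg in rng.uniform(-8, 8, 100):
            assert ll_opt >= reml_profile_loglik(lg, ys, Xs, d)[0] - 1e-8

    def test_heritability_recovery(self, midsize_panel):
        _, _, grm = midsize_panel
        n = grm.matrix.shape[0]
        Kn = grm.matrix / grm.matrix.diagonal().mean()  # unit-diagonal scale
        L = np.linalg.cholesky(Kn + 1e-8 * np.eye(n))
        h2s = []
        for s in range(15):
            rng = substream(s, "h2")
            y = L @ rng.normal(0, np.sqrt(0.5), n) + rng.normal(0, np.sqrt(0.5), n)
            h2s.append(fit_gblup(y, Kn).h2)
        assert 0.4 < np.mean(h2s) < 0.6

    def test_line_permutation_invariance(self, small_panel):
        _, _, _, grm = small_panel
        rng = substream(6, "perm")
        n = grm.matrix.shape[0]
        y = rng.normal(0, 1, n)
        fit = fit_gblup(y, grm.matrix)
        perm = rng.permutation(n)
        fit_p = fit_gblup(y[perm], grm.matrix[np.ix_(perm, perm)])
        assert fit_p.h2 == pytest.approx(fit.h2, abs=1e-6)
        assert np.allclose(fit_p.u_hat.to_numpy(), fit.u_hat.to_numpy()[perm], atol=1e-6)

    def test_unphenotyped_lines_predicted(self, small_panel):
        _, _, _, grm = small_panel
        rng = substream(7, "miss")
        n = grm.matrix.shape[0]
        y = rng.normal(0, 1, n)
        y[:10] = np.nan
        fit = fit_gblup(y, grm)
        assert np.isfinite(fit.u_hat.to_numpy()).all()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="phenotyped"):
            fit_gblup(np.full(10, np.nan), np.eye(10))


class TestBayesB:
    def test_zero_variance_response(self):
        rng = substream(8, "flat")
        X = rng.integers(0, 3, (50, 30)).astype(float)
        fit = fit_bayesb(np.full(50, 3.0), X, burn_in=100, n_iter=400, seed=1)
        assert fit.mu == pytest.approx(3.0, abs=0.05)
        assert np.abs(fit.marker_effects).max() < 0.05

    def test_causal_marker_gets_top_inclusion(self):
        rng = substream(9, "qtl")
        n, m = 300, 201
        X = rng.integers(0, 2, (n, m)).astype(float) * 2
        beta = np.zeros(m)
        causal = 77
        g = X[:, causal] - X[:, causal].mean()
        g = g / g.std()
        y = g + rng.normal(0, 1.0, n)  # QTL explains 50% of variance
        fit = fit_bayesb(y, X, burn_in=300, n_iter=1200, seed=2)
        assert int(np.argmax(fit.inclusion_prob)) == causal

    def test_pi_zero_matches_all_markers_model(self, small_panel):
        _, geno, _, grm = small_panel
        rng = substream(10, "pi0")
        n = geno.n_lines
        Xc = geno.dosages - geno.dosages.mean(axis=0)
        beta = rng.normal(0, 0.1, geno.n_markers)
        y = Xc @ beta + rng.normal(0, 0.5, n)
        fit = fit_bayesb(y, geno.dosages, burn_in=300, n_iter=1200, pi=0.0, seed=3)
        pred_b = fit.predict(geno.dosages)
        pred_g = fit_gblup(y, grm).predictions.to_numpy()
        assert np.corrcoef(pred_b, pred_g)[0, 1] > 0.99

    def test_chain_length_validation(self):
        with pytest.raises(ValueError, match="n_iter"):
            fit_bayesb(np.zeros(10), np.zeros((10, 5)), burn_in=100, n_iter=100)


class TestBayesBvsGblupAccuracy:
    def test_sparse_and_polygenic_architectures(self, midsize_panel):
        """BayesB should not trail GBLUP by > 0.05 when the architecture is
        sparse, and the two should agree within 0.05 when polygenic."""
        _, geno, grm = midsize_panel
        n, m = geno.n_lines, geno.n_markers
        Xc = geno.dosages - geno.dosages.mean(axis=0)
        diffs = {"sparse": [], "polygenic": []}
        for s in range(6):
            rng = substream(s, "arch")
            for kind in ("sparse", "polygenic"):
                nq = 5 if kind == "sparse" else m
                beta = np.zeros(m)
                idx = rng.choice(m, nq, replace=False)
                beta[idx] = rng.normal(0, 1, nq)
                g = Xc @ beta
                g = (g - g.mean()) / g.std()
                y = g + rng.normal(0, 1, n)  # h2 = 0.5
                test = rng.choice(n, 50, replace=False)
                ytr = y.copy()
                ytr[test] = np.nan
                acc_g = np.corrcoef(
                    fit_gblup(ytr, grm).u_hat.to_numpy()[test], g[test]
                )[0, 1]
                fb = fit_bayesb(ytr, geno.dosages, burn_in=300, n_iter=1200, seed=s)
                obs = np.isfinite(ytr)
                fb_pred = fb.predict(geno.dosages)
                acc_b = np.corrcoef(fb_pred[test], g[test])[0, 1]
                diffs[kind].append(acc_b - acc_g)
        assert np.mean(diffs["sparse"]) > -0.05
        assert abs(np.mean(diffs["polygenic"])) < 0.05
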