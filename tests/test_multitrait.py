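"""Multi-trait Gibbs samplers: structure choices, recovery, prediction."""

import numpy as np
import pandas as pd
import pytest

from dhpredict._rng import substream
from dhpredict.lmm import fit_gblup
from dhpredict.multitrait import (
    CovStructureSpec,
    fit_bivariate_dh_hap,
    fit_factor_model,
    fit_multitrait,
    predict_masked,
)
from dhpredict.simpop import block_covariance, sample_breeding_values

CHAIN = dict(burn_in=400, n_iter=1600, thin=4)


def _simulate_Y(K, h2, rG, seed, n_blocks_resid=1):
    """Line-level phenotypes for len(h2) traits with genetic correlation rG."""
    t = len(h2)
    R = np.full((t, t), rG) + (1 - rG) * np.eye(t)
    G0, R0 = block_covariance(np.asarray(h2), R)
    rng = substream(seed, "mtsim")
    U = sample_breeding_values(K, G0, rng)
    E = rng.standard_normal((K.shape[0], t)) @ np.linalg.cholesky(R0 + 1e-12 * np.eye(t)).T
    return U + E, U


class TestCovStructureSpec:
    @pytest.mark.parametrize(
        "s,genetic,residual,k",
        [("UN-UN", "UN", "UN", 1), ("D-D", "D", "D", 1), ("FA(3)-D", "FA", "D", 3)],
    )
    def test_parse(self, s, genetic, residual, k):
        spec = CovStructureSpec.parse(s)
        assert (spec.genetic, spec.residual, spec.k) == (genetic, residual, k)

    def test_fa_needs_fewer_factors_than_traits(self, small_panel):
        _, _, _, grm = small_panel
        Y = np.zeros((grm.matrix.shape[0], 2))
        with pytest.raises(ValueError, match="FA"):
            fit_multitrait(Y, grm, "FA(2)-D", **CHAIN)


class TestFitMultitrait:
    def test_dd_matches_independent_gblup(self, midsize_panel):
        _, _, grm = midsize_panel
        K = grm.matrix
        Y, _ = _simulate_Y(K / 2, [0.5, 0.4], 0.0, seed=21)
        fit = fit_multitrait(Y, K, "D-D", seed=1, **CHAIN)
        for j in range(2):
            ug = fit_gblup(Y[:, j], K).u_hat.to_numpy()
            r = np.corrcoef(fit.U_hat.iloc[:, j], ug)[0, 1]
            assert r > 0.98

    def test_unun_recovers_genetic_correlation(self, midsize_panel):
        _, _, grm = midsize_panel
        K = grm.matrix / 2
        Y, _ = _simulate_Y(K, [0.5, 0.5], 0.7, seed=8)
        fit = fit_multitrait(Y, grm.matrix, "UN-UN", seed=2, **CHAIN)
        G = fit.G0_hat
        r = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
        assert abs(r - 0.7) < 0.15

    def test_un_shrinks_null_correlation(self, full_panel):
        # true diagonal G0: posterior off-diagonal correlation shrinks to 0
        _, _, grm = full_panel
        K = grm.matrix / 2
        rs = []
        for s in range(8):
            Y, _ = _simulate_Y(K, [0.5, 0.5], 0.0, seed=400 + s)
            fit = fit_multitrait(Y, grm.matrix, "UN-UN", seed=s, burn_in=300,
                                 n_iter=1200, thin=4)
            G = fit.G0_hat
            rs.append(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
        assert np.median(np.abs(rs)) < 0.2

    def test_fa_rank_one_recovery(self, full_panel):
        _, _, grm = full_panel
        K = grm.matrix / 2
        # rank-1 genetic covariance: all pairwise genetic correlations 1,
        # strongly heritable so the shared factor is well identified
        Y, _ = _simulate_Y(K, [0.8, 0.8, 0.8], 1.0, seed=78)
        fit = fit_multitrait(Y, grm.matrix, "FA(1)-D", seed=5, **CHAIN)
        G = fit.G0_hat
        r01 = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
        assert abs(r01 - 1.0) < 0.1

    def test_sampled_covariances_psd(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.5, seed=9)
        fit = fit_multitrait(Y, grm.matrix, "UN-UN", seed=6, **CHAIN)
        for M in np.concatenate([fit.G0_samples, fit.R0_samples]):
            assert np.linalg.eigvalsh(M).min() >= -1e-8
        assert np.linalg.eigvalsh(fit.G0_hat).min() >= -1e-8

    def test_seed_determinism_and_cross_seed_agreement(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.5, 0.5], 0.5, seed=10)
        f1 = fit_multitrait(Y, grm.matrix, "UN-UN", seed=7, **CHAIN)
        f2 = fit_multitrait(Y, grm.matrix, "UN-UN", seed=7, **CHAIN)
        assert np.array_equal(f1.G0_samples, f2.G0_samples)
        f3 = fit_multitrait(Y, grm.matrix, "UN-UN", seed=8, **CHAIN)
        # different seeds agree within combined MC error
        se = np.sqrt(
            f1.G0_samples.std(axis=0) ** 2 / f1.G0_samples.shape[0]
            + f3.G0_samples.std(axis=0) ** 2 / f3.G0_samples.shape[0]
        )
        assert np.all(np.abs(f1.G0_hat - f3.G0_hat) < 6 * se + 0.05)

    def test_trait_observation_minimum(self, small_panel):
        _, _, _, grm = small_panel
        n = grm.matrix.shape[0]
        Y = np.random.default_rng(0).normal(size=(n, 2))
        Y[2:, 1] = np.nan
        with pytest.raises(ValueError, match="observed"):
            fit_multitrait(Y, grm.matrix, "D-D", **CHAIN)


class TestBivariateDHHap:
    def test_duplicated_trait_gives_unit_correlation(self, full_panel):
        # identical DH and haploid phenotypes: rG approaches 1 (the weakly
        # informative covariance prior keeps the plug-in just below 1)
        _, _, grm = full_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.5], 0.0, seed=40)
        y = Y[:, 0]
        res = fit_bivariate_dh_hap(y, y.copy(), grm.matrix, seed=1, **CHAIN)
        assert res.rG > 0.95

    def test_independent_traits_near_zero(self, full_panel):
        _, _, grm = full_panel
        rs = []
        for s in range(10):
            Y, _ = _simulate_Y(grm.matrix / 2, [0.5, 0.5], 0.0, seed=45 + s)
            res = fit_bivariate_dh_hap(Y[:, 0], Y[:, 1], grm.matrix, seed=2 + s, **CHAIN)
            rs.append(res.rG)
        assert np.median(np.abs(rs)) < 0.15

    def test_equals_two_trait_multitrait_fit(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.6, seed=42)
        res = fit_bivariate_dh_hap(Y[:, 0], Y[:, 1], grm.matrix, seed=3, **CHAIN)
        direct = fit_multitrait(
            Y, grm.matrix, "UN-UN", seed=3, line_ids=None,
            trait_names=["DH", "HAP"], **CHAIN,
        )
        assert np.array_equal(res.fit.G0_hat, direct.G0_hat)

    def test_few_pairs_warns(self):
        K = np.eye(20)
        y = np.random.default_rng(1).normal(size=20)
        with pytest.warns(UserWarning, match="30"):
            fit_bivariate_dh_hap(y, y, K, burn_in=50, n_iter=200, seed=1)

    def test_median_generating_correlation_recovered(self, full_panel):
        # generating value 0.71: the reference-table median DH/haploid rG;
        # phenotypes follow the field design (2 replicate blocks, line means)
        from dhpredict.simpop import SimConfig, compound_labels, simulate_phenotypes

        _, _, grm = full_panel
        G0, R0 = block_covariance([0.4, 0.35], np.array([[1, 0.71], [0.71, 1]]))
        labels = compound_labels(["T"], ["E1"], ("DH", "HAP"))
        cfg = SimConfig(n_lines=187, n_blocks=2, G0=G0, R0=R0, seed=1)
        errs = []
        for s in range(10):
            ph = simulate_phenotypes(
                grm.matrix / 2, cfg, labels=labels, line_ids=grm.line_ids, seed=900 + s
            )
            Y = (
                ph.groupby(["population", "line_id"])["value"]
                .mean()
                .unstack(0)
                .loc[grm.line_ids]
            )
            res = fit_bivariate_dh_hap(
                Y["DH"].to_numpy(), Y["HAP"].to_numpy(), grm.matrix, seed=s, **CHAIN
            )
            errs.append(abs(res.rG - 0.71))
        assert np.median(errs) < 0.15


class TestFactorModel:
    def _two_factor_data(self, grm, seed=60, n_sec=8, n_foc=6):
        rng = substream(seed, "fa2")
        t = n_sec + n_foc
        L = np.zeros((t, 2))
        L[:n_sec, 0] = rng.uniform(0.5, 0.8, n_sec)
        L[n_sec:, 0] = rng.uniform(0.3, 0.5, n_foc)
        L[n_sec:, 1] = rng.uniform(0.4, 0.7, n_foc)
        Rg = L @ L.T + np.diag(rng.uniform(0.1, 0.3, t))
        dd = np.sqrt(np.diag(Rg))
        Rg = Rg / np.outer(dd, dd)
        h2 = np.concatenate([rng.uniform(0.3, 0.6, n_sec), rng.uniform(0.15, 0.4, n_foc)])
        G0, R0 = block_covariance(h2, Rg)
        n = grm.matrix.shape[0]
        U = sample_breeding_values(grm.matrix / 2, G0, rng)
        E = rng.standard_normal((n, t)) @ np.linalg.cholesky(R0 + 1e-12 * np.eye(t)).T
        cols = [f"S{j}" for j in range(n_sec)] + [f"F{j}" for j in range(n_foc)]
        return pd.DataFrame(U + E, index=grm.line_ids, columns=cols), n_sec

    def test_beats_traitwise_gblup_under_shared_structure(self, midsize_panel):
        _, _, grm = midsize_panel
        Y, n_sec = self._two_factor_data(grm)
        n, t = Y.shape
        rng = substream(61, "mask")
        test = rng.choice(n, n // 2, replace=False)
        mask = np.zeros((n, t), dtype=bool)
        mask[test, n_sec:] = True
        fit = fit_factor_model(Y, grm.matrix, k=4, mask=mask, seed=1, **CHAIN)
        gains = []
        for c in Y.columns[n_sec:]:
            j = list(Y.columns).index(c)
            yobs = Y[c].to_numpy()[test]
            ytr = Y[c].to_numpy().copy()
            ytr[mask[:, j]] = np.nan
            pg = fit_gblup(ytr, grm.matrix).u_hat.to_numpy()[test]
            pf = fit.predictions[c].to_numpy()[test]
            gains.append(
                np.corrcoef(pf, yobs)[0, 1] - np.corrcoef(pg, yobs)[0, 1]
            )
        assert np.mean(gains) > 0

    def test_no_shared_structure_collapses_to_traitwise(self, midsize_panel):
        _, _, grm = midsize_panel
        # independent traits: factor model cannot beat per-trait GBLUP by much
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4] * 6, 0.0, seed=62)
        Y = pd.DataFrame(Y, index=grm.line_ids, columns=[f"T{j}" for j in range(6)])
        n = len(Y)
        rng = substream(63, "mask0")
        test = rng.choice(n, n // 2, replace=False)
        mask = np.zeros(Y.shape, dtype=bool)
        mask[test, 3:] = True
        fit = fit_factor_model(Y, grm.matrix, k=3, mask=mask, seed=2, **CHAIN)
        diffs = []
        for j, c in enumerate(Y.columns[3:], start=3):
            yobs = Y[c].to_numpy()[test]
            ytr = Y[c].to_numpy().copy()
            ytr[mask[:, j]] = np.nan
            pg = fit_gblup(ytr, grm.matrix).u_hat.to_numpy()[test]
            pf = fit.predictions[c].to_numpy()[test]
            diffs.append(np.corrcoef(pf, yobs)[0, 1] - np.corrcoef(pg, yobs)[0, 1])
        assert abs(np.mean(diffs)) < 0.1

    def test_seeded_rerun_identical(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4] * 5, 0.5, seed=64)
        f1 = fit_factor_model(Y, grm.matrix, k=2, seed=5, **CHAIN)
        f2 = fit_factor_model(Y, grm.matrix, k=2, seed=5, **CHAIN)
        assert np.array_equal(
            f1.predictions.to_numpy(), f2.predictions.to_numpy()
        )

    def test_k_validation(self, small_panel):
        _, _, _, grm = small_panel
        Y = np.zeros((grm.matrix.shape[0], 4))
        with pytest.raises(ValueError, match="k"):
            fit_factor_model(Y, grm.matrix, k=5, **CHAIN)


class TestPredictMasked:
    def test_empty_mask(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.5, seed=70)
        fit = fit_multitrait(Y, grm.matrix, "D-D", seed=1, **CHAIN)
        out = predict_masked(fit, [])
        assert out.empty

    def test_masked_cells_match_posterior_mean_surface(self, small_panel):
        _, _, _, grm = small_panel
        n = grm.matrix.shape[0]
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.5, seed=71)
        mask = np.zeros((n, 2), dtype=bool)
        mask[:5, 0] = True
        fit = fit_multitrait(Y, grm.matrix, "UN-UN", seed=2, mask=mask, **CHAIN)
        out = predict_masked(fit, mask)
        expected = fit.predictions.to_numpy()[mask]
        assert np.allclose(out["prediction"].to_numpy(), expected)

    def test_refit_contract_ignores_observed_value(self, small_panel):
        _, _, _, grm = small_panel
        n = grm.matrix.shape[0]
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.5, seed=72)
        fit = fit_multitrait(Y, grm.matrix, "UN-UN", seed=3, **CHAIN)
        cell = (fit.line_ids[0], fit.trait_names[0])
        out = predict_masked(fit, [cell])
        # the prediction must come from a refit that masked the cell,
        # not from conditioning on its observed value
        assert out.iloc[0]["prediction"] != pytest.approx(Y[0, 0], abs=1e-12)
        assert out.iloc[0]["prediction"] != pytest.approx(
            fit.predictions.iloc[0, 0], abs=1e-12
        )

    def test_unknown_address_rejected(self, small_panel):
        _, _, _, grm = small_panel
        Y, _ = _simulate_Y(grm.matrix / 2, [0.4, 0.4], 0.5, seed=73)
        fit = fit_multitrait(Y, grm.matrix, "D-D", seed=4, **CHAIN)
        with pytest.raises(KeyError, match="unknown"):
            predict_masked(fit, [("nonexistent", fit.trait_names[0])])
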