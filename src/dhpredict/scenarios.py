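"""Synthetic study scenarios mirroring the maize DH trait-assisted design.

These builders assemble complete, self-contained study datasets for the
headline comparisons:

* :func:`trait_assisted_scenario` — a single-environment panel with
  easily-measured "agronomic-like" secondary traits (moderate heritability,
  h2 in [0.3, 0.6]) genetically correlated through a factor structure with
  hard-to-measure "stalk-like" focal traits (low heritability, h2 in
  [0.15, 0.4]); optionally haploid-derived copies of every trait at a
  chosen DH-haploid genetic correlation (default 0.7, the reference-table
  median).
* :func:`ttest_calibration` — repeated null studies with two exchangeable
  prediction models evaluated on overlapping cross-validation splits, used
  to measure type-I error of the corrected vs naive resampled t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import GRM
from .markers import compute_grm
from .simpop import SimConfig, block_covariance, simulate_biparental_dh

__all__ = ["TraitAssistedStudy", "trait_assisted_scenario", "ttest_calibration"]


@dataclass
class TraitAssistedStudy:
    Y: pd.DataFrame  # line-level phenotypes, all columns
    U: pd.DataFrame  # true breeding values (same layout)
    grm: GRM
    secondary: list  # secondary trait names (fully observed)
    focal: list  # focal trait names (masked on test lines)
    hap_traits: list  # haploid-derived secondary columns (may be empty)
    h2: pd.Series  # generating heritabilities per column


def trait_assisted_scenario(
    n_lines: int = 150,
    n_secondary: int = 8,
    n_focal: int = 12,
    with_haploids: bool = False,
    rg_dh_hap: float = 0.7,
    seed: int = 0,
    n_chrom: int = 5,
    markers_per_chrom: int = 50,
) -> TraitAssistedStudy:
    """Build a single-environment trait-assisted study on a fresh DH panel.

    Cross-trait genetic correlations come from a two-factor structure: a
    strong general factor loading on all traits and a focal-specific
    factor, calibrated so secondary-focal genetic correlations fall in
    [0.4, 0.8] — the moderate-to-strong range the trait-assisted design
    assumes. When ``with_haploids`` is set, each trait also gets a haploid
    counterpart whose breeding values correlate ``rg_dh_hap`` with the DH
    ones (the haploid genome is identical; the imperfect correlation
    emulates ploidy-driven expression differences).
    """
    cfg = SimConfig(
        n_lines=n_lines,
        chrom_lengths_cM=[150.0] * n_chrom,
        markers_per_chrom=[markers_per_chrom] * n_chrom,
        seed=seed,
    )
    geno, _ = simulate_biparental_dh(cfg)
    grm = compute_grm(geno)
    K = grm.matrix / grm.matrix.diagonal().mean()

    rng = substream(seed, "trait_assisted")
    t = n_secondary + n_focal
    L = np.zeros((t, 2))
    L[:n_secondary, 0] = rng.uniform(0.75, 0.9, n_secondary)
    L[n_secondary:, 0] = rng.uniform(0.45, 0.75, n_focal)
    L[n_secondary:, 1] = rng.uniform(0.3, 0.5, n_focal)
    Rg = L @ L.T + np.diag(rng.uniform(0.05, 0.2, t))
    d = np.sqrt(np.diag(Rg))
    Rg = Rg / np.outer(d, d)
    h2 = np.concatenate(
        [rng.uniform(0.3, 0.6, n_secondary), rng.uniform(0.15, 0.4, n_focal)]
    )
    G0, R0 = block_covariance(h2, Rg)

    Lk = np.linalg.cholesky(K + 1e-8 * np.eye(n_lines))
    wg, Qg = np.linalg.eigh(G0)
    Lg = Qg * np.sqrt(np.clip(wg, 0, None))
    U = Lk @ rng.standard_normal((n_lines, t)) @ Lg.T
    E = rng.standard_normal((n_lines, t)) * np.sqrt((1.0 - h2))
    sec = [f"S{j + 1}" for j in range(n_secondary)]
    foc = [f"F{j + 1}" for j in range(n_focal)]
    cols = sec + foc
    Y = pd.DataFrame(U + E, index=grm.line_ids, columns=cols)
    Umat = pd.DataFrame(U, index=grm.line_ids, columns=cols)
    h2_s = pd.Series(h2, index=cols)

    hap_cols = []
    if with_haploids:
        # haploid counterpart of every trait: breeding values correlated
        # rg_dh_hap with the DH ones, same heritability
        U_ind = Lk @ rng.standard_normal((n_lines, t)) @ Lg.T
        U_hap = rg_dh_hap * U + np.sqrt(1.0 - rg_dh_hap**2) * U_ind
        E_hap = rng.standard_normal((n_lines, t)) * np.sqrt((1.0 - h2))
        hap_cols = [f"H_{c}" for c in cols]
        Y_hap = pd.DataFrame(U_hap + E_hap, index=grm.line_ids, columns=hap_cols)
        Y = pd.concat([Y, Y_hap], axis=1)
        Umat = pd.concat(
            [Umat, pd.DataFrame(U_hap, index=grm.line_ids, columns=hap_cols)], axis=1
        )
        h2_s = pd.concat([h2_s, pd.Series(h2, index=hap_cols)])

    return TraitAssistedStudy(
        Y=Y, U=Umat, grm=grm, secondary=sec, focal=foc,
        hap_traits=hap_cols, h2=h2_s,
    )


def ttest_calibration(
    n_studies: int = 500,
    J: int = 10,
    n_samples: int = 60,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Type-I error of corrected vs naive resampled t-tests under a null.

    Each study draws a fixed set of true values and two exchangeable
    predictors of equal skill, then evaluates their accuracy difference on
    J random 50:50 splits of the same samples — the overlapping-folds
    setting in which the naive paired t-test is anti-conservative.
    Returns ``(corrected_rate, naive_rate)``.
    """
    from .crossval import corrected_resampled_ttest, naive_resampled_ttest

    rng = substream(seed, "ttest_calibration")
    rej_c = rej_n = 0
    half = n_samples // 2
    for _ in range(n_studies):
        z = rng.standard_normal(n_samples)
        p1 = z + rng.standard_normal(n_samples)
        p2 = z + rng.standard_normal(n_samples)
        d = np.empty(J)
        for j in range(J):
            test = rng.choice(n_samples, half, replace=False)
            d[j] = (
                np.corrcoef(p1[test], z[test])[0, 1]
                - np.corrcoef(p2[test], z[test])[0, 1]
            )
        zero = np.zeros(J)
        if corrected_resampled_ttest(d, zero, half, half).p_value < alpha:
            rej_c += 1
        if naive_resampled_ttest(d, zero).p_value < alpha:
            rej_n += 1
    return rej_c / n_studies, rej_n / n_studies
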