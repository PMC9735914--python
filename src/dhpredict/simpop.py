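"""Synthetic doubled-haploid (DH) and haploid maize populations.

This module simulates the genetic material of a biparental DH breeding
program: gametes are sampled from an F1 (or a selfed descendant of the F1)
under a Haldane map (independent crossovers, Poisson counts per chromosome),
chromosome doubling makes each line fully homozygous, and haploid
counterparts carry marker-for-marker the same gamete as their DH line.
Phenotypes follow the standard multi-trait animal model

    y = Xb + Zu + e,   vec(U) ~ N(0, G0 (x) K),   rows of E ~ N(0, R0)

with a compound trait dimension spanning trait x environment x population
combinations, so genetic correlations between traits, between environments
and between the DH and haploid expression of the same genotype are all
encoded as off-diagonal blocks of G0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import (
    ORIGIN_P1,
    ORIGIN_P2,
    GenotypeMatrix,
    OriginMatrix,
    validate_marker_map,
)

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "default_marker_map",
    "simulate_meiosis_gamete",
    "simulate_biparental_dh",
    "derive_haploid_population",
    "simulate_phenotypes",
    "compound_labels",
    "block_covariance",
    "sample_breeding_values",
]


def default_marker_map(chrom_lengths_cM=None, markers_per_chrom=None) -> pd.DataFrame:
    """Evenly spaced default genome: 10 chromosomes x 150 cM x ~132 markers.

    Physical positions are laid out at 1 Mb per cM for plotting purposes.
    """
    if chrom_lengths_cM is None:
        chrom_lengths_cM = [150.0] * 10
    if markers_per_chrom is None:
        markers_per_chrom = [132] * len(chrom_lengths_cM)
    if len(markers_per_chrom) != len(chrom_lengths_cM):
        raise ValueError("markers_per_chrom and chrom_lengths_cM length mismatch")
    rows = []
    for c, (L, m) in enumerate(zip(chrom_lengths_cM, markers_per_chrom), start=1):
        pos_cM = np.linspace(0.0, float(L), m)
        pos_bp = np.round(pos_cM * 1_000_000).astype(np.int64) + 1
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(m))  # strictly increasing
        for j in range(m):
            rows.append((f"chr{c}_m{j + 1}", c, int(pos_bp[j]), float(pos_cM[j])))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "pos_cM"])
    validate_marker_map(df)
    return df


@dataclass
class SimConfig:
    """Recipe for one synthetic study.

    Defaults emulate a biparental maize DH panel: 187 lines genotyped at
    ~1320 markers on 10 chromosomes of 150 cM, with a 10% minority of lines
    derived after 3 extra generations of recurrent selfing (hence carrying
    more recombinations), phenotyped in 4 environments x 2 blocks.

    ``G0``/``R0`` are covariance matrices over the compound trait dimension
    (see :func:`compound_labels`); when left ``None`` the phenotype
    generator requires them to be supplied explicitly.
    """

    n_lines: int = 187
    chrom_lengths_cM: list = field(default_factory=lambda: [150.0] * 10)
    markers_per_chrom: list = field(default_factory=lambda: [132] * 10)
    selfing_fraction: float = 0.1
    selfing_generations: int = 3
    n_traits: int = 1
    n_envs: int = 4
    n_blocks: int = 2
    G0: np.ndarray | None = None
    R0: np.ndarray | None = None
    n_qtl_per_trait: int = 20
    block_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.selfing_fraction <= 1.0:
            raise ValueError("selfing_fraction must be in [0, 1]")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        for M in (self.G0, self.R0):
            if M is not None:
                _check_psd(np.asarray(M), "covariance matrix")

    def marker_map(self) -> pd.DataFrame:
        return default_marker_map(self.chrom_lengths_cM, self.markers_per_chrom)


@dataclass
class TraitArchitecture:
    """QTL positions and additive effects generating each trait.

    Effects are rescaled at phenotype-generation time so that the realized
    additive variance of each trait matches the target diagonal of G0.
    """

    qtl_markers: list  # per trait: integer marker indices
    qtl_effects: list  # per trait: additive allele-substitution effects
    intercepts: np.ndarray | None = None


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis_gamete(
    parent_haplotypes, map_df: pd.DataFrame, seed=None, rng=None, return_crossovers=False
):
    """Sample one gamete from a diploid parent under the Haldane model.

    Parameters
    ----------
    parent_haplotypes
        Sequence over chromosomes of ``(hap1, hap2)`` pairs of equal-length
        binary arrays aligned to the marker map of that chromosome.
    map_df
        Marker map covering the same chromosomes in order.
    seed, rng
        Either a seed (int) or an explicit generator.

    Returns
    -------
    list of arrays, one recombinant haplotype per chromosome. Crossover
    counts per chromosome are Poisson(length_cM / 100) with crossover
    positions uniform on the genetic map (no interference). With
    ``return_crossovers=True`` also returns the list of crossover counts.
    """
    validate_marker_map(map_df)
    if rng is None:
        rng = substream(0 if seed is None else seed, "meiosis")
    chroms = list(dict.fromkeys(map_df["chrom"]))
    if len(parent_haplotypes) != len(chroms):
        raise ValueError("parent_haplotypes must have one pair per chromosome")
    out, n_cos = [], []
    for chrom, (h1, h2) in zip(chroms, parent_haplotypes):
        pos = map_df.loc[map_df["chrom"] == chrom, "pos_cM"].to_numpy()
        h1 = np.asarray(h1)
        h2 = np.asarray(h2)
        if h1.shape != pos.shape or h2.shape != pos.shape:
            raise ValueError(f"chromosome {chrom}: haplotype length mismatch with map")
        length = pos.max() - pos.min() if pos.size else 0.0
        n_co = int(rng.poisson(length / 100.0))
        n_cos.append(n_co)
        start = rng.integers(2)
        if n_co == 0:
            out.append((h1 if start == 0 else h2).copy())
            continue
        xovers = np.sort(rng.uniform(pos.min(), pos.max(), size=n_co))
        # phase at each marker = start + number of crossovers to its left
        phase = (start + np.searchsorted(xovers, pos, side="right")) % 2
        out.append(np.where(phase == 0, h1, h2))
    if return_crossovers:
        return out, n_cos
    return out


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def simulate_biparental_dh(config: SimConfig):
    """Simulate a biparental DH population and the parental-origin truth.

    Parent 1 carries allele 0 at every marker and parent 2 allele 1, so the
    F1 is heterozygous everywhere and every marker is fully informative.
    A fraction ``selfing_fraction`` of lines samples its gamete from an
    individual selfed for ``selfing_generations`` extra generations after
    the F1, accumulating extra recombinations. Chromosome doubling yields
    dosages 0/2 only.

    Returns
    -------
    (GenotypeMatrix, OriginMatrix)
        The origin matrix records which parent contributed each marker
        (identical to the sampled gamete, since parents are fully
        informative).
    """
    map_df = config.marker_map()
    chroms = list(dict.fromkeys(map_df["chrom"]))
    sizes = [int((map_df["chrom"] == c).sum()) for c in chroms]
    n = config.n_lines
    rng = substream(config.seed, "simpop", "dh")
    n_self = int(round(config.selfing_fraction * n))
    is_self = np.zeros(n, dtype=bool)
    if n_self:
        is_self[rng.choice(n, size=n_self, replace=False)] = True

    gametes = np.empty((n, sum(sizes)), dtype=np.int8)
    f1 = [(np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)) for m in sizes]
    for i in range(n):
        line_rng = substream(config.seed, "simpop", "line", i)
        ind = f1
        if is_self[i]:
            for _ in range(config.selfing_generations):
                g1 = simulate_meiosis_gamete(ind, map_df, rng=line_rng)
                g2 = simulate_meiosis_gamete(ind, map_df, rng=line_rng)
                ind = list(zip(g1, g2))
        gam = simulate_meiosis_gamete(ind, map_df, rng=line_rng)
        gametes[i] = np.concatenate(gam)

    line_ids = [f"DH{i + 1:03d}" for i in range(n)]
    geno = GenotypeMatrix(
        line_ids=line_ids,
        marker_ids=list(map_df["marker_id"]),
        dosages=2.0 * gametes,
        map=map_df,
        population="DH",
    )
    origins = np.where(gametes == 0, ORIGIN_P1, ORIGIN_P2).astype(np.int8)
    origin = OriginMatrix(
        line_ids=line_ids,
        marker_ids=list(map_df["marker_id"]),
        origins=origins,
        map=map_df,
    )
    return geno, origin


def derive_haploid_population(dh: GenotypeMatrix) -> GenotypeMatrix:
    """Derive the haploid population from a fully homozygous DH panel.

    A homozygous line produces a single gamete type, so after induction
    (the inducer genome is eliminated) haploid line *i* is marker-for-marker
    identical to DH line *i*; only the population label changes.
    """
    vals = dh.dosages[~np.isnan(dh.dosages)]
    if np.any(vals == 1.0):
        raise ValueError("DH input contains heterozygous calls; gamete not unique")
    return GenotypeMatrix(
        line_ids=list(dh.line_ids),
        marker_ids=list(dh.marker_ids),
        dosages=dh.dosages.copy(),
        map=dh.map,
        population="HAP",
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def compound_labels(traits, envs, populations=("DH",)) -> pd.DataFrame:
    """Enumerate the compound trait dimension in a fixed order.

    Order: population (outer), environment, trait (inner). G0/R0 passed to
    :func:`simulate_phenotypes` must follow this order.
    """
    rows = [
        (p, e, t)
        for p in populations
        for e in (envs if not isinstance(envs, int) else [f"E{i + 1}" for i in range(envs)])
        for t in (traits if not isinstance(traits, int) else [f"T{i + 1}" for i in range(traits)])
    ]
    return pd.DataFrame(rows, columns=["population", "env", "trait"])


def block_covariance(h2, rG, sigma2_P=1.0):
    """Build matched (G0, R0) from heritabilities and a genetic correlation matrix.

    ``h2`` is a vector over the compound dimension, ``rG`` a correlation
    matrix of the same size. Genetic variances are ``h2 * sigma2_P`` and
    residual variances ``(1 - h2) * sigma2_P``; residuals are uncorrelated.
    """
    h2 = np.atleast_1d(np.asarray(h2, dtype=float))
    rG = np.atleast_2d(np.asarray(rG, dtype=float))
    sg = np.sqrt(h2 * sigma2_P)
    G0 = rG * np.outer(sg, sg)
    R0 = np.diag((1.0 - h2) * sigma2_P)
    _check_psd(G0, "G0")
    return G0, R0


def sample_breeding_values(K: np.ndarray, G0: np.ndarray, rng) -> np.ndarray:
    """Draw U (n x T) with vec(U) ~ N(0, G0 (x) K)."""
    K = np.asarray(K, dtype=float)
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    _check_psd(K, "K", tol=1e-6)
    _check_psd(G0, "G0")
    n, T = K.shape[0], G0.shape[0]
    wk, Qk = np.linalg.eigh(K)
    wg, Qg = np.linalg.eigh(G0)
    Lk = Qk * np.sqrt(np.clip(wk, 0.0, None))
    Lg = Qg * np.sqrt(np.clip(wg, 0.0, None))
    Z = rng.standard_normal((n, T))
    return Lk @ Z @ Lg.T


def simulate_phenotypes(
    K,
    config: SimConfig,
    labels: pd.DataFrame | None = None,
    arch: TraitArchitecture | None = None,
    genotypes: GenotypeMatrix | None = None,
    line_ids=None,
    seed=None,
) -> pd.DataFrame:
    """Generate a plot-level long-format phenotype table.

    Parameters
    ----------
    K
        Genomic relationship matrix (n x n array or :class:`GRM`-like with
        ``.matrix``/``.line_ids``) over the simulated lines.
    config
        Must carry ``G0`` and ``R0`` over the compound dimension, and
        ``n_blocks``.
    labels
        Compound-dimension labels from :func:`compound_labels`; defaults to
        single population "DH" x ``config.n_envs`` x ``config.n_traits``.
    arch
        Optional QTL architecture; when given together with ``genotypes``,
        breeding values for each compound trait are built from marker
        effects (rescaled to the target variance) instead of being drawn
        from N(0, G0 (x) K). Cross-trait genetic correlations are then
        whatever the shared-QTL structure implies.
    seed
        Overrides ``config.seed``.

    Returns
    -------
    DataFrame with columns line_id, population, env, block, trait, value.
    Fixed block effects are drawn once per (population, env, block) from
    N(0, block_effect_sd^2); plot residual vectors over the compound
    dimension are iid N(0, R0) per (line, block).
    """
    if hasattr(K, "matrix"):
        if line_ids is None:
            line_ids = list(K.line_ids)
        K = K.matrix
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if line_ids is None:
        line_ids = [f"DH{i + 1:03d}" for i in range(n)]
    if config.G0 is None or config.R0 is None:
        raise ValueError("config.G0 and config.R0 must be set to simulate phenotypes")
    G0 = np.atleast_2d(np.asarray(config.G0, dtype=float))
    R0 = np.atleast_2d(np.asarray(config.R0, dtype=float))
    T = G0.shape[0]
    if labels is None:
        labels = compound_labels(config.n_traits, config.n_envs)
    if len(labels) != T:
        raise ValueError("labels length must match G0 dimension")
    seed = config.seed if seed is None else seed
    rng = substream(seed, "simpop", "pheno")

    if arch is not None:
        if genotypes is None:
            raise ValueError("QTL architecture requires genotypes")
        U = _qtl_breeding_values(genotypes, arch, G0, rng)
    else:
        U = sample_breeding_values(K, G0, rng)

    # fixed block effects per (population, env, block)
    blocks = range(1, config.n_blocks + 1)
    key_cols = labels[["population", "env"]].drop_duplicates()
    block_eff = {
        (p, e, b): rng.normal(0.0, config.block_effect_sd)
        for p, e in key_cols.itertuples(index=False)
        for b in blocks
    }

    Lr = _chol_psd(R0)
    recs = []
    for b in blocks:
        E = rng.standard_normal((n, T)) @ Lr.T
        Y = U + E
        for j, (p, e, t) in enumerate(labels.itertuples(index=False)):
            be = block_eff[(p, e, b)]
            vals = Y[:, j] + be
            recs.append(
                pd.DataFrame(
                    {
                        "line_id": line_ids,
                        "population": p,
                        "env": e,
                        "block": b,
                        "trait": t,
                        "value": vals,
                    }
                )
            )
    return pd.concat(recs, ignore_index=True)


def _chol_psd(M: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(np.asarray(M, dtype=float))
    return Q * np.sqrt(np.clip(w, 0.0, None))


def _qtl_breeding_values(genotypes, arch, G0, rng):
    X = genotypes.dosages - np.nanmean(genotypes.dosages, axis=0)
    T = G0.shape[0]
    if len(arch.qtl_markers) != T:
        raise ValueError("architecture must define QTL for every compound trait")
    n = X.shape[0]
    U = np.zeros((n, T))
    for j in range(T):
        idx = np.asarray(arch.qtl_markers[j], dtype=int)
        eff = np.asarray(arch.qtl_effects[j], dtype=float)
        a = X[:, idx] @ eff
        v = a.var()
        target = G0[j, j]
        if v > 0:
            a = a * np.sqrt(target / v)
        U[:, j] = a
    return U


def make_trait_architecture(genotypes: GenotypeMatrix, config: SimConfig, seed=None) -> TraitArchitecture:
    """Sample a sparse QTL architecture: n_qtl markers per compound trait."""
    seed = config.seed if seed is None else seed
    rng = substream(seed, "simpop", "arch")
    T = 1 if config.G0 is None else np.atleast_2d(config.G0).shape[0]
    qtl_markers, qtl_effects = [], []
    for _ in range(T):
        idx = rng.choice(genotypes.n_markers, size=config.n_qtl_per_trait, replace=False)
        qtl_markers.append(np.sort(idx))
        qtl_effects.append(rng.standard_normal(config.n_qtl_per_trait))
    return TraitArchitecture(qtl_markers=qtl_markers, qtl_effects=qtl_effects)
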