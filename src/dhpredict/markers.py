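"""Marker QC, genomic relationship matrices and graphical genotypes.

QC follows the strict-inequality convention common on SNP-chip panels:
a marker is kept when MAF > 5%, missing rate < 20% and heterozygosity
< 10%; a line is kept when its missing rate and heterozygous-call rate are
each < 20%. Boundary values fail. Markers are filtered before lines, in a
single pass.

The additive GRM is VanRaden method 1: dosages centered by twice the allele
frequency, cross-product scaled by 2 * sum p_k (1 - p_k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ORIGIN_NA,
    ORIGIN_P1,
    ORIGIN_P2,
    GRM,
    GenotypeMatrix,
    OriginMatrix,
)

__all__ = [
    "QCReport",
    "qc_filter",
    "compute_grm",
    "encode_parental_origin",
    "count_recombinations",
    "export_graphical_genotypes",
    "genotype_from_vcf",
]


@dataclass
class QCReport:
    """Counts of markers/lines removed per criterion (strict thresholds)."""

    thresholds: dict
    n_markers_in: int
    n_lines_in: int
    removed_markers_maf: int = 0
    removed_markers_missing: int = 0
    removed_markers_het: int = 0
    removed_lines_missing: int = 0
    removed_lines_het: int = 0

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - (
            self.removed_markers_maf + self.removed_markers_missing + self.removed_markers_het
        )

    @property
    def n_lines_out(self) -> int:
        return self.n_lines_in - (self.removed_lines_missing + self.removed_lines_het)

    def __str__(self) -> str:  # report header states boundary semantics
        lines = [
            "Marker/line QC (strict thresholds: boundary values FAIL)",
            f"  thresholds: {self.thresholds}",
            f"  markers: {self.n_markers_in} in, {self.n_markers_out} kept "
            f"(MAF {self.removed_markers_maf}, missing {self.removed_markers_missing}, "
            f"het {self.removed_markers_het} removed)",
            f"  lines:   {self.n_lines_in} in, {self.n_lines_out} kept "
            f"(missing {self.removed_lines_missing}, het {self.removed_lines_het} removed)",
        ]
        return "\n".join(lines)


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    marker_miss_max: float = 0.20,
    marker_het_max: float = 0.10,
    line_miss_max: float = 0.20,
    line_het_max: float = 0.20,
    order: str = "markers_first",
):
    """Filter markers then lines by MAF / missingness / heterozygosity.

    All thresholds are strict: a marker passes MAF only if MAF > maf_min,
    and passes missingness only if its missing rate < marker_miss_max
    (analogously for lines). Returns ``(filtered GenotypeMatrix, QCReport)``.
    """
    D = g.dosages
    report = QCReport(
        thresholds=dict(
            maf_min=maf_min,
            marker_miss_max=marker_miss_max,
            marker_het_max=marker_het_max,
            line_miss_max=line_miss_max,
            line_het_max=line_het_max,
        ),
        n_markers_in=g.n_markers,
        n_lines_in=g.n_lines,
    )
    if order != "markers_first":
        raise ValueError("only order='markers_first' is implemented")

    miss_m = np.isnan(D).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(D, axis=0) / 2.0
        het_m = np.nanmean(D == 1.0, axis=0)
    p = np.where(np.isnan(p), 0.0, p)
    het_m = np.where(np.isnan(het_m), 0.0, het_m)
    maf = np.minimum(p, 1.0 - p)

    fail_maf = maf <= maf_min
    fail_miss = miss_m >= marker_miss_max
    fail_het = het_m >= marker_het_max
    # attribute each failing marker to the first criterion it fails (i)-(iii)
    report.removed_markers_maf = int(fail_maf.sum())
    report.removed_markers_missing = int((~fail_maf & fail_miss).sum())
    report.removed_markers_het = int((~fail_maf & ~fail_miss & fail_het).sum())
    keep_m = ~(fail_maf | fail_miss | fail_het)
    if not keep_m.any():
        raise ValueError("no markers left after QC")

    D2 = D[:, keep_m]
    miss_l = np.isnan(D2).mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        het_l = np.nanmean(D2 == 1.0, axis=1)
    het_l = np.where(np.isnan(het_l), 0.0, het_l)
    fail_lmiss = miss_l >= line_miss_max
    fail_lhet = het_l >= line_het_max
    report.removed_lines_missing = int(fail_lmiss.sum())
    report.removed_lines_het = int((~fail_lmiss & fail_lhet).sum())
    keep_l = ~(fail_lmiss | fail_lhet)
    if not keep_l.any():
        raise ValueError("no lines left after QC")

    out = g.subset(np.where(keep_l)[0], np.where(keep_m)[0])
    return out, report


def compute_grm(g: GenotypeMatrix) -> GRM:
    """VanRaden method-1 additive GRM.

    Missing dosages are imputed to the per-marker mean before centering by
    2p_k; the cross-product is divided by 2 * sum p_k (1 - p_k).
    """
    D = g.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(D, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("markers with all calls missing; run qc_filter first")
    nan_mask = np.isnan(D)
    D[nan_mask] = np.broadcast_to(col_mean, D.shape)[nan_mask]
    p = col_mean / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = D - 2.0 * p
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    return GRM(line_ids=list(g.line_ids), matrix=K)


def encode_parental_origin(g: GenotypeMatrix, p1, p2) -> OriginMatrix:
    """Translate genotypes to parental origins (graphical-genotype coding).

    ``p1``/``p2`` are parental dosage rows aligned to ``g``'s markers.
    Only markers where both parents are homozygous and different are
    informative; others are dropped. Per cell: identical to parent 1 ->
    P1, identical to parent 2 -> P2, heterozygous or missing -> NA
    (heterozygous calls in a DH line are treated as probable genotyping
    errors).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != (g.n_markers,) or p2.shape != (g.n_markers,):
        raise ValueError("parent rows must align with the genotype matrix markers")
    informative = (
        np.isin(p1, (0.0, 2.0)) & np.isin(p2, (0.0, 2.0)) & (p1 != p2)
    )
    idx = np.where(informative)[0]
    if idx.size == 0:
        raise ValueError("no informative markers (parents identical or not homozygous)")
    D = g.dosages[:, idx]
    codes = np.full(D.shape, ORIGIN_NA, dtype=np.int8)
    codes[D == p1[idx]] = ORIGIN_P1
    codes[D == p2[idx]] = ORIGIN_P2
    return OriginMatrix(
        line_ids=list(g.line_ids),
        marker_ids=[g.marker_ids[j] for j in idx],
        origins=codes,
        map=g.map.iloc[idx].reset_index(drop=True),
    )


def count_recombinations(o: OriginMatrix) -> pd.DataFrame:
    """Count origin switches per line and chromosome.

    A switch is a change of parental origin between consecutive *informative*
    (non-NA) markers in map order; NA cells are skipped, never counted.
    Chromosomes with fewer than two informative markers on a line count 0.
    """
    chroms = list(dict.fromkeys(o.map["chrom"]))
    counts = np.zeros((len(o.line_ids), len(chroms)), dtype=int)
    few = False
    for cj, chrom in enumerate(chroms):
        cols = np.where((o.map["chrom"] == chrom).to_numpy())[0]
        sub = o.origins[:, cols]
        for i in range(sub.shape[0]):
            run = sub[i][sub[i] != ORIGIN_NA]
            if run.size < 2:
                few = True
                continue
            counts[i, cj] = int(np.sum(run[1:] != run[:-1]))
    if few:
        warnings.warn("some line/chromosome pairs had < 2 informative markers; counted 0")
    return pd.DataFrame(counts, index=list(o.line_ids), columns=chroms)


def _merge_runs(o: OriginMatrix) -> pd.DataFrame:
    """Run-length encode same-origin segments per line and chromosome."""
    rows = []
    chroms = list(dict.fromkeys(o.map["chrom"]))
    pos = o.map["pos_bp"].to_numpy()
    for chrom in chroms:
        cols = np.where((o.map["chrom"] == chrom).to_numpy())[0]
        cpos = pos[cols]
        for i, line in enumerate(o.line_ids):
            vals = o.origins[i, cols]
            nz = np.where(vals != ORIGIN_NA)[0]
            if nz.size == 0:
                continue
            start = nz[0]
            cur = vals[start]
            prev = start
            for j in nz[1:]:
                if vals[j] != cur:
                    rows.append((line, chrom, int(cpos[start]), int(cpos[prev]), cur))
                    start, cur = j, vals[j]
                prev = j
            rows.append((line, chrom, int(cpos[start]), int(cpos[prev]), cur))
    df = pd.DataFrame(rows, columns=["line", "chrom", "start_bp", "end_bp", "origin"])
    df["origin"] = df["origin"].map({ORIGIN_P1: "P1", ORIGIN_P2: "P2"})
    return df


def export_graphical_genotypes(o: OriginMatrix, path=None) -> pd.DataFrame:
    """Merged same-origin segments per line/chromosome, in long TSV form.

    Segments use 1-based closed intervals [start_bp, end_bp] anchored at the
    first and last marker of each run. Lines are ordered by genome-wide
    similarity to parent 1 (fraction of P1-origin markers, descending), the
    order used for plotting. When ``path`` is given the table is written as
    TSV; the table itself is always returned so plotting layers can consume
    it directly.
    """
    segs = _merge_runs(o)
    informative = o.origins != ORIGIN_NA
    with np.errstate(invalid="ignore"):
        frac_p1 = np.where(
            informative.sum(axis=1) > 0,
            (o.origins == ORIGIN_P1).sum(axis=1) / np.maximum(informative.sum(axis=1), 1),
            0.0,
        )
    order = {line: f for line, f in zip(o.line_ids, frac_p1)}
    segs = segs.sort_values(
        by=["line", "chrom", "start_bp"],
        key=lambda s: s.map(lambda v: -order[v]) if s.name == "line" else s,
        kind="stable",
    ).reset_index(drop=True)
    if path is not None:
        segs.to_csv(path, sep="\t", index=False)
    return segs


def plot_graphical_genotypes(o: OriginMatrix, chrom, ax=None):
    """Thin matplotlib layer over :func:`export_graphical_genotypes`."""
    import matplotlib.pyplot as plt

    segs = export_graphical_genotypes(o)
    segs = segs[segs["chrom"] == chrom]
    lines = list(dict.fromkeys(segs["line"]))
    ypos = {l: i for i, l in enumerate(lines)}
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, len(lines) * 0.08)))
    colors = {"P1": "tab:blue", "P2": "tab:red"}
    for _, r in segs.iterrows():
        ax.barh(
            ypos[r["line"]],
            r["end_bp"] - r["start_bp"] + 1,
            left=r["start_bp"],
            height=0.9,
            color=colors[r["origin"]],
            linewidth=0,
        )
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("DH line")
    ax.set_title(f"chromosome {chrom}")
    return ax


def genotype_from_vcf(path, population: str = "DH") -> GenotypeMatrix:
    """Import biallelic SNPs from a VCF (GT field -> dosage of ALT allele)."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("VCF import requires cyvcf2") from e

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, chroms, pos_bp, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos_bp.append(var.POS)
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=missing,3=hom-alt
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
    chrom_codes = pd.factorize(pd.Series(chroms))[0] + 1
    map_df = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": chrom_codes,
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "pos_cM": np.zeros(len(marker_ids)),
        }
    )
    return GenotypeMatrix(
        line_ids=samples,
        marker_ids=marker_ids,
        dosages=np.asarray(rows).T,
        map=map_df,
        population=population,
    )
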