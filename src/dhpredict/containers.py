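"""Core data containers shared across the package.

Genotypes are held as dosage matrices (lines x markers, values 0/1/2 with
``NaN`` for missing) together with a marker map ordered by chromosome and
physical position. Parental origins of doubled-haploid (DH) genomes are held
as coded matrices over the informative markers only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "OriginMatrix",
    "GRM",
    "ORIGIN_P1",
    "ORIGIN_P2",
    "ORIGIN_NA",
]

# integer codes for parental origin
ORIGIN_P1 = 0
ORIGIN_P2 = 1
ORIGIN_NA = -1


def MarkerMap(marker_id, chromosome, position_bp, position_cM) -> pd.DataFrame:
    """Build and validate a marker map table.

    Returns a DataFrame with columns ``marker_id, chrom, pos_bp, pos_cM``,
    one row per marker, in map order. Within a chromosome markers must be
    strictly increasing in physical position and non-decreasing in genetic
    position.
    """
    df = pd.DataFrame(
        {
            "marker_id": np.asarray(marker_id, dtype=object),
            "chrom": np.asarray(chromosome, dtype=int),
            "pos_bp": np.asarray(position_bp, dtype=np.int64),
            "pos_cM": np.asarray(position_cM, dtype=float),
        }
    )
    validate_marker_map(df)
    return df


def validate_marker_map(map_df: pd.DataFrame) -> None:
    required = {"marker_id", "chrom", "pos_bp", "pos_cM"}
    missing = required - set(map_df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    if map_df["marker_id"].duplicated().any():
        raise ValueError("marker_id values must be unique")
    if (map_df["pos_bp"] < 1).any():
        raise ValueError("pos_bp must be >= 1 (1-based)")
    if (map_df["pos_cM"] < 0).any():
        raise ValueError("pos_cM must be >= 0")
    for chrom, grp in map_df.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos_bp"].to_numpy()) > 0):
            raise ValueError(f"chromosome {chrom}: pos_bp not strictly increasing")
        if not np.all(np.diff(grp["pos_cM"].to_numpy()) >= 0):
            raise ValueError(f"chromosome {chrom}: pos_cM not non-decreasing")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with an attached marker map.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for missing
    calls. Column order matches ``map`` row order.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray
    map: pd.DataFrame
    population: str = "DH"

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosages shape inconsistent with line/marker ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if list(self.map["marker_id"]) != self.marker_ids:
            raise ValueError("marker_ids must match map order")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, line_idx=None, marker_idx=None) -> "GenotypeMatrix":
        li = np.arange(self.n_lines) if line_idx is None else np.asarray(line_idx, dtype=int)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx, dtype=int)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in li],
            marker_ids=[self.marker_ids[j] for j in mi],
            dosages=self.dosages[np.ix_(li, mi)],
            map=self.map.iloc[mi].reset_index(drop=True),
            population=self.population,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids).to_csv(
            path, sep="\t", index_label="line_id", na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path, map_df: pd.DataFrame, population: str = "DH") -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="line_id", na_values=["NA"])
        df = df[list(map_df["marker_id"])]
        return cls(
            line_ids=list(df.index),
            marker_ids=list(df.columns),
            dosages=df.to_numpy(dtype=float),
            map=map_df.reset_index(drop=True),
            population=population,
        )


@dataclass
class OriginMatrix:
    """Parental origin of each marker call: codes P1/P2/NA.

    Defined only over markers where the two parents are homozygous for
    different alleles. ``origins`` is int8 with values ``ORIGIN_P1`` (0),
    ``ORIGIN_P2`` (1) and ``ORIGIN_NA`` (-1).
    """

    line_ids: list
    marker_ids: list
    origins: np.ndarray
    map: pd.DataFrame

    def __post_init__(self):
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if self.origins.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("origins shape inconsistent with ids")
        if not np.isin(self.origins, (ORIGIN_P1, ORIGIN_P2, ORIGIN_NA)).all():
            raise ValueError("origin codes must be P1/P2/NA")


@dataclass
class GRM:
    """Genomic relationship matrix over a set of lines."""

    line_ids: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over line_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-6:
            raise ValueError(f"GRM not PSD: min eigenvalue {w.min():.3g}")

    def align(self, line_ids) -> np.ndarray:
        """Return the submatrix over ``line_ids`` in that order."""
        idx = {l: i for i, l in enumerate(self.line_ids)}
        try:
            pos = [idx[l] for l in line_ids]
        except KeyError as e:
            raise KeyError(f"line {e.args[0]!r} not in GRM") from None
        return self.matrix[np.ix_(pos, pos)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids).to_csv(
            path, sep="\t", index_label="line_id"
        )

    @classmethod
    def from_tsv(cls, path) -> "GRM":
        df = pd.read_csv(path, sep="\t", index_col="line_id")
        return cls(line_ids=list(df.index), matrix=df.to_numpy(dtype=float))
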