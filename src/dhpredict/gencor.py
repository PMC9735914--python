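"""Genetic/phenotypic correlation and heritability estimators.

These are plug-in estimators applied to fitted variance components of a
bivariate DH/haploid genomic model:

    rG = sigma_G(D,H) / sqrt(sigma2_G(D) * sigma2_G(H))
    rP = (sigma_G(D,H) + sigma_e(D,H))
         / sqrt((sigma2_G(D) + sigma2_e(D)) * (sigma2_G(H) + sigma2_e(H)))
    h2 = sigma2_G / (sigma2_G + sigma2_e)

The residual covariance between populations defaults to zero: DH and
haploid plots are randomized in separate blocks, so they share no plot-level
environment. Monte-Carlo noise can push a plug-in correlation slightly past
the [-1, 1] bound; estimates are clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarCompPair",
    "genetic_correlation",
    "phenotypic_correlation",
    "heritability",
    "correlation_table",
]


@dataclass
class VarCompPair:
    """Variance components of one trait in the DH and haploid populations."""

    sigma_G_DH: float
    sigma2_G_D: float
    sigma2_G_H: float
    sigma2_e_D: float
    sigma2_e_H: float
    sigma_e_DH: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_G_D", "sigma2_G_H", "sigma2_e_D", "sigma2_e_H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def genetic_correlation(v: VarCompPair) -> float:
    """Genetic correlation between the DH and haploid expression of a trait."""
    if v.sigma2_G_D <= 0 or v.sigma2_G_H <= 0:
        raise ValueError("genetic correlation undefined with zero genetic variance")
    r = v.sigma_G_DH / np.sqrt(v.sigma2_G_D * v.sigma2_G_H)
    return float(np.clip(r, -1.0, 1.0))


def phenotypic_correlation(v: VarCompPair) -> float:
    """Phenotypic correlation; residual covariance defaults to zero."""
    tot_D = v.sigma2_G_D + v.sigma2_e_D
    tot_H = v.sigma2_G_H + v.sigma2_e_H
    if tot_D <= 0 or tot_H <= 0:
        raise ValueError("phenotypic correlation undefined with zero total variance")
    r = (v.sigma_G_DH + v.sigma_e_DH) / np.sqrt(tot_D * tot_H)
    return float(np.clip(r, -1.0, 1.0))


def heritability(sigma2_G: float, sigma2_e: float) -> float:
    """Narrow-sense heritability on a line-mean basis."""
    if sigma2_G < 0 or sigma2_e < 0:
        raise ValueError("variance components must be >= 0")
    tot = sigma2_G + sigma2_e
    if tot <= 0:
        raise ValueError("heritability undefined when both components are zero")
    return float(sigma2_G / tot)


def correlation_table(
    pheno: pd.DataFrame,
    K,
    env: str,
    traits=None,
    burn_in: int = 1000,
    n_iter: int = 4000,
    thin: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait (h2_D, h2_H, rP, rG) table for one environment.

    ``pheno`` is a long table with columns line_id, population (DH/HAP),
    env, trait, value; replicate plots are averaged to line means before
    the bivariate fit. Heritabilities are the marginals of the bivariate
    fit (each trait's genetic fraction of its total variance).
    """
    from .multitrait import fit_bivariate_dh_hap

    sub = pheno[pheno["env"] == env]
    if traits is None:
        traits = sorted(sub["trait"].unique())
    line_ids = list(K.line_ids) if hasattr(K, "line_ids") else None
    rows = []
    for i, trait in enumerate(traits):
        tsub = sub[sub["trait"] == trait]
        means = tsub.groupby(["population", "line_id"])["value"].mean()
        y_D = means.get("DH", pd.Series(dtype=float)).reindex(line_ids).to_numpy()
        y_H = means.get("HAP", pd.Series(dtype=float)).reindex(line_ids).to_numpy()
        res = fit_bivariate_dh_hap(
            y_D, y_H, K, burn_in=burn_in, n_iter=n_iter, thin=thin,
            seed=seed + i, line_ids=line_ids,
        )
        vc = res.var_comps
        rows.append(
            {
                "trait": trait,
                "env": env,
                "h2_D": heritability(vc.sigma2_G_D, vc.sigma2_e_D),
                "h2_H": heritability(vc.sigma2_G_H, vc.sigma2_e_H),
                "rP": res.rP,
                "rG": res.rG,
            }
        )
    return pd.DataFrame(rows)
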