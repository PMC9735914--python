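"""Deterministic selection-response theory for DH versus haploid selection.

Breeders can either select DH lines directly on their own phenotypes, or
select on the correlated haploid progenitors one generation earlier
(indirect selection). With selection intensity i, heritability h2 and
additive standard deviation sigma_A(D) in the DH population, the expected
responses in the DH population are

    direct:    R_D = i_D * h_D * sigma_A(D)
    indirect:  R_D = i_H * r_A(D,H) * h_H * sigma_A(D)

so at equal intensities indirect selection wins exactly when
r_A(D,H) * h_H > h_D.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SelectionParams",
    "indirect_response",
    "direct_response",
    "relative_efficiency",
    "count_hybrid_combinations",
    "selection_intensity",
]


@dataclass
class SelectionParams:
    """Inputs of the selection-response formulas.

    ``h_H``/``h_D`` are square roots of narrow-sense heritabilities,
    ``sigma_A_D`` the additive SD in the DH population (trait units),
    ``r_A`` the additive genetic correlation between populations,
    ``i_H``/``i_D`` standardized selection intensities.
    """

    i_H: float = 1.0
    i_D: float = 1.0
    h_H: float = 0.0
    h_D: float = 0.0
    sigma_A_D: float = 0.0
    r_A: float = 0.0

    def __post_init__(self):
        for name in ("h_H", "h_D"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_A_D < 0:
            raise ValueError("sigma_A_D must be >= 0")
        if abs(self.r_A) > 1.0:
            raise ValueError("|r_A| must be <= 1")


def indirect_response(p: SelectionParams) -> float:
    """Expected DH-level response to selection among haploids."""
    return float(p.i_H * p.r_A * p.h_H * p.sigma_A_D)


def direct_response(p: SelectionParams) -> float:
    """Expected DH-level response to selection among DH lines themselves."""
    return float(p.i_D * p.h_D * p.sigma_A_D)


def relative_efficiency(p: SelectionParams):
    """Indirect/direct efficiency ratio at equal selection intensities.

    Returns ``(RE, verdict)`` where RE = r_A * h_H / h_D and verdict is
    "indirect_better", "direct_better" or "tie".
    """
    if p.h_D <= 0:
        raise ValueError("relative efficiency undefined for h_D = 0")
    re = p.r_A * p.h_H / p.h_D
    if re > 1.0:
        verdict = "indirect_better"
    elif re < 1.0:
        verdict = "direct_better"
    else:
        verdict = "tie"
    return float(re), verdict


def count_hybrid_combinations(n_pool1: int, n_pool2: int) -> int:
    """Single crosses between two heterotic pools: n1 * n2 combinations."""
    if n_pool1 < 0 or n_pool2 < 0:
        raise ValueError("pool sizes must be >= 0")
    return int(n_pool1) * int(n_pool2)


def selection_intensity(selected_fraction: float) -> float:
    """Standardized intensity i = phi(z) / p under truncation selection.

    ``p`` is the selected fraction and ``z`` the standard-normal truncation
    point with upper-tail mass p.
    """
    if not 0.0 < selected_fraction < 1.0:
        raise ValueError("selected fraction must be in (0, 1)")
    z = stats.norm.isf(selected_fraction)
    return float(stats.norm.pdf(z) / selected_fraction)
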