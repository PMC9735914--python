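import numpy as np
import pytest

from dhpredict.markers import compute_grm
from dhpredict.simpop import SimConfig, simulate_biparental_dh


@pytest.fixture(scope="session")
def small_panel():
    """60-line biparental DH panel on 3 chromosomes with its GRM."""
    cfg = SimConfig(
        n_lines=60,
        chrom_lengths_cM=[150.0] * 3,
        markers_per_chrom=[40] * 3,
        seed=101,
    )
    geno, origin = simulate_biparental_dh(cfg)
    grm = compute_grm(geno)
    return cfg, geno, origin, grm


@pytest.fixture(scope="session")
def full_panel():
    """Study-scale panel: 187 lines, 10 chromosomes x 132 markers."""
    cfg = SimConfig(n_lines=187, seed=1)
    geno, _ = simulate_biparental_dh(cfg)
    grm = compute_grm(geno)
    return cfg, geno, grm


@pytest.fixture(scope="session")
def midsize_panel():
    """150-line panel used by the heavier model-fit tests."""
    cfg = SimConfig(
        n_lines=150,
        chrom_lengths_cM=[150.0] * 5,
        markers_per_chrom=[50] * 5,
        seed=202,
    )
    geno, _ = simulate_biparental_dh(cfg)
    grm = compute_grm(geno)
    return cfg, geno, grm
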