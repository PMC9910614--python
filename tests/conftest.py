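import numpy as np
import pytest

from sweepscan.panel import GeneticMapTable, PhasedPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(alleles, positions=None, chrom="chr1", population="pop",
               ref=None, alt=None, missing=None, polarized=True):
    """Small hand-built panel; alleles is (n_hap, n_sites) array-like."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_sites = alleles.shape
    if positions is None:
        positions = np.arange(n_sites) * 1000 + 100
    return PhasedPanel(
        chrom=chrom,
        positions=np.asarray(positions),
        alleles=alleles,
        haplotype_ids=[f"s{i//2}|{i % 2}" for i in range(n_hap)],
        population=population,
        ref=np.array(["A"] * n_sites) if ref is None else np.asarray(ref),
        alt=np.array(["G"] * n_sites) if alt is None else np.asarray(alt),
        missing=missing,
        polarized=polarized,
    )


def random_panel(rng, n_hap=8, n_sites=20, length=200_000):
    """Random polarized panel with segregating sites."""
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    # ensure segregating
    for j in range(n_sites):
        if alleles[:, j].all() or not alleles[:, j].any():
            alleles[rng.integers(0, n_hap), j] ^= 1
    return make_panel(alleles, positions)


def uniform_map(chrom="chr1", length=1_000_000, cm_per_mb=100.0):
    return GeneticMapTable(chrom=chrom,
                           anchor_positions=np.array([0, length]),
                           anchor_cM=np.array([0.0, cm_per_mb * length / 1e6]))


@pytest.fixture
def panel_factory():
    return make_panel


@pytest.fixture
def random_panel_factory():
    return random_panel
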