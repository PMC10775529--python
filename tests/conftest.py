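"""Shared fixtures: drift banks and simulated studies reused across tests."""

import numpy as np
import pandas as pd
import pytest

from driftscan import SimulationParams, build_drift_bank, simulate_experiment
from driftscan.simulate import merged_matrix
from driftscan.variant_io import GenotypeMatrix

TEN_CHROMS = tuple((f"A{i:02d}", 28_300_000) for i in range(1, 11))


@pytest.fixture(scope="session")
def bank16():
    """Default drift null: Ne=16, 8 transitions, 10,000 sims per grid point."""
    return build_drift_bank(seed=123)


@pytest.fixture(scope="session")
def bank36():
    """Drift null matched to the census size of a 36-plant replicate."""
    return build_drift_bank(ne=36, seed=123)


@pytest.fixture(scope="session")
def small_study():
    """A 200-SNP neutral study used for structural checks."""
    params = SimulationParams(
        n_snps=200,
        chromosomes=(("A01", 5_000_000), ("A02", 5_000_000)),
        missing_rate=0.02,
        seed=42,
    )
    return simulate_experiment(params)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return merged_matrix(small_study)


def linked_params(seed: int) -> SimulationParams:
    """Linked architecture: dense markers, tight linkage, strong selection,
    founders carrying short-range standing LD (segmental haplotype pool)."""
    return SimulationParams(
        n_snps=240,
        chromosomes=(("A01", 600_000), ("A02", 600_000)),
        recomb_fraction=0.005,
        selected_loci=tuple((i, 0.5) for i in range(10, 240, 20)),
        founder_pool_size=3,
        founder_segment_loci=4,
        missing_rate=0.0,
        seed=seed,
    )


def soft_sweep_params(seed: int) -> SimulationParams:
    """Polygenic soft-sweep architecture: many selected loci starting rare,
    free recombination, genome-scale marker map."""
    return SimulationParams(
        n_snps=600,
        chromosomes=TEN_CHROMS,
        recomb_fraction=0.5,
        selected_loci=tuple((i, 0.25) for i in range(7, 600, 20)),
        selected_founder_af=0.1,
        missing_rate=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def linked_study():
    return simulate_experiment(linked_params(6))


@pytest.fixture(scope="session")
def soft_sweep_study():
    return simulate_experiment(soft_sweep_params(5))


def make_matrix(dosage, positions=None, chrom="A01", gq=None, dp=None):
    """GenotypeMatrix from a plain dosage array with evenly spaced positions."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        dosage=dosage,
        snps=snps,
        sample_ids=[f"s{i:03d}" for i in range(n)],
        gq=gq,
        dp=dp,
    )
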