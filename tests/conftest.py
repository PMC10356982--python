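from __future__ import annotations

import numpy as np
import pytest

from rohmap.detect import detect_roh
from rohmap.simulate import RiskRegion, SimulationConfig, simulate_study
from rohmap.types import GenotypeDataset, MarkerMap


@pytest.fixture(scope="session")
def default_study():
    """The package's reference study (default configuration, seed 1)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_roh(default_study):
    return detect_roh(default_study.dataset)


@pytest.fixture(scope="session")
def small_study():
    """A fast small-scale study used by I/O and CLI-level tests."""
    cfg = SimulationConfig(
        n_animals=60,
        n_chromosomes=2,
        markers_per_chromosome=800,
        mean_spacing_kb=15.0,
        roh_rate_per_chrom=1.0,
        pedigree_depth=3,
        n_sires=8,
        risk_regions=(RiskRegion(1, 4_000_000, 7_000_000, -5.0, 0.3),),
        seed=11,
    )
    return simulate_study(cfg)


def make_map(
    positions: list[int], chromosome: int = 1, chromosome_lengths=None
) -> MarkerMap:
    return MarkerMap(
        np.array([f"m{i}" for i in range(len(positions))], dtype=object),
        np.full(len(positions), chromosome, dtype=np.int64),
        np.array(positions, dtype=np.int64),
        chromosome_lengths=chromosome_lengths,
    )


def make_dataset(codes_by_animal: dict[str, list[int]], positions: list[int],
                 chromosome: int = 1) -> GenotypeDataset:
    markers = make_map(positions, chromosome)
    genotypes = np.array(list(codes_by_animal.values()), dtype=np.int8)
    return GenotypeDataset(list(codes_by_animal), markers, genotypes)


def random_dataset(
    rng: np.random.Generator,
    n_animals: int = 3,
    n_markers: int = 500,
    spacing_kb: float = 12.0,
    het_rate: float = 0.3,
    missing_rate: float = 0.02,
    hom_patch: tuple[int, int] | None = None,
) -> GenotypeDataset:
    """Random genotypes with optional forced-homozygous index patch."""
    positions = np.cumsum(
        rng.exponential(spacing_kb * 1000.0, n_markers).astype(np.int64) + 1
    )
    markers = MarkerMap(
        np.array([f"s{i}" for i in range(n_markers)], dtype=object),
        np.ones(n_markers, dtype=np.int64),
        positions,
    )
    u = rng.random((n_animals, n_markers))
    codes = np.where(
        u < het_rate, 1, np.where(u < het_rate + (1 - het_rate) / 2, 0, 2)
    ).astype(np.int8)
    codes[rng.random((n_animals, n_markers)) < missing_rate] = -1
    if hom_patch is not None:
        lo, hi = hom_patch
        codes[:, lo:hi] = (rng.random((n_animals, hi - lo)) < 0.5).astype(
            np.int8
        ) * 2
    return GenotypeDataset(
        [f"a{i}" for i in range(n_animals)], markers, codes
    )
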