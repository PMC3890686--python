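import numpy as np
import pytest

from barcodegap import (
    AlignedMatrix,
    BarcodeDataset,
    DistanceMatrix,
    SimulationConfig,
    SpecimenRecord,
    build_dataset,
    k2p_matrix,
    simulate_dataset,
)


def make_dataset(labels: dict[str, str]) -> BarcodeDataset:
    """Minimal dataset carrying only IDs and species labels (dummy sequences)."""
    alignment = AlignedMatrix(tuple((sid, "AC") for sid in labels))
    metadata = tuple(
        SpecimenRecord(specimen_id=sid, species_label=sp) for sid, sp in labels.items()
    )
    return build_dataset(alignment, metadata)


def make_dm(ids: tuple[str, ...], d: np.ndarray) -> DistanceMatrix:
    """Distance matrix from a hand-written symmetric array."""
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=tuple(ids), d=d, n_sites=np.full_like(d, 100, dtype=int))


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric zero-diagonal matrix (valid metric not required)."""
    m = rng.random((n, n)) * 0.2
    d = np.triu(m, 1)
    d = d + d.T
    return make_dm(tuple(f"S{i}" for i in range(n)), d)


@pytest.fixture(scope="session")
def study_sim():
    """Paper-scale synthetic dataset: 5 species x {9,12,4,11,20}, 654 bp,
    5 injected mislabels, fixed seed."""
    return simulate_dataset(
        SimulationConfig(seed=42, inter_depth=0.073, n_mislabels=5)
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Same conditions without mislabels (observed labels == truth)."""
    return simulate_dataset(SimulationConfig(seed=42, inter_depth=0.073))


@pytest.fixture(scope="session")
def study_dm(study_sim):
    return k2p_matrix(study_sim.dataset)


@pytest.fixture(scope="session")
def clean_dm(clean_sim):
    return k2p_matrix(clean_sim.dataset)
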