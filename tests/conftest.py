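"""Shared fixtures: small hand-checkable matrices and random-matrix factories."""

import numpy as np
import pytest

from prwr.core_data import EnvironmentTable, OccurrenceMatrix


@pytest.fixture
def tiny_occ() -> OccurrenceMatrix:
    """3 sites x 4 species with nested species sets (a ⊃ b ⊃ c)."""
    return OccurrenceMatrix(
        site_ids=np.array(["a", "b", "c"], dtype=object),
        species_ids=np.array(["sp1", "sp2", "sp3", "sp4"], dtype=object),
        presence=np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [1, 0, 0, 0],
            ]
        ),
    )


@pytest.fixture
def disjoint_occ() -> OccurrenceMatrix:
    """3 sites with disjoint species sets of sizes 5, 3, 1."""
    presence = np.zeros((3, 9), dtype=int)
    presence[0, :5] = 1
    presence[1, 5:8] = 1
    presence[2, 8] = 1
    return OccurrenceMatrix(
        site_ids=np.array(["s1", "s2", "s3"], dtype=object),
        species_ids=np.array([f"sp{i}" for i in range(9)], dtype=object),
        presence=presence,
    )


def random_occurrence(
    rng: np.random.Generator,
    n_sites: int,
    n_species: int,
    density: float = 0.3,
    ensure_occupied: bool = True,
) -> OccurrenceMatrix:
    """Random binary matrix; optionally guarantees every species occurs."""
    presence = (rng.random((n_sites, n_species)) < density).astype(int)
    if ensure_occupied:
        for j in np.flatnonzero(presence.sum(axis=0) == 0):
            presence[rng.integers(n_sites), j] = 1
    return OccurrenceMatrix(
        site_ids=np.array([f"s{i:04d}" for i in range(n_sites)], dtype=object),
        species_ids=np.array([f"sp{j:04d}" for j in range(n_species)], dtype=object),
        presence=presence,
    )


@pytest.fixture
def occ_factory():
    return random_occurrence


@pytest.fixture
def small_env() -> EnvironmentTable:
    rng = np.random.default_rng(42)
    n = 40
    return EnvironmentTable(
        site_ids=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        variable_names=np.array(["temp", "precip", "ndvi"], dtype=object),
        values=rng.standard_normal((n, 3)),
    )
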