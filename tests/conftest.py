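"""Shared fixtures: force-field parameter sets and small conformations."""

import numpy as np
import pytest

from topobraid import (
    BraidSystem,
    Conformation,
    ForceFieldParams,
    UnitSystem,
    build_initial_braid,
)


@pytest.fixture(scope="session")
def defaults() -> ForceFieldParams:
    return ForceFieldParams()


@pytest.fixture(scope="session")
def fine_units() -> UnitSystem:
    return UnitSystem()


@pytest.fixture(scope="session")
def coarse_units() -> UnitSystem:
    return UnitSystem.coarse(5.0)


@pytest.fixture(scope="session")
def coarse_params(coarse_units) -> ForceFieldParams:
    return ForceFieldParams.for_units(coarse_units)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_conformation(rng, n_per_chain=5, n_chains=2, spread=0.8,
                        params=None):
    """Two short chains with bonds safely below R0 and no overlaps."""
    params = params or ForceFieldParams()
    chains = []
    for c in range(n_chains):
        start = np.array([3.0 * c, 0.0, 0.0])
        steps = rng.normal(scale=spread / np.sqrt(3), size=(n_per_chain - 1, 3))
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        steps = steps / norms * rng.uniform(0.85, 1.05, (n_per_chain - 1, 1))
        chains.append(start + np.vstack([np.zeros(3), np.cumsum(steps, 0)]))
    pos = np.vstack(chains)
    cid = np.repeat(np.arange(n_chains), n_per_chain)
    return Conformation(pos, cid)


@pytest.fixture
def small_system() -> BraidSystem:
    """A short braid cheap enough for per-test simulation."""
    return BraidSystem(dna_bp=600, spacing_e_nm=80.0, force_pN=1.0,
                      n_turns=1)


@pytest.fixture(scope="session")
def exemplar_system() -> BraidSystem:
    """The single-crossing assay geometry: 3 kb tethers, 624 nm apart,
    1 pN."""
    return BraidSystem(dna_bp=3000, spacing_e_nm=624.0, force_pN=1.0,
                      n_turns=1)
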