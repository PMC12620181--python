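"""Shared fixtures: default timing and reduced-grid dictionaries.

The reduced grids keep the Bloch simulation cheap while preserving the
structure of the full mapping grids (same ranges, coarser steps)."""

import numpy as np
import pytest

from aquamap.sequence import (
    DictionaryGrid,
    SequenceTiming,
    _default_t1_grid,
    _default_t2_grid,
    build_dictionary,
    build_timing,
)
from aquamap.subspace import compute_basis, project_dictionary


@pytest.fixture(scope="session")
def timing() -> SequenceTiming:
    return build_timing()


@pytest.fixture(scope="session")
def small_grid() -> DictionaryGrid:
    """Coarsened mapping grid with the extended +-300 Hz B0 axis."""
    return DictionaryGrid(
        t1_values=_default_t1_grid()[::6],
        t2_values=_default_t2_grid()[::6],
        b0_values=np.arange(-300.0, 301.0, 60.0),
    )


@pytest.fixture(scope="session")
def small_dictionary(small_grid, timing):
    return build_dictionary(small_grid, timing)


@pytest.fixture(scope="session")
def small_basis(small_dictionary):
    return compute_basis(small_dictionary, k=5)


@pytest.fixture(scope="session")
def small_cdict(small_dictionary, small_basis):
    return project_dictionary(small_dictionary, small_basis)
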