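import numpy as np
import pytest

from ilscreen import (
    DEFAULT_GRID,
    InteractionParams,
    SigmaGrid,
    SigmaProfile,
    SolverSettings,
    load_ion_library,
    make_dha_like,
    make_ion_like,
)


@pytest.fixture(scope="session")
def grid() -> SigmaGrid:
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def params() -> InteractionParams:
    return InteractionParams()


@pytest.fixture(scope="session")
def params_no_hb() -> InteractionParams:
    return InteractionParams(hb_enabled=False)


@pytest.fixture(scope="session")
def settings() -> SolverSettings:
    return SolverSettings()


@pytest.fixture(scope="session")
def library():
    return load_ion_library()


@pytest.fixture(scope="session")
def dha(grid) -> SigmaProfile:
    return make_dha_like(grid)


@pytest.fixture(scope="session")
def ion_profiles(library, grid):
    return {ion.abbreviation: make_ion_like(ion, grid) for ion in library.ions()}


def three_bin_grid() -> SigmaGrid:
    return SigmaGrid(sigma_min=-0.01, sigma_max=0.01, spacing=0.01)


def profile_on(grid: SigmaGrid, areas, compound_id="toy", volume=None) -> SigmaProfile:
    return SigmaProfile(
        compound_id=compound_id,
        grid=grid,
        areas=np.asarray(areas, dtype=float),
        cavity_volume=volume,
    )
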