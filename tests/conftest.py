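import numpy as np
import pytest

from cilpf import engine
from cilpf.params import GridSpec, ModelParams


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def quiet_params() -> ModelParams:
    """Default parameter set with the inhibitor noise switched off."""
    return ModelParams(eta=0.0)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(nx=48, ny=32, dx=1.0, dt=0.04)


@pytest.fixture(scope="session")
def relaxed_cell(quiet_params):
    """One noise-free relaxed migrating cell, shared across the session.

    This is the reference steady state for the calibration checks and
    for tests that need a realistic polarized cell.
    """
    cell, summary = engine.relax_single_cell(quiet_params, seed=0)
    return cell, summary


def smooth_blob(grid: GridSpec, cx: float, cy: float, R: float,
                eps: float = 3.0) -> np.ndarray:
    """Small tanh disk used as a generic smooth test field."""
    from cilpf.domain import init_phase_field
    return init_phase_field(grid, (cx, cy), R, eps).values
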