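import numpy as np
import pytest

from microhet import (ColonyConfig, ExpressionParams, ImagingParams,
                      render_frames, simulate_colony)


@pytest.fixture(scope="session")
def small_imaging():
    return ImagingParams(image_shape=(256, 256))


@pytest.fixture(scope="session")
def small_colony_gt():
    """A ~30-cell constitutive colony reaching stationary phase."""
    cfg = ColonyConfig(n_initial_cells=1, total_duration=240.0,
                       stationary_cell_cap=30, rng_seed=42)
    expr = ExpressionParams(model="constitutive", synthesis_rate_on=2.0)
    return simulate_colony(cfg, expr)


@pytest.fixture(scope="session")
def small_colony_stacks(small_colony_gt, small_imaging):
    return render_frames(small_colony_gt, small_imaging)
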