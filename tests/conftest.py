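import numpy as np
import pytest

from aquaopes import (LangevinSpec, OPESConfig, make_potential, run_opes,
                      synth_water_scene)
from aquaopes.synthetic import SyntheticWaterScene


@pytest.fixture(scope="session")
def double_well_opes():
    """A converged medium-length OPES run on the symmetric double well,
    shared by the FES/reweighting tests."""
    pot = make_potential("double_well_1d", {"h": 5.0})
    spec = LangevinSpec(potential=pot, n_steps=2_000_000, seed=42,
                        friction=10.0, initial_position=(-1.0,))
    config = OPESConfig(barrier=6.0, gamma=10.0, grid=(-2.5, 2.5, 501))
    series, state = run_opes(spec, config)
    return spec, config, series, state


@pytest.fixture(scope="session")
def planted_scene():
    """Default planted water scene + generated trajectory."""
    scene = SyntheticWaterScene(seed=7)
    traj, anchors = synth_water_scene(scene)
    return scene, traj, anchors


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
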