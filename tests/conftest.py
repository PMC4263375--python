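import numpy as np
import pytest

import meiomotion as mm


@pytest.fixture(scope="session")
def pachytene_truth():
    """Short pachytene time-lapse ground truth (3 frames, 7 s)."""
    return mm.simulate_timelapse(mm.make_stage_preset("pachytene"), 3, 7.0, seed=1)


@pytest.fixture(scope="session")
def pachytene_stack(pachytene_truth):
    return mm.render_stack(pachytene_truth, seed=1)


@pytest.fixture(scope="session")
def stack_center(pachytene_stack):
    return np.array(pachytene_stack.meta["center_px_offset_um"])


@pytest.fixture(scope="session")
def sun1_null_cell():
    truth = mm.simulate_timelapse(mm.make_stage_preset("sun1_null"), 2, 7.0, seed=4)
    stack = mm.render_stack(truth, seed=5)
    return truth, stack


@pytest.fixture(scope="session")
def wt_spread():
    return mm.render_spread(mm.make_spread_preset("wt"), seed=2)


@pytest.fixture(scope="session")
def sphere_preset():
    """Pachytene preset with all envelope deformation switched off."""
    import dataclasses

    return dataclasses.replace(mm.make_stage_preset("pachytene"),
                               deform_amplitude=0.0, static_deform=0.0)


@pytest.fixture(scope="session")
def sphere_stack(sphere_preset):
    truth = mm.simulate_timelapse(sphere_preset, 2, 7.0, seed=9)
    return mm.render_stack(truth, seed=9)
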