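import numpy as np
import pytest

from cuttlecamo.arena import ArenaSpec, ReflectanceField, build_arena
from cuttlecamo.camo_model import make_csa_mask
from cuttlecamo.synthetic_data import CalibrationConstants, load_default_calibration


@pytest.fixture(scope="session")
def default_mask():
    return make_csa_mask()


@pytest.fixture(scope="session")
def calib() -> CalibrationConstants:
    return load_default_calibration()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def arena_60() -> ArenaSpec:
    return ArenaSpec(patch_width_cm=60.0)


@pytest.fixture(scope="session")
def field_60(arena_60) -> ReflectanceField:
    return build_arena(arena_60)
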