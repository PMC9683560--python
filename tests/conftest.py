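import numpy as np
import pytest

from fundusmt.models import TINY, build_csp_unet, build_branch1, build_mtnet, build_model
from fundusmt.synthetic import SynthConfig, dr_batch, vessel_batch
from fundusmt.training import GradeData, SegData


@pytest.fixture(scope="session")
def small_vessel_data() -> SegData:
    """8 synthetic vessel pairs at 64x64 for fast training smoke tests."""
    cfg = SynthConfig(size=64, seed=7)
    images, masks = vessel_batch(cfg, range(8))
    return SegData(images, masks)


@pytest.fixture(scope="session")
def small_dr_data() -> GradeData:
    """8 synthetic graded images at 64x64."""
    cfg = SynthConfig(size=64, seed=8)
    images, grades = dr_batch(cfg, 8)
    return GradeData(images, grades)


@pytest.fixture()
def tiny_mtnet():
    return build_model(build_mtnet(TINY), seed=0)


@pytest.fixture()
def tiny_unet():
    return build_model(build_csp_unet(TINY), seed=0)
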