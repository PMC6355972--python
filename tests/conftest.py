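import numpy as np
import pytest

from cellvol3d import morphometry, phantoms


@pytest.fixture(scope="session")
def sphere_r5_iso():
    """Noise-free digitized r=5 µm sphere at 0.2 µm isotropic spacing."""
    return phantoms.make_sphere_stack(5.0, (0.2, 0.2, 0.2))


@pytest.fixture(scope="session")
def sphere_r5_iso_records(sphere_r5_iso):
    stack, truth = sphere_r5_iso
    thr = morphometry.select_threshold(stack)
    mask = morphometry.segment_cells(stack, thr)
    return morphometry.measure_cells(mask), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
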