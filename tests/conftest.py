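import numpy as np
import pytest

from salispect.phantom import PhantomSpec, generate_study
from salispect.volumes import CalibratedVolume, GlandLabelMap


@pytest.fixture(scope="session")
def default_study():
    """One default-resolution noisy study with misalignment."""
    return generate_study(PhantomSpec(seed=1234), 0)


@pytest.fixture(scope="session")
def aligned_noiseless_study():
    """Noiseless study without inter-timepoint motion (exact bookkeeping)."""
    spec = PhantomSpec(
        noiseless=True, misalign_translation_mm=0.0, misalign_rotation_deg=0.0, seed=77
    )
    return generate_study(spec, 0)


@pytest.fixture
def small_ct():
    rng = np.random.default_rng(0)
    vox = rng.normal(40.0, 10.0, (12, 10, 8))
    return CalibratedVolume(voxels=vox, spacing=(2.0, 2.0, 3.0), modality="CT")


@pytest.fixture
def small_labels():
    lab = np.zeros((12, 10, 8), dtype=np.int16)
    lab[2:5, 2:5, 2:5] = 1
    lab[7:10, 2:5, 2:5] = 2
    return GlandLabelMap(labels=lab, spacing=(2.0, 2.0, 3.0))
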