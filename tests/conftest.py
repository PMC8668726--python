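import numpy as np
import pytest

import escapeflight as ef


@pytest.fixture(scope="session")
def params():
    return ef.GroundTruthParams()


@pytest.fixture(scope="session")
def rig():
    return ef.default_rig()


@pytest.fixture(scope="session")
def dlts(rig):
    """Cameras calibrated from a noiseless 30-bead field."""
    field = ef.generate_calibration_field(rig, n_beads=30, seed=42)
    return [ef.fit_dlt(field.positions, field.pixels[ci], camera_id=f"cam{ci}")
            for ci in range(len(rig.cameras))]


@pytest.fixture(scope="session")
def video_study(params):
    """One full synthetic study measured through the videogrammetry chain."""
    return ef.run_study(params, seed=20, mode="video")


@pytest.fixture(scope="session")
def truth_study(params):
    """One synthetic study analysed on generator ground truth."""
    return ef.run_study(params, seed=21, mode="truth")


@pytest.fixture(scope="session")
def noisefree_params(params):
    from dataclasses import replace
    return replace(params, pixel_noise_sd=0.0, bob_amplitude_m=0.0,
                   lateral_wobble_sd_m=0.0)


def truth_by_trial(study):
    return {t.trial_id: t for t in study["trials"]}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
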