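import numpy as np
import pytest

from otoreflex import (CameraGeometry, ReflexParams, make_tilt_schedule,
                       make_translation_profile)


@pytest.fixture
def geometry():
    return CameraGeometry()


@pytest.fixture(scope="session")
def small_translation():
    """Cheap sled profile: 2 round trips at 60 Hz (legs 3-4 still exist)."""
    return make_translation_profile(a_max_g=0.9, v_max_mps=3.25,
                                    n_round_trips=2, rate_hz=60.0)


@pytest.fixture(scope="session")
def small_tilt():
    """Cheap tilt schedule: 0..30 deg steps, short dwells."""
    return make_tilt_schedule(max_deg=30.0, step_deg=10.0, dwell_s=2.0,
                              rate_hz=30.0)


@pytest.fixture
def noise_free_params():
    return ReflexParams(landmark_noise_px=0.0, angle_noise_deg=0.0,
                        gain_jitter_sd=0.0)


def zero_prefixed_series(comps_deg, eye="left", rate_hz=240.0, n_zero=120):
    """EyeSeries whose first n_zero frames are the identity pose, so the
    reconstruction reference window sees a stationary eye."""
    from otoreflex import EyeSeries, components_to_rotvec

    comps = np.vstack([np.zeros((n_zero, 3)), np.atleast_2d(comps_deg)])
    return EyeSeries(time=np.arange(len(comps)) / rate_hz, eye=eye,
                     rotvec=components_to_rotvec(comps), components_deg=comps)
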