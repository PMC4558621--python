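import numpy as np
import pytest

import choroidmap as cm


@pytest.fixture(scope="session")
def cohort_spec():
    return cm.default_cohort_spec()


@pytest.fixture(scope="session")
def low_group(cohort_spec):
    return cohort_spec.groups["low"]


@pytest.fixture(scope="session")
def small_params():
    """Reduced raster for fast unit tests (same physical extent)."""
    return cm.RenderParams(dims=(256, 128, 24))


@pytest.fixture(scope="session")
def clean_params():
    """Default raster, speckle off."""
    return cm.RenderParams(speckle_on=False)


@pytest.fixture(scope="session")
def clean_eye(low_group, clean_params):
    """One motion-free, speckle-free eye with its rendered volume."""
    truth = cm.make_eye_truth(low_group, "OD", 123, motion_amplitude_px=0)
    vol, _ = cm.render_volume(truth, clean_params, seed=5)
    return truth, vol


@pytest.fixture(scope="session")
def speckled_eye(low_group):
    """One eye rendered at the default (speckled, moving) conditions."""
    params = cm.RenderParams()
    truth = cm.make_eye_truth(low_group, "OD", 123)
    vol, motion = cm.render_volume(truth, params, seed=5)
    return truth, vol, motion


def flat_step_bscan(n_axial=60, n_cols=32, row=30, lo=0.1, hi=1.0):
    """Noiseless image that is dark above `row` and bright below."""
    img = np.full((n_axial, n_cols), lo)
    img[row:, :] = hi
    return img
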