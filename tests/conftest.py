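"""Shared fixtures: small synthetic recordings and window sets."""

import numpy as np
import pytest

from gaitspeed.data_io import RawRecording, SensorSelection, convert_units
from gaitspeed.preprocess import make_windows, resample_uniform
from gaitspeed.synthetic import (GaitModelParams, generate_speed_profile,
                                 synthesize_recording)


@pytest.fixture(scope="session")
def toy_matrix():
    """3-row minimal valid 20-column matrix with increasing time."""
    m = np.zeros((3, 20))
    m[:, :18] = np.arange(54).reshape(3, 18)
    m[:, 18] = [5.0, 5.5, 6.0]
    m[:, 19] = [0.0, 0.01, 0.02]
    return m


@pytest.fixture(scope="session")
def synthetic_recording():
    """One ~30 s synthetic subject (raw counts, unconverted)."""
    rng = np.random.default_rng(123)
    params = GaitModelParams.for_subject(rng)
    profile = generate_speed_profile(30.0, rng)
    return synthesize_recording(params, profile, rng, subject_id="T01")


@pytest.fixture(scope="session")
def foot_windows(synthetic_recording):
    """Foot-sensor 2 s windows of the synthetic subject."""
    rec = convert_units(synthetic_recording)
    uni = resample_uniform(rec, sel=SensorSelection(("foot",)))
    return make_windows(uni, stride=512)


@pytest.fixture(scope="session")
def small_cohort():
    """Three short synthetic subjects, converted, for pipeline tests."""
    from gaitspeed.synthetic import synthesize_cohort

    return [convert_units(r) for r in synthesize_cohort(3, 60.0, seed=7)]
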