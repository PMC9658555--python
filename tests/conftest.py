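import numpy as np
import pandas as pd
import pytest

from cgmactivity.cleaning import CleaningConfig
from cgmactivity.records import make_series_frame, SubjectSeries
from cgmactivity.synthetic import SimConfig, generate_cohort


#: Simulator settings that remove every stochastic ingredient except the
#: exercise mechanism itself; used for mechanism and label-recovery checks.
NOISE_FREE = dict(
    cgm_noise_sd=0.0,
    hr_noise_sd=0.0,
    activity_noise_sd=0.0,
    meal_rate=0.0,
    bg_drift=(0.005, 0.0),
    gap_rate=0.0,
    unreported_fraction=0.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 3 days at default (noisy) settings, no 1 Hz streams."""
    return generate_cohort(
        SimConfig(n_subjects=4, days_per_subject=3, seed=42), include_highrate=False
    )


@pytest.fixture(scope="session")
def cleaning_config():
    return CleaningConfig()


def grid_series(
    n_days=1, interval=5, bg=None, hr=None, exercise=None, subject_id="T01", weight=70.0
):
    """A gap-free series on the nominal grid with supplied channel values."""
    n = n_days * 24 * 60 // interval
    ts = pd.Timestamp("2022-03-01") + pd.to_timedelta(
        np.arange(n) * interval, unit="m"
    )
    if bg is None:
        bg = np.full(n, 120.0)
    frame = make_series_frame(ts, bg, hr, exercise)
    return SubjectSeries(subject_id=subject_id, weight=weight, data=frame)
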