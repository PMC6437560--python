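import numpy as np
import pandas as pd
import pytest

from phenoconn.config import CohortConfig
from phenoconn import synthgen


@pytest.fixture(scope="session")
def small_cohort_config():
    """Desk-scale cohort: small grid, short runs, short term."""
    return CohortConfig(n_subjects=4, n_days=25, rng_seed=42,
                        grid_shape=(12, 14, 12), n_frames=120,
                        tr_seconds=2.5, missing_day_rate=0.0,
                        motion_spike_rate=0.03)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return synthgen.generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def one_subject_stream(small_cohort_config):
    sub = synthgen.draw_subjects(small_cohort_config)[0]
    events, schedule = synthgen.generate_phone_stream(sub, small_cohort_config)
    return sub, events, schedule


@pytest.fixture(scope="session")
def one_bold_run(small_cohort_config):
    sub = synthgen.draw_subjects(small_cohort_config)[0]
    run, truth = synthgen.generate_bold_run(sub, small_cohort_config)
    return sub, run, truth


def make_events(rows):
    """Hand-crafted event stream from (event_type, start, end, lat, lon)."""
    return pd.DataFrame(
        [("S0", et, pd.Timestamp(s), pd.Timestamp(e) if e else pd.Timestamp(s),
          lat, lon) for et, s, e, lat, lon in rows],
        columns=["subject_id", "event_type", "start", "end",
                 "latitude", "longitude"])


def full_day_heartbeats(day):
    base = pd.Timestamp(day)
    return [("heartbeat", str(base + pd.Timedelta(hours=h)), None,
             np.nan, np.nan) for h in range(24)]
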