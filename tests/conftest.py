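import dataclasses

import numpy as np
import pandas as pd
import pytest

from vestwear.report import PipelineConfig, run_pipeline
from vestwear.synthetic_cohort import SimParams, simulate_cohort


def make_epochs(
    hr=80.0, st=34.0, hr_conf=90.0, rr_conf=90.0, n=4, activity="stationary",
    start="2019-01-01T08:00:00", battery=90.0, rr=18.0,
):
    """Hand-built epoch frame; scalar arguments broadcast, lists are per-epoch."""

    def col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    ts = pd.date_range(start, periods=n, freq="15s")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "hr": col(hr),
            "rr": col(rr),
            "st": col(st),
            "hr_conf": col(hr_conf),
            "rr_conf": col(rr_conf),
            "activity": col(activity),
            "battery": col(battery),
        }
    )


@pytest.fixture(scope="session")
def small_params():
    return dataclasses.replace(SimParams(), n_aecopd=4, n_stable=5, protocol_days=10)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params, seed=7)


@pytest.fixture(scope="session")
def clean_params():
    """Degenerate regime: no missingness, no schedule or confidence noise."""
    return dataclasses.replace(
        SimParams(),
        n_aecopd=2,
        n_stable=2,
        protocol_days=6,
        p_missing_day=0.0,
        p_missing_day_aecopd=0.0,
        p_battery_depletion_day=0.0,
        daily_wear_sd=0.0,
        daily_wear_between_sd=0.0,
        daily_wear_mean=12.0,
        conf_noise_sd=0.0,
        conf_participant_sd=0.0,
        conf_bmi_slope_hr=0.0,
        conf_adiposity_slope_rr=0.0,
        conf_base_hr=95.0,
        conf_base_rr=95.0,
    )


@pytest.fixture(scope="session")
def full_bundle():
    """One default-condition cohort (35 + 49 participants, 42 days) end to end."""
    return run_pipeline(PipelineConfig(seed=11), write=False)
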