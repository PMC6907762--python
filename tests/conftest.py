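import numpy as np
import pandas as pd
import pytest

from shiftaudit.sessionize import SegmentationParams
from shiftaudit.simulate import SimulationProfile, simulate_study
from shiftaudit.types import Source, make_shift_frame
from shiftaudit.violations import DutyHourRules

UTC_EPOCH = pd.Timestamp("2015-07-06T07:00:00Z")


def ts(minutes) -> pd.DatetimeIndex:
    """Instants at the given minute offsets from a fixed UTC epoch."""
    return UTC_EPOCH + pd.to_timedelta(np.atleast_1d(np.asarray(minutes, dtype=float)), unit="m")


def shifts_at(minute_pairs, trainee="T1", source=Source.EHR_DEFINED) -> pd.DataFrame:
    pairs = np.asarray(minute_pairs, dtype=float)
    return make_shift_frame(trainee, ts(pairs[:, 0]), ts(pairs[:, 1]), source)


def events_at(minutes, trainee="T1", workstation="WS_ON_000") -> pd.DataFrame:
    t = ts(minutes)
    return pd.DataFrame(
        {
            "trainee_id": trainee,
            "timestamp": t,
            "workstation_id": workstation,
            "event_code": "LOGIN",
        }
    )


@pytest.fixture(scope="session")
def rules() -> DutyHourRules:
    return DutyHourRules()


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def minimal_sim():
    """One small simulated study shared across read-only tests."""
    return simulate_study(SimulationProfile.minimal(), seed=7)


def stats_fixture_3x20() -> pd.DataFrame:
    """Frozen 3-group x 20-observation table for statistics cross-checks."""
    rng = np.random.default_rng(20260301)
    vals = np.round(
        np.concatenate([rng.normal(m, 1.0, 20) for m in (0.0, 0.5, 1.0)]), 4
    )
    return pd.DataFrame(
        {"group": np.repeat(["JR_FLC", "SR_FLC", "SR_SUPRV"], 20), "value": vals}
    )
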