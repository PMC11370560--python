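import numpy as np
import pandas as pd
import pytest

from sipflow import stream_io, synthetic_data


@pytest.fixture(scope="session")
def small_cfg():
    """A cheap cohort: 16 animals, 2 days, reduced RFID read rate."""
    return synthetic_data.SimConfig(
        n_males=8, n_females=8, n_days=2, rfid_hz=20.0, seed=11
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    return synthetic_data.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_events(small_fixture):
    """Bouts + attributed events for the small cohort."""
    bouts = stream_io.collapse_visits(small_fixture.rfid, max_gap=1.0)
    result = stream_io.assign_drinks(
        small_fixture.vdm, bouts, small_fixture.animals, small_fixture.stations,
        tolerance=2.0,
    )
    return {"bouts": bouts, "events": result.events, "result": result}


@pytest.fixture()
def toy_roster():
    return pd.DataFrame(
        {
            "tag": ["m1", "m2", "f1", "f2"],
            "sex": ["M", "M", "F", "F"],
            "body_weight_g": [25.0, 20.0, 25.0, 25.0],
            "cage": ["c1", "c1", "c2", "c2"],
        }
    )


@pytest.fixture()
def toy_stations():
    return synthetic_data.DEFAULT_STATIONS.copy()


def make_events(rows):
    """rows: (tag, station, substance, dose_label, t_sec, volume_ul)."""
    return pd.DataFrame(
        rows,
        columns=["tag", "station", "substance", "dose_label", "t_sec", "volume_ul"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
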