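import numpy as np
import pandas as pd
import pytest

import riskdays as rd
from riskdays.synthetic_data import SMU_ORDER, build_lake


def make_detections(rows, tz="UTC"):
    """rows: iterable of (tag_id, receiver_id, timestamp_str[, depth])."""
    recs = []
    for row in rows:
        tag, rec, ts = row[:3]
        depth = row[3] if len(row) > 3 else np.nan
        t = pd.Timestamp(ts)
        t = t.tz_localize(tz) if t.tzinfo is None else t.tz_convert(tz)
        recs.append({"tag_id": tag, "receiver_id": rec,
                     "timestamp": t, "tag_depth_m": depth})
    df = pd.DataFrame(recs)
    return df.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)


@pytest.fixture(scope="session")
def lake():
    cfg = rd.ScenarioConfig()
    smus, receivers = build_lake(cfg)
    return smus, receivers


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study (8 fish, 9 months, spanning the
    hypoxic season)."""
    cfg = rd.ScenarioConfig(seed=42, n_fish=8, n_months=9)
    return rd.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def smu_order():
    return list(SMU_ORDER)
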