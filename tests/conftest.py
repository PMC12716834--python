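import datetime as dt

import pytest

from lifespace.core import LOCAL_TZ, GpsFix, StayNode
from lifespace.pipeline import ModeHeuristicConfig, StopDetectionConfig
from lifespace.synthetic import ScenarioConfig, generate_diary, render_fixes, signatures_for

T0 = dt.datetime(2025, 3, 3, 8, 0, tzinfo=LOCAL_TZ)


def make_fix(seconds: float, lat: float, lon: float, **kw) -> GpsFix:
    return GpsFix(participant_id="p", t=T0 + dt.timedelta(seconds=seconds),
                  lat=lat, lon=lon, **kw)


def make_stop(start_s: float, end_s: float, lat=1.35, lon=103.85,
              node_type="other", **kw) -> StayNode:
    return StayNode(node_id=f"s{start_s}", centroid_lat=lat, centroid_lon=lon,
                    arrive_t=T0 + dt.timedelta(seconds=start_s),
                    depart_t=T0 + dt.timedelta(seconds=end_s),
                    node_type=node_type, **kw)


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(seed=11, days=14)


@pytest.fixture(scope="session")
def participant(scenario):
    """One rendered synthetic participant: (ground truth, fixes, signatures)."""
    gt = generate_diary(scenario)
    fixes = render_fixes(gt, scenario)
    sigs = signatures_for(gt, scenario)
    return gt, fixes, sigs


@pytest.fixture
def stop_cfg():
    return StopDetectionConfig()


@pytest.fixture
def mode_cfg():
    return ModeHeuristicConfig()
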