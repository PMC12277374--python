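import numpy as np
import pytest

from meaburst.core import Periods, WaveformCluster


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def clusters_from_trains(trains: dict, unit_of: dict | None = None):
    """Wrap raw spike-time dicts as WaveformCluster objects (raster-level
    tests need no waveforms)."""
    out = []
    for cid in sorted(trains):
        out.append(WaveformCluster(
            cluster_id=int(cid),
            unit_id=int(unit_of[cid]) if unit_of else int(cid),
            representative_electrode=-1,
            spike_times=np.sort(np.asarray(trains[cid], float)),
            mean_waveform=np.zeros((9, 41))))
    return out


@pytest.fixture
def short_periods():
    return Periods.from_durations(60.0, 90.0, 60.0)
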