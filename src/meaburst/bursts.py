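"""Network-burst detection, initiation-point attribution and propagation.

A burst exists wherever some 100 ms window of the pooled spike raster of
all retained waveform clusters contains strictly more than 50 spikes;
overlapping qualifying windows merge into one burst whose onset is the
first contained spike. The cluster owning the earliest spike at or after
the onset is the burst initiator, and mapping it to its recording-unit
position gives the burst initiation point. Clusters initiating fewer than
three bursts are dropped from the initiator table.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Burst, ElectrodeLayout, Periods, WaveformCluster
from .params import BurstParams


def pooled_raster(clusters: Sequence[WaveformCluster]) -> np.ndarray:
    if not clusters:
        return np.empty(0)
    return np.sort(np.concatenate([c.spike_times for c in clusters]))


def detect_bursts(pooled: np.ndarray, params: BurstParams | None = None
                  ) -> list[Burst]:
    """Sliding-window burst detection on a sorted pooled spike raster.

    The window advances spike-by-spike (event-driven): the window anchored
    at spike ``i`` spans the closed interval ``[t_i, t_i + window]`` and
    qualifies when it holds more than ``min_spikes`` spikes. Overlapping
    qualifying windows are merged; each merged region becomes one burst
    with onset at its first spike and offset at its last.
    """
    params = params or BurstParams()
    t = np.asarray(pooled, dtype=np.float64)
    if np.any(np.diff(t) < 0):
        raise ValueError("pooled spike times must be sorted")
    n = len(t)
    if n == 0:
        return []
    right = np.searchsorted(t, t + params.window, side="right")
    qual = np.nonzero(right - np.arange(n) > params.min_spikes)[0]
    if len(qual) == 0:
        return []
    bursts = []
    start = t[qual[0]]
    end = t[qual[0]] + params.window
    for i in qual[1:]:
        if t[i] <= end:
            end = t[i] + params.window
        else:
            bursts.append(_close_burst(t, start, end))
            start, end = t[i], t[i] + params.window
    bursts.append(_close_burst(t, start, end))
    return bursts


def _close_burst(t: np.ndarray, start: float, end: float) -> Burst:
    i0 = int(np.searchsorted(t, start, side="left"))
    i1 = int(np.searchsorted(t, end, side="right"))
    return Burst(onset=float(t[i0]), offset=float(t[i1 - 1]),
                 spike_count=i1 - i0)


def detect_bursts_per_cluster(clusters: Sequence[WaveformCluster],
                              params: BurstParams | None = None
                              ) -> Dict[int, list[Burst]]:
    """Literal per-cluster reading of the burst rule (alternate mode)."""
    return {c.cluster_id: detect_bursts(c.spike_times, params)
            for c in clusters}


def _first_spike_at_or_after(times: np.ndarray, onset: float) -> float | None:
    i = int(np.searchsorted(times, onset, side="left"))
    return float(times[i]) if i < len(times) else None


def attribute_initiators(bursts: Sequence[Burst],
                         clusters: Sequence[WaveformCluster],
                         params: BurstParams | None = None
                         ) -> tuple[list[Burst], pd.DataFrame]:
    """Assign each burst its initiating cluster and build the initiator table.

    The initiator is the cluster owning the earliest spike at or after the
    burst onset (ties broken by the lowest cluster id); participants are
    all clusters with at least one spike inside ``[onset, offset]``.
    The summary table counts bursts initiated per cluster; clusters below
    ``min_bursts_for_initiator`` (default 3) are excluded from the table
    and their bursts flagged ``initiator_below_threshold``.
    """
    params = params or BurstParams()
    times = {c.cluster_id: c.spike_times for c in clusters}
    unit_of = {c.cluster_id: c.unit_id for c in clusters}
    attributed: list[Burst] = []
    counts: Dict[int, int] = {}
    for b in bursts:
        firsts = []
        participants = []
        for cid in sorted(times):
            ft = _first_spike_at_or_after(times[cid], b.onset)
            if ft is not None and ft <= b.offset:
                participants.append(cid)
                firsts.append((ft, cid))
        if not firsts:
            raise ValueError("burst has no post-onset spike in any cluster")
        ft, cid = min(firsts)
        counts[cid] = counts.get(cid, 0) + 1
        attributed.append(Burst(onset=b.onset, offset=b.offset,
                                spike_count=b.spike_count,
                                participants=tuple(participants),
                                initiator=cid, initiator_unit=unit_of[cid]))
    for b in attributed:
        b.initiator_below_threshold = \
            counts[b.initiator] < params.min_bursts_for_initiator
    table = pd.DataFrame(
        [{"cluster_id": cid, "unit_id": unit_of[cid], "n_initiated": n}
         for cid, n in sorted(counts.items())
         if n >= params.min_bursts_for_initiator],
        columns=["cluster_id", "unit_id", "n_initiated"]).astype(
            {"cluster_id": int, "unit_id": int, "n_initiated": int})
    return attributed, table


def propagation_order(burst: Burst, clusters: Sequence[WaveformCluster]
                      ) -> list[tuple[int, float]]:
    """Participants ordered by their first spike at or after the burst
    onset: ``[(cluster_id, first_spike_time), ...]``, initiator first."""
    times = {c.cluster_id: c.spike_times for c in clusters}
    entries = []
    for cid in burst.participants:
        ft = _first_spike_at_or_after(times[cid], burst.onset)
        if ft is not None and ft <= burst.offset:
            entries.append((ft, cid))
    return [(cid, ft) for ft, cid in sorted(entries)]


def order_similarity(order_a: Sequence[tuple[int, float]],
                     order_b: Sequence[tuple[int, float]]) -> float:
    """Spearman rank correlation of the shared clusters' positions in two
    propagation orders; NaN when fewer than two clusters are shared."""
    rank_a = {cid: i for i, (cid, _) in enumerate(order_a)}
    rank_b = {cid: i for i, (cid, _) in enumerate(order_b)}
    shared = sorted(set(rank_a) & set(rank_b))
    if len(shared) < 2:
        return float("nan")
    ra = [rank_a[c] for c in shared]
    rb = [rank_b[c] for c in shared]
    if len(shared) == 2:  # correlation degenerate but well defined by sign
        return 1.0 if (ra[0] < ra[1]) == (rb[0] < rb[1]) else -1.0
    return float(stats.spearmanr(ra, rb).statistic)


def assign_periods(bursts: Sequence[Burst], periods: Periods) -> list[str]:
    """Period of each burst, by onset time."""
    return [periods.which(b.onset) for b in bursts]


def initiation_point_map(bursts: Sequence[Burst], periods: Periods,
                         layout: ElectrodeLayout) -> pd.DataFrame:
    """Per-period, per-unit count of initiated bursts (Fig-style heat map
    table): columns period, unit_id, x_um, y_um, n_initiated."""
    rows: Dict[tuple, int] = {}
    for b, per in zip(bursts, assign_periods(bursts, periods)):
        if b.initiator_unit is None:
            continue
        key = (per, int(b.initiator_unit))
        rows[key] = rows.get(key, 0) + 1
    records = [{"period": per, "unit_id": u,
                "x_um": layout.unit_positions[u, 0],
                "y_um": layout.unit_positions[u, 1],
                "n_initiated": n}
               for (per, u), n in sorted(rows.items())]
    return pd.DataFrame(records,
                        columns=["period", "unit_id", "x_um", "y_um",
                                 "n_initiated"])


def initiation_point_counts(map_table: pd.DataFrame) -> Dict[str, int]:
    """Number of distinct initiation-point units per period."""
    out = {}
    for per in ("pre", "in", "post"):
        sub = map_table[map_table["period"] == per]
        out[per] = int(sub["unit_id"].nunique())
    return out
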