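"""Ground-truth evaluation helpers for synthetic sessions.

Used to score the pipeline against the simulator's truth: spike-level
recall/precision, sorting-recovery counts, and burst-initiator accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import Burst, GroundTruth, StimLog, WaveformCluster
from .params import DetectionParams


@dataclass(frozen=True)
class SpikeMatch:
    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected \
            else float("nan")


def match_spike_trains(detected: np.ndarray, truth: np.ndarray,
                       tol: float = 0.001) -> SpikeMatch:
    """Greedy one-to-one matching of two sorted spike trains within ``tol``.

    Walks both trains in time order; each truth spike can absorb at most
    one detection. Both trains sorted ascending.
    """
    det = np.asarray(detected, float)
    tru = np.asarray(truth, float)
    i = j = matched = 0
    while i < len(det) and j < len(tru):
        d = det[i] - tru[j]
        if abs(d) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return SpikeMatch(n_truth=len(tru), n_detected=len(det),
                      n_matched=matched)


def recoverable_truth(times: np.ndarray, stim: StimLog | None,
                      params: DetectionParams | None = None) -> np.ndarray:
    """Drop truth spikes inside the artifact-exclusion windows, which the
    pipeline removes by construction."""
    if stim is None or len(stim) == 0:
        return np.asarray(times)
    params = params or DetectionParams()
    t = np.asarray(times)
    keep = np.ones(len(t), bool)
    for on, off in zip(stim.onsets, stim.offsets):
        keep &= ~((t >= on - params.artifact_pre)
                  & (t <= off + params.artifact_post))
    return t[keep]


def session_spike_scores(electrode_spikes, clusters: Sequence[WaveformCluster],
                         truth: GroundTruth, stim: StimLog | None,
                         neuron_of_unit: Mapping[int, int],
                         tol: float = 0.001) -> dict:
    """Pooled spike recall/precision, scored on each unit's representative
    electrode against its resident neuron's recoverable truth train."""
    by_el = {s.electrode_id: s for s in electrode_spikes}
    n_truth = n_det = n_match = 0
    for c in clusters:
        nid = neuron_of_unit[c.unit_id]
        tru = recoverable_truth(truth.spike_times[nid], stim)
        det = by_el[c.representative_electrode].spike_times
        m = match_spike_trains(det, tru, tol)
        n_truth += m.n_truth
        n_det += m.n_detected
        n_match += m.n_matched
    return {"recall": n_match / n_truth if n_truth else float("nan"),
            "precision": n_match / n_det if n_det else float("nan"),
            "n_truth": n_truth, "n_detected": n_det, "n_matched": n_match}


def sorting_recovery(clusters: Sequence[WaveformCluster],
                     truth: GroundTruth, electrode_spikes,
                     layout, neuron_of_unit: Mapping[int, int],
                     min_spikes: int = 50) -> dict:
    """Fraction of units whose retained-cluster count equals the number of
    resident ground-truth neurons with more than ``min_spikes`` detectable
    spikes (one resident neuron per unit in the default sessions)."""
    counts = {u: 0 for u in range(layout.n_units)}
    for c in clusters:
        counts[c.unit_id] += 1
    ok = 0
    for u in range(layout.n_units):
        nid = neuron_of_unit[u]
        expected = 1 if len(truth.spike_times[nid]) > min_spikes else 0
        ok += counts[u] == expected
    return {"fraction_units_correct": ok / layout.n_units,
            "n_units": layout.n_units,
            "n_clusters": len(clusters)}


def initiator_accuracy(bursts: Sequence[Burst], truth: GroundTruth,
                       neuron_of_unit: Mapping[int, int],
                       onset_tol: float = 0.15) -> dict:
    """Fraction of detected bursts whose attributed initiator's unit hosts
    the ground-truth leader of the matching truth burst (matched by onset
    within ``onset_tol`` seconds)."""
    truth_onsets = np.array([e.onset for e in truth.burst_events])
    n_scored = n_correct = 0
    for b in bursts:
        if b.initiator_unit is None or len(truth_onsets) == 0:
            continue
        k = int(np.argmin(np.abs(truth_onsets - b.onset)))
        if abs(truth_onsets[k] - b.onset) > onset_tol:
            continue
        n_scored += 1
        n_correct += (neuron_of_unit[b.initiator_unit]
                      == truth.burst_events[k].leader)
    return {"accuracy": n_correct / n_scored if n_scored else float("nan"),
            "n_scored": n_scored, "n_detected_bursts": len(bursts),
            "n_truth_bursts": len(truth.burst_events)}
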