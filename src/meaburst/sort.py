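"""Waveform sorting: representative electrode, multi-electrode waveform
extraction, 2-D UMAP embedding and DBSCAN density clustering.

Each recording unit (9 electrodes) is sorted independently by default: the
electrode with the most detections becomes the representative electrode,
a 9 x 41-sample waveform is cut around each of its spikes, the flattened
waveforms are embedded to two dimensions (UMAP, 20 neighbours, min_dist
0.2) and clustered (DBSCAN, min_samples 5, radius at the knee of the
k-nearest-neighbour distance curve). Clusters with 50 or fewer spikes are
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .core import ElectrodeSpikes, WaveformCluster
from .params import SortingParams

NOISE_LABEL = -1


class UnsortableUnit(Exception):
    """Raised when a unit has too few waveforms to embed."""


def select_representative(unit_spikes: list[ElectrodeSpikes]) -> int | None:
    """Electrode with the greatest spike count; ties go to the lowest
    electrode id; ``None`` (unit skipped) if no electrode detected anything."""
    best_id, best_n = None, 0
    for sp in sorted(unit_spikes, key=lambda s: s.electrode_id):
        if sp.n_spikes > best_n:
            best_id, best_n = sp.electrode_id, sp.n_spikes
    return best_id


def extract_waveforms(filtered_traces: np.ndarray, spike_times: np.ndarray,
                      sampling_rate: float, halfwidth: int = 20
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut multi-electrode waveform snippets around representative spikes.

    Returns ``(waveforms, kept_times, n_dropped)``; each waveform is
    ``(n_electrodes, 2*halfwidth + 1)`` samples centred on the spike.
    Spikes whose window would overrun the session edge are dropped and
    counted.
    """
    n_el, n_samp = filtered_traces.shape
    centers = np.round(np.asarray(spike_times) * sampling_rate).astype(int)
    ok = (centers - halfwidth >= 0) & (centers + halfwidth + 1 <= n_samp)
    kept = centers[ok]
    waveforms = np.empty((len(kept), n_el, 2 * halfwidth + 1))
    for i, c in enumerate(kept):
        waveforms[i] = filtered_traces[:, c - halfwidth:c + halfwidth + 1]
    return waveforms, np.asarray(spike_times)[ok], int(np.sum(~ok))


def knee_eps(embedding: np.ndarray, min_samples: int) -> float:
    """DBSCAN radius at the knee of the sorted k-distance curve.

    Each point's distance to its ``min_samples``-th neighbour is sorted
    ascending; the knee is the point of maximum discrete second difference
    (where the curve "increases rapidly"). Because the knee belongs to the
    curve's upper tail, the result is floored at the 90th-percentile
    k-distance — the radius must cover the bulk of the population as core
    points, while between-cluster gaps in the embedding are far larger —
    and at a small positive value for degenerate (duplicate-point) inputs.
    """
    k = min(min_samples, len(embedding) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    d = np.sort(nn.kneighbors(embedding)[0][:, -1])
    if len(d) < 3:
        return float(max(d[-1], 1e-9))
    curvature = np.diff(d, 2)
    eps = float(d[int(np.argmax(curvature)) + 1])
    eps = max(eps, float(np.quantile(d, 0.90)))
    return max(eps, 1e-9)


def embed_and_cluster(waveforms: np.ndarray, params: SortingParams | None = None,
                      seed: int = 0, return_embedding: bool = False):
    """UMAP 2-D embedding of flattened waveforms followed by DBSCAN.

    Returns one integer label per waveform (-1 = unassigned noise);
    reproducible for a fixed seed (UMAP runs in its deterministic
    single-threaded mode when a random state is given).
    """
    params = params or SortingParams()
    n = len(waveforms)
    if n < params.n_neighbors + 1:
        raise UnsortableUnit(
            f"{n} waveforms < n_neighbors + 1 = {params.n_neighbors + 1}")
    feats = np.asarray(waveforms, dtype=np.float64).reshape(n, -1)
    if np.all(feats == feats[0]):
        # embedding identical points is ill-posed for UMAP; they are one
        # trivially dense cluster
        labels = np.zeros(n, dtype=int)
        if return_embedding:
            return labels, np.zeros((n, 2))
        return labels

    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=params.n_neighbors,
                            min_dist=params.min_dist, random_state=int(seed))
        emb = reducer.fit_transform(feats)
    emb = np.asarray(emb, dtype=np.float64)
    eps = params.eps if params.eps is not None \
        else knee_eps(emb, params.min_samples)
    labels = DBSCAN(eps=eps, min_samples=params.min_samples).fit_predict(emb)
    if return_embedding:
        return labels, emb
    return labels


def filter_clusters(labels: np.ndarray, waveforms: np.ndarray,
                    spike_times: np.ndarray, unit_id: int,
                    representative_electrode: int,
                    params: SortingParams | None = None,
                    first_cluster_id: int = 0) -> list[WaveformCluster]:
    """Build retained clusters: strictly more than ``min_cluster_spikes``
    members (default >50); the noise label never forms a cluster."""
    params = params or SortingParams()
    out = []
    cid = first_cluster_id
    for lab in np.unique(labels):
        if lab == NOISE_LABEL:
            continue
        mask = labels == lab
        if int(mask.sum()) <= params.min_cluster_spikes:
            continue
        order = np.argsort(spike_times[mask], kind="stable")
        out.append(WaveformCluster(
            cluster_id=cid, unit_id=unit_id,
            representative_electrode=representative_electrode,
            spike_times=np.asarray(spike_times)[mask][order],
            mean_waveform=np.asarray(waveforms)[mask].mean(axis=0)))
        cid += 1
    return out


@dataclass
class UnitSortReport:
    unit_id: int
    representative_electrode: int | None
    n_waveforms: int
    n_edge_dropped: int
    n_noise: int
    status: str   # "ok" | "empty" | "unsortable"


def sort_unit(unit_spikes: list[ElectrodeSpikes], filtered_traces: np.ndarray,
              sampling_rate: float, unit_id: int,
              params: SortingParams | None = None, seed: int = 0,
              first_cluster_id: int = 0
              ) -> tuple[list[WaveformCluster], UnitSortReport]:
    """Full sorting of one recording unit; skips empty/unsortable units."""
    params = params or SortingParams()
    rep = select_representative(unit_spikes)
    if rep is None:
        return [], UnitSortReport(unit_id, None, 0, 0, 0, "empty")
    rep_times = next(s.spike_times for s in unit_spikes
                     if s.electrode_id == rep)
    waveforms, kept, dropped = extract_waveforms(
        filtered_traces, rep_times, sampling_rate, params.waveform_halfwidth)
    try:
        labels = embed_and_cluster(waveforms, params, seed=seed)
    except UnsortableUnit:
        return [], UnitSortReport(unit_id, rep, len(waveforms), dropped, 0,
                                  "unsortable")
    clusters = filter_clusters(labels, waveforms, kept, unit_id, rep,
                               params, first_cluster_id)
    return clusters, UnitSortReport(unit_id, rep, len(waveforms), dropped,
                                    int(np.sum(labels == NOISE_LABEL)), "ok")
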