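"""File formats: HDF5 recordings, CSV tables, JSON configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (ElectrodeLayout, ElectrodeSpikes, GroundTruth, Periods,
                   Recording, StimLog, WaveformCluster)


def write_recording(path, rec: Recording) -> None:
    """Datasets: traces (uV, float32), sampling_rate, period bounds and an
    electrode table (id, position, unit grouping)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=rec.traces.astype(np.float32),
                         chunks=(1, min(rec.n_samples, 1 << 18)))
        f.create_dataset("sampling_rate", data=float(rec.sampling_rate))
        f.create_dataset("period_bounds", data=np.asarray(rec.periods.bounds))
        g = f.create_group("electrodes")
        lay = rec.layout
        g.create_dataset("electrode_id", data=lay.electrode_id)
        g.create_dataset("positions", data=lay.positions)
        g.create_dataset("unit_id", data=lay.unit_id)
        g.create_dataset("unit_positions", data=lay.unit_positions)


def _read_layout(f: h5py.File) -> ElectrodeLayout:
    g = f["electrodes"]
    return ElectrodeLayout(electrode_id=g["electrode_id"][:],
                           positions=g["positions"][:],
                           unit_id=g["unit_id"][:],
                           unit_positions=g["unit_positions"][:])


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(traces=f["traces"][:],
                         sampling_rate=float(f["sampling_rate"][()]),
                         layout=_read_layout(f),
                         periods=Periods(tuple(f["period_bounds"][:])))


def read_recording_meta(path) -> tuple[ElectrodeLayout, float, Periods]:
    with h5py.File(path, "r") as f:
        return (_read_layout(f), float(f["sampling_rate"][()]),
                Periods(tuple(f["period_bounds"][:])))


def read_unit_traces(path, unit: int) -> tuple[np.ndarray, np.ndarray]:
    """Load only the 9 trace rows of one recording unit."""
    with h5py.File(path, "r") as f:
        lay = _read_layout(f)
        ids = lay.electrodes_of_unit(unit)
        rows = np.searchsorted(lay.electrode_id, ids)
        return f["traces"][np.sort(rows), :], ids


def write_stim_log(path, stim: StimLog) -> None:
    stim.to_frame().to_csv(path, index=False)


def read_stim_log(path) -> StimLog:
    df = pd.read_csv(path)
    if len(df) == 0:
        return StimLog.empty()
    width = float(np.median(df["offset_s"] - df["onset_s"]))
    return StimLog.from_frame(df, pulse_width=width)


def write_spike_tables(out_dir, spikes: Sequence[ElectrodeSpikes]) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    spike_rows = [{"electrode_id": s.electrode_id, "time_s": t}
                  for s in spikes for t in s.spike_times]
    spikes_path = out_dir / "spikes.csv"
    pd.DataFrame(spike_rows, columns=["electrode_id", "time_s"])\
        .to_csv(spikes_path, index=False)
    thr_path = out_dir / "thresholds.csv"
    pd.DataFrame([{"electrode_id": s.electrode_id, "mean": s.trace_mean,
                   "sd_est": s.noise_sd_estimate, "threshold": s.threshold,
                   "n_spikes": s.n_spikes, "degenerate": s.degenerate}
                  for s in spikes]).to_csv(thr_path, index=False)
    return spikes_path, thr_path


def write_cluster_tables(out_dir, clusters: Sequence[WaveformCluster]
                         ) -> tuple[Path, Path, Path]:
    out_dir = Path(out_dir)
    ct = out_dir / "clusters.csv"
    pd.DataFrame([{"cluster_id": c.cluster_id, "unit_id": c.unit_id,
                   "n_spikes": c.n_spikes,
                   "representative_electrode": c.representative_electrode}
                  for c in clusters],
                 columns=["cluster_id", "unit_id", "n_spikes",
                          "representative_electrode"]).to_csv(ct, index=False)
    at = out_dir / "assignments.csv"
    rows = [{"cluster_id": c.cluster_id, "time_s": t}
            for c in clusters for t in c.spike_times]
    pd.DataFrame(rows, columns=["cluster_id", "time_s"]).to_csv(at, index=False)
    wt = out_dir / "mean_waveforms.h5"
    with h5py.File(wt, "w") as f:
        for c in clusters:
            f.create_dataset(f"cluster_{c.cluster_id}", data=c.mean_waveform)
    return ct, at, wt


def read_cluster_times(assignments_path, clusters_path=None
                       ) -> Dict[int, np.ndarray]:
    df = pd.read_csv(assignments_path)
    return {int(cid): np.sort(g["time_s"].to_numpy(float))
            for cid, g in df.groupby("cluster_id")}


def read_cluster_units(clusters_path) -> Dict[int, int]:
    df = pd.read_csv(clusters_path)
    return dict(zip(df["cluster_id"].astype(int), df["unit_id"].astype(int)))


def write_ground_truth(out_dir, truth: GroundTruth) -> None:
    out_dir = Path(out_dir)
    rows = [{"neuron_id": nid, "time_s": t}
            for nid in sorted(truth.spike_times)
            for t in truth.spike_times[nid]]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"])\
        .to_csv(out_dir / "truth_spikes.csv", index=False)
    pd.DataFrame([{"onset_s": e.onset, "leader": e.leader,
                   "members": ";".join(map(str, e.members))}
                  for e in truth.burst_events],
                 columns=["onset_s", "leader", "members"])\
        .to_csv(out_dir / "truth_bursts.csv", index=False)


def read_points_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(float)


def write_points_csv(path, points: np.ndarray) -> None:
    pd.DataFrame(points, columns=["x_um", "y_um"]).to_csv(path, index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default, allow_nan=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
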