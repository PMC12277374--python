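"""End-to-end session analysis: detect -> sort -> bursts -> metrics.

Recording units are processed one at a time (streaming), so a full
20 kHz multi-hundred-electrode session never has to be resident in
memory at once. A session can come from an HDF5 file, an in-memory
:class:`~meaburst.core.Recording`, or be synthesized lazily per unit by
the simulator with bit-identical results to a full render.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import (ElectrodeLayout, ElectrodeSpikes, GroundTruth,
                   NeuronTemplate, PERIOD_NAMES, Periods, Recording, StimLog,
                   WaveformCluster)
from .detect import detect_unit
from .params import ActivitySpec, BurstParams, DetectionParams, SortingParams
from .sort import UnitSortReport, sort_unit
from . import bursts as burst_mod
from . import metrics as metric_mod
from . import io as io_mod
from .simulate import synthesize_recording


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class H5TraceProvider:
    """Streams unit traces from a recording HDF5 file."""

    def __init__(self, path):
        self.path = Path(path)
        self.layout, self.sampling_rate, self.periods = \
            io_mod.read_recording_meta(self.path)

    def unit_traces(self, unit: int):
        return io_mod.read_unit_traces(self.path, unit)


class InMemoryTraceProvider:
    def __init__(self, recording: Recording):
        self.rec = recording
        self.layout = recording.layout
        self.sampling_rate = recording.sampling_rate
        self.periods = recording.periods

    def unit_traces(self, unit: int):
        return self.rec.unit_traces(unit), self.layout.electrodes_of_unit(unit)


class SimulatedTraceProvider:
    """Synthesizes each unit's traces on demand (noise streams are keyed by
    electrode id, so per-unit rendering equals slicing a full render)."""

    def __init__(self, layout: ElectrodeLayout,
                 templates: Sequence[NeuronTemplate], truth: GroundTruth,
                 stim: StimLog, periods: Periods, noise_sd: float = 5.0,
                 artifact_amp: float = 30.0, seed: int = 0):
        self.layout = layout
        self.templates = templates
        self.truth = truth
        self.stim = stim
        self.periods = periods
        self.noise_sd = noise_sd
        self.artifact_amp = artifact_amp
        self.seed = seed
        self.sampling_rate = 20_000.0

    def unit_traces(self, unit: int):
        rec = synthesize_recording(self.templates, self.truth, self.stim,
                                   self.layout, noise_sd=self.noise_sd,
                                   artifact_amp=self.artifact_amp,
                                   seed=self.seed, periods=self.periods,
                                   units=[unit])
        return rec.traces, rec.layout.electrode_id


@dataclass
class SessionResult:
    electrode_spikes: list[ElectrodeSpikes]
    sort_reports: list[UnitSortReport]
    clusters: list[WaveformCluster]
    bursts: list
    initiator_table: pd.DataFrame
    initiation_map: pd.DataFrame
    rates: pd.DataFrame
    changes: pd.DataFrame
    metrics: dict


def analyze_session(provider, stim: StimLog | None = None,
                    detection: DetectionParams | None = None,
                    sorting: SortingParams | None = None,
                    burst_params: BurstParams | None = None,
                    bin_width: float = 0.100, seed: int = 0,
                    burst_mode: str = "pooled",
                    units: Iterable[int] | None = None,
                    progress=None) -> SessionResult:
    """Run the full analysis over all (or selected) recording units."""
    detection = detection or DetectionParams()
    sorting = sorting or SortingParams()
    burst_params = burst_params or BurstParams()
    if burst_mode not in ("pooled", "per-cluster"):
        raise ValueError("burst_mode must be 'pooled' or 'per-cluster'")
    layout, periods = provider.layout, provider.periods
    unit_list = list(units) if units is not None else list(range(layout.n_units))

    all_spikes: list[ElectrodeSpikes] = []
    reports: list[UnitSortReport] = []
    clusters: list[WaveformCluster] = []
    for u in unit_list:
        traces, el_ids = provider.unit_traces(u)
        unit_spikes, filtered = detect_unit(traces, el_ids,
                                            provider.sampling_rate, stim,
                                            detection)
        all_spikes.extend(unit_spikes)
        cl, rep = sort_unit(unit_spikes, filtered, provider.sampling_rate,
                            unit_id=u, params=sorting, seed=seed,
                            first_cluster_id=len(clusters))
        clusters.extend(cl)
        reports.append(rep)
        if progress is not None:
            progress(u, rep, cl)

    pooled = burst_mod.pooled_raster(clusters)
    bursts = burst_mod.detect_bursts(pooled, burst_params)
    if clusters and bursts:
        bursts, initiator_table = burst_mod.attribute_initiators(
            bursts, clusters, burst_params)
    else:
        initiator_table = pd.DataFrame(
            columns=["cluster_id", "unit_id", "n_initiated"])
    init_map = burst_mod.initiation_point_map(bursts, periods, layout)

    cluster_times = {c.cluster_id: c.spike_times for c in clusters}
    rates = metric_mod.rates_by_period(cluster_times, periods) if clusters \
        else pd.DataFrame(columns=["cluster_id"])
    changes = metric_mod.change_scores(rates) if clusters else pd.DataFrame()
    metrics = _session_metrics(cluster_times, clusters, bursts, periods,
                               bin_width, init_map)
    return SessionResult(electrode_spikes=all_spikes, sort_reports=reports,
                         clusters=clusters, bursts=bursts,
                         initiator_table=initiator_table,
                         initiation_map=init_map, rates=rates,
                         changes=changes, metrics=metrics)


def _session_metrics(cluster_times, clusters, bursts, periods, bin_width,
                     init_map) -> dict:
    m: dict = {"n_clusters": len(clusters), "n_bursts": len(bursts)}
    if cluster_times:
        dist = metric_mod.presence_distribution(cluster_times, periods)
        m["presence"] = {"".join(map(str, k)): v for k, v in dist.items()}
        m["fraction_not_present_before"] = \
            metric_mod.fraction_not_present_before(dist)
        m["fraction_all_periods"] = metric_mod.fraction_all_periods(dist)
        syn = metric_mod.pairwise_synchrony(cluster_times, periods, bin_width)
        m["synchrony"] = {"bin_width": syn.bin_width, "mean_r": syn.mean_r,
                          "n_pairs": syn.n_pairs,
                          "ratio_in_pre_pct": syn.ratio_in_pre,
                          "ratio_post_pre_pct": syn.ratio_post_pre}
    bf = metric_mod.burst_frequency_change(bursts, periods)
    m["burst_rate_per_min"] = {"pre": bf.rate_pre, "in": bf.rate_in,
                               "post": bf.rate_post}
    m["burst_fold_in"] = bf.fold_in if np.isfinite(bf.fold_in) else None
    m["burst_fold_post"] = bf.fold_post if np.isfinite(bf.fold_post) else None
    m["burst_pre_rate_zero"] = bf.pre_rate_zero
    if clusters:
        m["collective_activity_strength_pct"] = \
            metric_mod.collective_activity_strength(bursts, len(clusters),
                                                    periods)
    m["initiation_point_counts"] = \
        burst_mod.initiation_point_counts(init_map)
    return m


@dataclass
class SessionConfig:
    """Configuration of one full-session run (JSON-serialisable)."""

    recording_path: str
    stim_path: str | None
    out_dir: str
    detection: DetectionParams = field(default_factory=DetectionParams)
    sorting: SortingParams = field(default_factory=SortingParams)
    bursts: BurstParams = field(default_factory=BurstParams)
    bin_width: float = 0.100
    seed: int = 0
    condition: str = "control"
    burst_mode: str = "pooled"

    def __post_init__(self):
        if self.condition not in ("control", "DRG-stim", "SC-stim"):
            raise ValueError("condition must be control, DRG-stim or SC-stim")

    @classmethod
    def from_json(cls, path) -> "SessionConfig":
        raw = io_mod.read_json(path)
        return cls(recording_path=raw["recording_path"],
                   stim_path=raw.get("stim_path"),
                   out_dir=raw["out_dir"],
                   detection=DetectionParams(**raw.get("detection", {})),
                   sorting=SortingParams(**raw.get("sorting", {})),
                   bursts=BurstParams(**raw.get("bursts", {})),
                   bin_width=raw.get("bin_width", 0.100),
                   seed=raw.get("seed", 0),
                   condition=raw.get("condition", "control"),
                   burst_mode=raw.get("burst_mode", "pooled"))

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: SessionConfig) -> SessionResult:
    """Execute the whole pipeline from files, write every stage table and a
    reproducibility manifest; rerunning an identical config reproduces
    byte-identical outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        provider = H5TraceProvider(config.recording_path)
    except Exception as e:
        raise StageError("load-recording", e)

    stim = None
    if config.stim_path is not None:
        try:
            stim = io_mod.read_stim_log(config.stim_path)
        except Exception as e:
            raise StageError("artifact-exclusion (stimulation log)", e)

    try:
        result = analyze_session(provider, stim, config.detection,
                                 config.sorting, config.bursts,
                                 config.bin_width, config.seed,
                                 config.burst_mode)
    except StageError:
        raise
    except Exception as e:
        raise StageError("analysis", e)

    periods = provider.periods
    written = []
    written += list(io_mod.write_spike_tables(out, result.electrode_spikes))
    written += list(io_mod.write_cluster_tables(out, result.clusters))
    bt = out / "bursts.csv"
    pd.DataFrame([{"onset_s": b.onset, "offset_s": b.offset,
                   "n_spikes": b.spike_count,
                   "initiator_cluster": b.initiator,
                   "initiator_unit": b.initiator_unit,
                   "initiator_below_threshold": b.initiator_below_threshold,
                   "n_participants": len(b.participants),
                   "period": periods.which(b.onset)}
                  for b in result.bursts],
                 columns=["onset_s", "offset_s", "n_spikes",
                          "initiator_cluster", "initiator_unit",
                          "initiator_below_threshold", "n_participants",
                          "period"]).to_csv(bt, index=False)
    written.append(bt)
    it = out / "initiator_table.csv"
    result.initiator_table.to_csv(it, index=False)
    written.append(it)
    im = out / "initiation_map.csv"
    result.initiation_map.to_csv(im, index=False)
    written.append(im)
    rt = out / "rates.csv"
    result.rates.to_csv(rt, index=False)
    written.append(rt)
    ch = out / "changes.csv"
    result.changes.to_csv(ch, index=False)
    written.append(ch)
    mj = out / "metrics.json"
    io_mod.write_json(mj, result.metrics)
    written.append(mj)

    manifest = {
        "package": "meaburst",
        "version": __version__,
        "seed": config.seed,
        "condition": config.condition,
        "config": config.to_dict(),
        "input_checksums": {
            "recording": _sha256(Path(config.recording_path)),
            **({"stim": _sha256(Path(config.stim_path))}
               if config.stim_path else {}),
        },
        "output_checksums": {p.name: _sha256(Path(p)) for p in written},
    }
    io_mod.write_json(out / "manifest.json", manifest)
    return result
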