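"""Core data containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

PERIOD_NAMES: Tuple[str, str, str] = ("pre", "in", "post")


@dataclass(frozen=True)
class Periods:
    """Session segmentation into pre-stimulation / stimulation / post periods.

    ``bounds`` holds the four ordered edge times (s); period ``i`` spans
    ``[bounds[i], bounds[i+1])`` (the last period is closed on the right).
    """

    bounds: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        b = self.bounds
        if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
            raise ValueError("period bounds must be four strictly increasing times")

    @classmethod
    def from_durations(cls, pre: float, stim: float, post: float,
                       start: float = 0.0) -> "Periods":
        return cls((start, start + pre, start + pre + stim,
                    start + pre + stim + post))

    @property
    def names(self) -> Tuple[str, str, str]:
        return PERIOD_NAMES

    @property
    def total(self) -> float:
        return self.bounds[3] - self.bounds[0]

    def span(self, name: str) -> Tuple[float, float]:
        i = PERIOD_NAMES.index(name)
        return (self.bounds[i], self.bounds[i + 1])

    def duration(self, name: str) -> float:
        a, b = self.span(name)
        return b - a

    def which(self, t: float) -> str:
        """Period containing time ``t`` (boundaries belong to the later period)."""
        if not (self.bounds[0] <= t <= self.bounds[3]):
            raise ValueError(f"time {t} outside session")
        i = int(np.searchsorted(np.asarray(self.bounds[1:3]), t, side="right"))
        return PERIOD_NAMES[i]

    def mask(self, times: np.ndarray, name: str) -> np.ndarray:
        a, b = self.span(name)
        if name == PERIOD_NAMES[-1]:
            return (times >= a) & (times <= b)
        return (times >= a) & (times < b)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode geometry: ids, 2-D positions (um) and 9-electrode unit grouping."""

    electrode_id: np.ndarray      # (n_electrodes,) int
    positions: np.ndarray         # (n_electrodes, 2) um
    unit_id: np.ndarray           # (n_electrodes,) int
    unit_positions: np.ndarray    # (n_units, 2) um

    def __post_init__(self) -> None:
        n = len(self.electrode_id)
        if self.positions.shape != (n, 2) or self.unit_id.shape != (n,):
            raise ValueError("inconsistent layout arrays")
        counts = np.bincount(self.unit_id, minlength=self.n_units)
        if not np.all(counts == 9):
            raise ValueError("every recording unit must contain exactly 9 electrodes")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_id)

    @property
    def n_units(self) -> int:
        return len(self.unit_positions)

    def electrodes_of_unit(self, unit: int) -> np.ndarray:
        """Electrode ids of one unit, in ascending id order (the fixed row order
        used for multi-electrode waveforms)."""
        ids = self.electrode_id[self.unit_id == unit]
        return np.sort(ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "electrode_id": self.electrode_id,
            "x_um": self.positions[:, 0],
            "y_um": self.positions[:, 1],
            "unit_id": self.unit_id,
            "unit_x_um": self.unit_positions[self.unit_id, 0],
            "unit_y_um": self.unit_positions[self.unit_id, 1],
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectrodeLayout":
        df = df.sort_values("electrode_id").reset_index(drop=True)
        units = df.drop_duplicates("unit_id").sort_values("unit_id")
        return cls(
            electrode_id=df["electrode_id"].to_numpy(int),
            positions=df[["x_um", "y_um"]].to_numpy(float),
            unit_id=df["unit_id"].to_numpy(int),
            unit_positions=units[["unit_x_um", "unit_y_um"]].to_numpy(float),
        )


@dataclass(frozen=True)
class NeuronTemplate:
    """Multi-electrode spike template of one simulated neuron.

    ``waveform`` is a (9, 41) matrix in uV over the electrodes of the home
    unit (rows in ascending electrode-id order); the dominant deflection is
    negative and sits at the centre column. ``amplitude_map`` is the
    per-electrode scaling, 1.0 on exactly one electrode.
    """

    neuron_id: int
    home_unit: int
    waveform: np.ndarray       # (9, 41) uV
    amplitude_map: np.ndarray  # (9,)

    def __post_init__(self) -> None:
        if self.waveform.shape != (9, 41):
            raise ValueError("waveform must be 9 x 41 samples (2 ms at 20 kHz)")
        if np.count_nonzero(self.amplitude_map == self.amplitude_map.max()) != 1:
            raise ValueError("exactly one electrode must carry the peak amplitude")
        peak_row = int(np.argmax(self.amplitude_map))
        if self.waveform[peak_row].min() >= 0:
            raise ValueError("dominant peak must be negative")

    @property
    def peak_electrode_index(self) -> int:
        return int(np.argmax(self.amplitude_map))


@dataclass(frozen=True)
class StimLog:
    """Ordered optical-stimulation pulses: (onset, offset, target neuron)."""

    onsets: np.ndarray    # (n,) s
    offsets: np.ndarray   # (n,) s
    targets: np.ndarray   # (n,) int
    pulse_width: float = 0.005
    rate: float = 0.2

    def __post_init__(self) -> None:
        if len(self.onsets) and (np.any(np.diff(self.onsets) <= 0)
                                 or np.any(self.offsets[:-1] > self.onsets[1:])):
            raise ValueError("pulses must be non-overlapping and strictly increasing")
        if np.any(self.offsets <= self.onsets):
            raise ValueError("offsets must exceed onsets")

    def __len__(self) -> int:
        return len(self.onsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_s": self.onsets, "offset_s": self.offsets,
                             "target": self.targets})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, pulse_width: float = 0.005,
                   rate: float = 0.2) -> "StimLog":
        return cls(df["onset_s"].to_numpy(float), df["offset_s"].to_numpy(float),
                   df["target"].to_numpy(int), pulse_width=pulse_width, rate=rate)

    @classmethod
    def empty(cls) -> "StimLog":
        z = np.empty(0)
        return cls(z, z.copy(), np.empty(0, int))


@dataclass(frozen=True)
class BurstEvent:
    """Simulator-side truth for one network burst."""

    onset: float
    members: Tuple[int, ...]
    leader: int


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth: spike trains, burst events, artifact windows."""

    spike_times: Dict[int, np.ndarray]
    burst_events: Tuple[BurstEvent, ...]
    artifact_windows: np.ndarray   # (n, 2) s

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.spike_times.values())


@dataclass(frozen=True)
class Recording:
    """Multi-channel extracellular recording (uV) at a fixed sampling rate."""

    traces: np.ndarray          # (n_electrodes, n_samples) uV
    sampling_rate: float
    layout: ElectrodeLayout
    periods: Periods

    def __post_init__(self) -> None:
        if self.traces.shape[0] != self.layout.n_electrodes:
            raise ValueError("one trace row per layout electrode required")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def unit_traces(self, unit: int) -> np.ndarray:
        ids = self.layout.electrodes_of_unit(unit)
        rows = np.searchsorted(self.layout.electrode_id, ids)
        return self.traces[rows]


@dataclass(frozen=True)
class ElectrodeSpikes:
    """Detected spike times (s) of one electrode plus its threshold report."""

    electrode_id: int
    spike_times: np.ndarray
    threshold: float
    noise_sd_estimate: float
    trace_mean: float
    degenerate: bool = False

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class WaveformCluster:
    """A putative single neuron: spikes sharing a multi-electrode waveform."""

    cluster_id: int
    unit_id: int
    representative_electrode: int
    spike_times: np.ndarray
    mean_waveform: np.ndarray   # (9, 41) uV

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class Burst:
    """A network-synchrony event on the pooled spike raster."""

    onset: float
    offset: float
    spike_count: int
    participants: Tuple[int, ...] = ()
    initiator: int | None = None
    initiator_unit: int | None = None
    initiator_below_threshold: bool = False

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PointSet:
    """Labelled 2-D point pattern (um), e.g. detected nuclei or marker peaks."""

    points: np.ndarray   # (n, 2)
    label: str = ""

    def __post_init__(self) -> None:
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)
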