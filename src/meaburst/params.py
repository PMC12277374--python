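"""Parameter containers for every pipeline stage.

Each analysis constant of the published pipeline (filter band, MAD scale,
threshold multiplier, refractory period, artifact window, waveform length,
UMAP/DBSCAN settings, cluster- and burst-size rules, colocalization radius)
surfaces here as a named, defaulted field so that deviations are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection settings.

    Attributes
    ----------
    band_low, band_high : float
        Bandpass corner frequencies in Hz (default 100-3000 Hz).
    threshold_multiplier : float
        Threshold in units of the robust noise SD (default 5).
    mad_scale : float
        Gaussian consistency constant for the MAD noise estimator
        (0.6745; the estimated SD is MAD / 0.6745).
    refractory : float
        Minimum inter-spike interval in seconds; detections closer than
        this to the previously kept spike are dropped (default 2 ms).
    artifact_pre, artifact_post : float
        Exclusion margins (s) around each stimulation pulse: spikes in
        [onset - artifact_pre, offset + artifact_post] are removed.
    filter_order : int
        Butterworth order (applied forward-backward, i.e. zero phase).
    """

    band_low: float = 100.0
    band_high: float = 3000.0
    threshold_multiplier: float = 5.0
    mad_scale: float = 0.6745
    refractory: float = 0.002
    artifact_pre: float = 0.001
    artifact_post: float = 0.001
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")
        if self.artifact_pre < 0 or self.artifact_post < 0:
            raise ValueError("artifact margins must be >= 0")


@dataclass(frozen=True)
class SortingParams:
    """Waveform-sorting settings (UMAP embedding + DBSCAN clustering).

    ``eps=None`` selects the DBSCAN radius automatically at the knee of
    the sorted k-nearest-neighbour distance curve (k = ``min_samples``);
    a fixed value can be given for exact reproducibility.
    ``min_cluster_spikes`` is exclusive: clusters with that many spikes
    or fewer are discarded (default 50).
    """

    n_neighbors: int = 20
    min_dist: float = 0.2
    min_samples: int = 5
    eps: float | None = None
    min_cluster_spikes: int = 50
    waveform_halfwidth: int = 20  # samples each side of the peak -> 41 total

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_cluster_spikes < 0:
            raise ValueError("min_cluster_spikes must be >= 0")
        if self.eps is not None and self.eps <= 0:
            raise ValueError("eps must be > 0 when given")


@dataclass(frozen=True)
class BurstParams:
    """Network-burst settings.

    A burst requires strictly more than ``min_spikes`` pooled spikes
    inside a ``window``-second sliding window (default >50 in 100 ms);
    clusters initiating fewer than ``min_bursts_for_initiator`` bursts
    are dropped from the initiator table (default 3).
    """

    window: float = 0.100
    min_spikes: int = 50
    min_bursts_for_initiator: int = 3

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")


@dataclass(frozen=True)
class ActivitySpec:
    """Statistical structure of a simulated session.

    Rates are per neuron; burst rates are events per minute per period.
    ``leader_ids`` maps each period name to the neuron ids allowed to
    initiate bursts there; ``inactive_ids`` lists neurons that emit no
    spikes before stimulation onset. Both default to ``None`` and are
    then filled by :func:`meaburst.simulate.generate_population`
    (one pre-stimulation leader; two additional, previously inactive,
    leaders during stimulation of which one persists afterwards; 40 %
    of neurons initially inactive).
    """

    baseline_rate: float = 0.2
    stim_response_prob: float = 0.5
    burst_rate_pre: float = 2.0
    burst_rate_in: float = 6.0
    burst_rate_post: float = 4.0
    leader_ids: Mapping[str, Sequence[int]] | None = None
    inactive_ids: Sequence[int] | None = None
    propagation_delay: float = 0.003
    within_burst_spikes: int = 5
    intra_burst_isi: float = 0.004
    burst_member_fraction: float = 1.0
    stim_rate: float = 0.2
    stim_pulse_width: float = 0.005
    stim_latency: float = 0.003
    min_burst_separation: float = 1.0
    inactive_fraction: float = 0.4

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "burst_rate_pre", "burst_rate_in",
                     "burst_rate_post", "stim_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.propagation_delay < 0:
            raise ValueError("propagation_delay must be >= 0")
        if not 0 <= self.stim_response_prob <= 1:
            raise ValueError("stim_response_prob must be in [0, 1]")
        if not 0 <= self.burst_member_fraction <= 1:
            raise ValueError("burst_member_fraction must be in [0, 1]")
        if self.within_burst_spikes < 1:
            raise ValueError("within_burst_spikes must be >= 1")


def params_to_dict(params) -> dict:
    return asdict(params)
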