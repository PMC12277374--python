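"""Per-electrode spike detection.

Pipeline: zero-phase Butterworth bandpass (100-3000 Hz) -> robust noise
estimate (median absolute deviation / 0.6745) -> negative-threshold
crossing at mean - 5*SD -> local-minimum spike times -> greedy 2 ms
refractory deduplication -> stimulation-artifact window exclusion.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import ElectrodeSpikes, StimLog
from .params import DetectionParams


def design_bandpass(sampling_rate: float, params: DetectionParams) -> np.ndarray:
    """Second-order sections of the detection bandpass filter."""
    if params.band_high >= sampling_rate / 2:
        raise ValueError("band_high must lie below the Nyquist frequency")
    return signal.butter(params.filter_order,
                         [params.band_low, params.band_high],
                         btype="bandpass", fs=sampling_rate, output="sos")


def bandpass_filter(trace: np.ndarray, sampling_rate: float,
                    params: DetectionParams | None = None) -> np.ndarray:
    """Zero-phase bandpass. Forward-backward filtering preserves spike
    timing, on which the burst-initiator attribution downstream depends."""
    params = params or DetectionParams()
    sos = design_bandpass(sampling_rate, params)
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default warm-up
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) <= padlen:
        raise ValueError("trace must be 1-D and longer than the filter warm-up")
    return signal.sosfiltfilt(sos, trace)


def estimate_threshold(filtered: np.ndarray,
                       params: DetectionParams | None = None
                       ) -> tuple[float, float, float]:
    """Robust threshold estimate for one electrode.

    Returns ``(mean, noise_sd_estimate, threshold)`` where the noise SD is
    ``median(|x - median(x)|) / 0.6745`` and the (negative) threshold is
    ``mean - threshold_multiplier * noise_sd_estimate``: a sample crosses
    when it falls below this value. A degenerate MAD of zero (constant or
    clipped trace) yields ``threshold == mean``, which callers must treat
    as unusable (see :func:`detect_spikes`).
    """
    params = params or DetectionParams()
    x = np.asarray(filtered, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    mu = float(np.mean(x))
    mad = float(np.median(np.abs(x - np.median(x))))
    sd_est = mad / params.mad_scale
    return mu, sd_est, mu - params.threshold_multiplier * sd_est


def _refractory_keep_first(times: np.ndarray, refractory: float) -> np.ndarray:
    """Greedy keep-first rule: drop any spike closer than ``refractory`` to
    the previously *kept* spike; the window restarts at each kept spike."""
    if len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def detect_spikes(filtered: np.ndarray, sampling_rate: float,
                  electrode_id: int = 0,
                  params: DetectionParams | None = None,
                  threshold_info: tuple[float, float, float] | None = None,
                  ) -> ElectrodeSpikes:
    """Find negative-peak spike times on one filtered trace.

    A candidate is any local minimum below the threshold: sample ``i`` with
    ``x[i] < threshold``, ``x[i] <= x[i-1]`` and ``x[i] < x[i+1]`` (the last
    sample of a flat minimum plateau). Candidates are then thinned with the
    greedy keep-first refractory rule (default 2 ms).

    Electrodes with a degenerate noise estimate (MAD = 0, threshold equal
    to the mean) are flagged and return no spikes: their threshold carries
    no information and would otherwise fire on every sample.
    """
    params = params or DetectionParams()
    x = np.asarray(filtered, dtype=np.float64)
    mu, sd_est, thr = threshold_info if threshold_info is not None \
        else estimate_threshold(x, params)
    if sd_est <= 0:
        return ElectrodeSpikes(electrode_id=electrode_id,
                               spike_times=np.empty(0), threshold=thr,
                               noise_sd_estimate=sd_est, trace_mean=mu,
                               degenerate=True)
    inner = x[1:-1]
    cand = np.nonzero((inner < thr) & (inner <= x[:-2]) & (inner < x[2:]))[0] + 1
    times = _refractory_keep_first(cand / sampling_rate, params.refractory)
    return ElectrodeSpikes(electrode_id=electrode_id, spike_times=times,
                           threshold=thr, noise_sd_estimate=sd_est,
                           trace_mean=mu)


def exclude_artifact_spikes(spikes: ElectrodeSpikes, stim: StimLog,
                            params: DetectionParams | None = None
                            ) -> ElectrodeSpikes:
    """Remove spikes inside any stimulation-artifact window.

    Windows are the closed intervals ``[onset - artifact_pre,
    offset + artifact_post]`` (default 1 ms margins); spikes exactly on a
    boundary are excluded. Idempotent, order-preserving.
    """
    params = params or DetectionParams()
    if len(stim) == 0 or spikes.n_spikes == 0:
        return spikes
    if np.any(np.diff(stim.onsets) < 0):
        raise ValueError("stimulation log must be sorted")
    starts = stim.onsets - params.artifact_pre
    ends = stim.offsets + params.artifact_post
    t = spikes.spike_times
    idx = np.searchsorted(starts, t, side="right") - 1
    inside = (idx >= 0) & (t <= ends[np.clip(idx, 0, len(ends) - 1)])
    return ElectrodeSpikes(electrode_id=spikes.electrode_id,
                           spike_times=t[~inside],
                           threshold=spikes.threshold,
                           noise_sd_estimate=spikes.noise_sd_estimate,
                           trace_mean=spikes.trace_mean,
                           degenerate=spikes.degenerate)


def detect_unit(unit_traces: np.ndarray, electrode_ids: np.ndarray,
                sampling_rate: float, stim: StimLog | None = None,
                params: DetectionParams | None = None
                ) -> tuple[list[ElectrodeSpikes], np.ndarray]:
    """Filter + detect + artifact-exclude all electrodes of one unit.

    Returns the per-electrode spike lists and the filtered traces (needed
    later for waveform extraction).
    """
    params = params or DetectionParams()
    filtered = np.empty(unit_traces.shape, dtype=np.float64)
    out = []
    for k, e in enumerate(electrode_ids):
        filtered[k] = bandpass_filter(unit_traces[k], sampling_rate, params)
        sp = detect_spikes(filtered[k], sampling_rate, electrode_id=int(e),
                           params=params)
        if stim is not None:
            sp = exclude_artifact_spikes(sp, stim, params)
        out.append(sp)
    return out, filtered
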