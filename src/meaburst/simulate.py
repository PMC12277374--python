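"""Synthetic HD-MEA session generator with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a DRG/spinal co-culture session: a grid of 9-electrode
recording units, one (by default) low-rate spinal neuron per unit with a
biphasic negative-dominant spike template, network bursts led by
designated initiator neurons with a fixed propagation delay, optical
stimulation pulses that evoke spikes and inject a ramp-shaped artifact,
and additive white Gaussian noise. Everything is deterministic given a
seed, and the per-electrode noise streams are independent so that any
subset of units can be synthesized bit-identically to the full session.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import (BurstEvent, ElectrodeLayout, GroundTruth, NeuronTemplate,
                   PERIOD_NAMES, Periods, PointSet, Recording, StimLog)
from .params import ActivitySpec

SAMPLING_RATE = 20_000.0
WAVEFORM_HALF = 20          # samples each side of the peak -> 41 total
DEFAULT_PITCH = 17.5        # um, typical CMOS-MEA electrode pitch


def generate_layout(n_units: int, pitch: float = DEFAULT_PITCH,
                    seed: int = 0) -> ElectrodeLayout:
    """Arrange ``n_units`` 3x3 electrode patches on a square grid.

    Units are laid out row-major on a grid of ~sqrt(n_units) columns with a
    3-electrode gap between patches; only unit membership and the unit's
    representative position matter downstream, so the geometry is a plain
    square lattice. Deterministic (the seed is accepted for interface
    symmetry but the construction is seed-free).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    grid_cols = int(np.ceil(np.sqrt(n_units)))
    offsets = np.array([(i % 3, i // 3) for i in range(9)], float) * pitch
    positions = np.empty((9 * n_units, 2))
    unit_id = np.repeat(np.arange(n_units), 9)
    unit_positions = np.empty((n_units, 2))
    for u in range(n_units):
        origin = np.array([(u % grid_cols) * 4 * pitch,
                           (u // grid_cols) * 4 * pitch])
        positions[9 * u:9 * u + 9] = origin + offsets
        unit_positions[u] = origin + pitch  # centre electrode of the patch
    return ElectrodeLayout(
        electrode_id=np.arange(9 * n_units),
        positions=positions,
        unit_id=unit_id,
        unit_positions=unit_positions,
    )


def _base_waveform(rng: np.random.Generator, width_jitter: float = 0.15) -> np.ndarray:
    """Peak-normalised biphasic shape: sharp negative lobe followed by a
    slower positive lobe (difference of Gaussians), 41 samples, minimum -1
    at the centre sample."""
    t = np.arange(-WAVEFORM_HALF, WAVEFORM_HALF + 1, dtype=float)
    w_neg = 2.0 * (1 + width_jitter * rng.uniform(-1, 1))
    w_pos = 7.0 * (1 + width_jitter * rng.uniform(-1, 1))
    lag = rng.uniform(5.0, 9.0)
    shape = -np.exp(-0.5 * (t / w_neg) ** 2) \
        + 0.45 * np.exp(-0.5 * ((t - lag) / w_pos) ** 2)
    shape -= shape.mean() * 0.0  # keep raw; bandpass removes any offset anyway
    # renormalise so the global minimum is exactly -1 at the centre
    shape = shape / abs(shape.min())
    shift = int(np.argmin(shape)) - WAVEFORM_HALF
    if shift:
        shape = np.roll(shape, -shift)
    return shape


def _make_template(neuron_id: int, unit: int, layout: ElectrodeLayout,
                   amplitude_uv: float, rng: np.random.Generator,
                   pitch: float) -> NeuronTemplate:
    ids = layout.electrodes_of_unit(unit)
    rows = np.searchsorted(layout.electrode_id, ids)
    pos = layout.positions[rows]
    soma = pos[rng.integers(len(pos))] + rng.uniform(-0.3, 0.3, 2) * pitch
    dist = np.linalg.norm(pos - soma, axis=1)
    amp_map = np.exp(-dist / pitch)
    # break exact ties so exactly one electrode carries the maximum
    order = np.argsort(-amp_map, kind="stable")
    amp_map[order[0]] = max(amp_map[order[0]], amp_map[order[1]] * 1.05 + 1e-9)
    amp_map = amp_map / amp_map.max()
    waveform = amplitude_uv * amp_map[:, None] * _base_waveform(rng)[None, :]
    return NeuronTemplate(neuron_id=neuron_id, home_unit=unit,
                          waveform=waveform, amplitude_map=amp_map)


def _poisson_train(rng: np.random.Generator, rate: float, a: float,
                   b: float) -> np.ndarray:
    if rate <= 0 or b <= a:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, n))


def _thin_refractory(times: np.ndarray, min_isi: float) -> np.ndarray:
    """Greedy keep-first thinning so consecutive spikes are >= min_isi apart."""
    if len(times) < 2:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_isi:
            kept.append(t)
    return np.asarray(kept)


def _default_leaders(active: np.ndarray, inactive: np.ndarray) -> dict:
    """One spontaneous leader before stimulation; stimulation recruits two
    previously inactive leaders, one of which persists afterwards."""
    pre = [int(active[0])]
    recruits = [int(i) for i in inactive[:2]]
    return {"pre": tuple(pre),
            "in": tuple(pre + recruits),
            "post": tuple(pre + recruits[:1])}


def generate_population(layout: ElectrodeLayout, n_neurons: int,
                        spec: ActivitySpec, seed: int,
                        periods: Periods | None = None,
                        amplitude_uv: float = 100.0,
                        pitch: float = DEFAULT_PITCH,
                        ) -> tuple[list[NeuronTemplate], GroundTruth, StimLog]:
    """Draw neuron templates, ground-truth spike trains and a stimulation log.

    Spike trains are homogeneous Poisson at ``spec.baseline_rate`` outside
    bursts; neurons listed in ``spec.inactive_ids`` are silent before the
    stimulation period. Each burst starts with the leader's spike and
    recruits the remaining members at multiples of
    ``spec.propagation_delay``, each member firing
    ``spec.within_burst_spikes`` spikes ``spec.intra_burst_isi`` apart.
    Stimulation pulses run at ``spec.stim_rate`` through the "in" period,
    cycling over neurons; a targeted neuron responds with probability
    ``spec.stim_response_prob`` with one spike ``spec.stim_latency`` after
    the pulse ends. All trains are thinned to a 2.5 ms minimum ISI.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if spec.propagation_delay < 0:
        raise ValueError("propagation_delay must be >= 0")
    periods = periods or Periods.from_durations(1200.0, 1800.0, 1200.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    neuron_ids = np.arange(n_neurons)
    homes = neuron_ids % layout.n_units

    inactive = (np.asarray(sorted(spec.inactive_ids), int)
                if spec.inactive_ids is not None
                else neuron_ids[n_neurons - round(spec.inactive_fraction * n_neurons):])
    if np.any((inactive < 0) | (inactive >= n_neurons)):
        raise ValueError("inactive_ids must be valid neuron ids")
    active = np.setdiff1d(neuron_ids, inactive)
    if len(active) == 0:
        raise ValueError("at least one neuron must be active before stimulation")

    leaders = (dict(spec.leader_ids) if spec.leader_ids is not None
               else _default_leaders(active, inactive))
    for name, ids in leaders.items():
        if not set(map(int, ids)) <= set(map(int, neuron_ids)):
            raise ValueError(f"leader_ids[{name!r}] outside neuron ids")

    templates = [_make_template(int(i), int(homes[i]), layout, amplitude_uv,
                                rng, pitch) for i in neuron_ids]

    t1, t2 = periods.bounds[1], periods.bounds[2]
    stim = _make_stim_log(spec, periods, neuron_ids)

    spikes: dict[int, list] = {int(i): [] for i in neuron_ids}

    # baseline Poisson (inactive neurons start at stimulation onset)
    for i in neuron_ids:
        a = t1 if i in inactive else periods.bounds[0]
        spikes[int(i)].append(_poisson_train(rng, spec.baseline_rate, a,
                                             periods.bounds[3]))

    # stimulation-evoked spikes
    for onset, offset, target in zip(stim.onsets, stim.offsets, stim.targets):
        if rng.uniform() < spec.stim_response_prob:
            spikes[int(target)].append(np.array([offset + spec.stim_latency]))

    # network bursts
    rates = {"pre": spec.burst_rate_pre, "in": spec.burst_rate_in,
             "post": spec.burst_rate_post}
    burst_span = (n_neurons * spec.propagation_delay
                  + spec.within_burst_spikes * spec.intra_burst_isi)
    events: list[BurstEvent] = []
    for name in PERIOD_NAMES:
        a, b = periods.span(name)
        onsets = _poisson_train(rng, rates[name] / 60.0,
                                a + 0.05, b - burst_span - 0.05)
        onsets = _thin_refractory(onsets, spec.min_burst_separation + burst_span)
        pool = (active if name == "pre" else neuron_ids)
        period_leaders = np.asarray(leaders.get(name, ()), int)
        period_leaders = period_leaders[np.isin(period_leaders, pool)]
        if len(period_leaders) == 0:
            period_leaders = pool[:1]
        for k, onset in enumerate(onsets):
            leader = int(period_leaders[k % len(period_leaders)])
            others = pool[pool != leader]
            if spec.burst_member_fraction < 1.0:
                n_take = round(spec.burst_member_fraction * len(pool)) - 1
                others = rng.choice(others, size=max(n_take, 0), replace=False)
            members = [leader] + list(rng.permutation(others))
            for rank, m in enumerate(members):
                first = onset + rank * spec.propagation_delay
                ts = first + np.arange(spec.within_burst_spikes) * spec.intra_burst_isi
                spikes[int(m)].append(ts)
            events.append(BurstEvent(onset=float(onset),
                                     members=tuple(int(m) for m in members),
                                     leader=leader))

    margin = (WAVEFORM_HALF + 1) / SAMPLING_RATE
    truth_spikes = {}
    for i in neuron_ids:
        ts = np.sort(np.concatenate(spikes[int(i)])) if spikes[int(i)] else np.empty(0)
        ts = ts[(ts >= periods.bounds[0] + margin) & (ts <= periods.bounds[3] - margin)]
        truth_spikes[int(i)] = _thin_refractory(ts, 0.0025)

    artifact = np.column_stack([stim.onsets, stim.offsets]) if len(stim) \
        else np.empty((0, 2))
    truth = GroundTruth(spike_times=truth_spikes,
                        burst_events=tuple(events),
                        artifact_windows=artifact)
    return templates, truth, stim


def _make_stim_log(spec: ActivitySpec, periods: Periods,
                   neuron_ids: np.ndarray) -> StimLog:
    if spec.stim_rate <= 0:
        return StimLog.empty()
    a, b = periods.span("in")
    interval = 1.0 / spec.stim_rate
    onsets = np.arange(a + interval / 2, b - spec.stim_pulse_width, interval)
    targets = neuron_ids[np.arange(len(onsets)) % len(neuron_ids)]
    return StimLog(onsets=onsets, offsets=onsets + spec.stim_pulse_width,
                   targets=targets, pulse_width=spec.stim_pulse_width,
                   rate=spec.stim_rate)


def synthesize_recording(templates: Sequence[NeuronTemplate],
                         truth: GroundTruth, stim: StimLog,
                         layout: ElectrodeLayout,
                         noise_sd: float = 5.0,
                         artifact_amp: float = 30.0,
                         seed: int = 0,
                         periods: Periods | None = None,
                         sampling_rate: float = SAMPLING_RATE,
                         units: Iterable[int] | None = None,
                         amp_jitter: float = 0.05) -> Recording:
    """Render voltage traces: templates at spike times + noise + artifact.

    The trace of each electrode is the additive superposition of
    (a) every neuron's template inserted at each ground-truth spike time on
    its home-unit electrodes, (b) white Gaussian noise of SD ``noise_sd``
    (uV), and (c) for every stimulation pulse a linear ramp running from
    ``+artifact_amp`` at onset to ``-artifact_amp`` at offset on all
    electrodes, i.e. step discontinuities at both pulse edges -- the
    minimal shape consistent with a monotonically drifting reference
    potential that jumps when stimulation switches.

    Spike insertions are scaled by a per-spike lognormal-like factor
    ``1 + N(0, amp_jitter)`` (clipped at 0.5) emulating the natural
    spike-to-spike amplitude variability of bursting neurons.

    ``units`` restricts synthesis to a subset of recording units; both the
    per-electrode noise streams and the per-neuron amplitude-jitter
    streams are seeded independently, so the subset is bit-identical to
    the corresponding rows of the full recording.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    periods = periods or Periods.from_durations(1200.0, 1800.0, 1200.0)
    n_samples = int(round(periods.total * sampling_rate))
    unit_list = (sorted(set(int(u) for u in units)) if units is not None
                 else list(range(layout.n_units)))
    for u in unit_list:
        if not 0 <= u < layout.n_units:
            raise ValueError(f"unknown unit {u}")

    sub_ids = np.concatenate([layout.electrodes_of_unit(u) for u in unit_list])
    order = np.argsort(sub_ids)
    sub_ids = sub_ids[order]
    traces = np.zeros((len(sub_ids), n_samples), dtype=np.float32)
    row_of = {int(e): r for r, e in enumerate(sub_ids)}

    # (c) stimulation artifact, common to all electrodes
    artifact = np.zeros(n_samples, dtype=np.float32)
    for onset, offset in zip(stim.onsets, stim.offsets):
        a = int(round(onset * sampling_rate))
        b = int(round(offset * sampling_rate))
        a, b = max(a, 0), min(b, n_samples)
        if b > a:
            artifact[a:b] = np.linspace(artifact_amp, -artifact_amp, b - a,
                                        dtype=np.float32)
    traces += artifact[None, :]

    # (b) independent noise per electrode (stream keyed by electrode id)
    if noise_sd > 0:
        for e in sub_ids:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7, int(e)]))
            traces[row_of[int(e)]] += rng.normal(0.0, noise_sd, n_samples)\
                .astype(np.float32)

    # (a) spike templates
    wanted = set(unit_list)
    for tpl in templates:
        if tpl.home_unit not in wanted:
            continue
        el_ids = layout.electrodes_of_unit(tpl.home_unit)
        rows = np.array([row_of[int(e)] for e in el_ids])
        times = truth.spike_times.get(tpl.neuron_id, np.empty(0))
        centers = np.round(times * sampling_rate).astype(int)
        wf = tpl.waveform.astype(np.float32)
        jrng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 13, int(tpl.neuron_id)]))
        gains = np.clip(1.0 + jrng.normal(0.0, amp_jitter, len(centers)),
                        0.5, None).astype(np.float32) if amp_jitter > 0 \
            else np.ones(len(centers), dtype=np.float32)
        for c, g in zip(centers, gains):
            lo, hi = c - WAVEFORM_HALF, c + WAVEFORM_HALF + 1
            if lo < 0 or hi > n_samples:
                raise ValueError("ground-truth spike outside renderable range")
            traces[rows, lo:hi] += g * wf

    sub_layout = _subset_layout(layout, unit_list)
    return Recording(traces=traces, sampling_rate=sampling_rate,
                     layout=sub_layout, periods=periods)


def _subset_layout(layout: ElectrodeLayout, units: Sequence[int]) -> ElectrodeLayout:
    if len(units) == layout.n_units:
        return layout
    mask = np.isin(layout.unit_id, units)
    remap = {int(u): k for k, u in enumerate(units)}
    return ElectrodeLayout(
        electrode_id=layout.electrode_id[mask],
        positions=layout.positions[mask],
        unit_id=np.array([remap[int(u)] for u in layout.unit_id[mask]]),
        unit_positions=layout.unit_positions[list(units)],
    )


def make_session(n_units: int = 20, seed: int = 0,
                 durations: tuple[float, float, float] = (120.0, 180.0, 120.0),
                 spec: ActivitySpec | None = None,
                 amplitude_uv: float = 100.0):
    """Standard synthetic study session: one neuron per unit, default
    activity structure, 2/3/2-minute periods (a duration-scaled version of
    the 20/30/20-minute protocol; every analysis rule is duration-agnostic).

    Returns ``(layout, templates, truth, stim, periods)``.
    """
    periods = Periods.from_durations(*durations)
    layout = generate_layout(n_units, seed=seed)
    spec = spec or ActivitySpec()
    templates, truth, stim = generate_population(
        layout, n_units, spec, seed=seed, periods=periods,
        amplitude_uv=amplitude_uv)
    return layout, templates, truth, stim, periods


def generate_colocalization_points(n_nuclei: int, n_marker: int,
                                   marker_fraction: float,
                                   jitter_sd: float = 1.0,
                                   field: tuple[float, float] = (1000.0, 1000.0),
                                   seed: int = 0) -> tuple[PointSet, PointSet]:
    """Nuclei uniform over ``field``; a ``marker_fraction`` of them receive a
    Gaussian-jittered marker point, remaining markers fall uniformly."""
    if n_nuclei < 0 or n_marker < 0:
        raise ValueError("counts must be >= 0")
    if not 0 <= marker_fraction <= 1:
        raise ValueError("marker_fraction must be in [0, 1]")
    n_matched = round(marker_fraction * n_nuclei)
    if n_marker < n_matched:
        raise ValueError("n_marker smaller than the matched-marker count")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    nuclei = rng.uniform([0, 0], field, size=(n_nuclei, 2))
    matched = nuclei[:n_matched] + rng.normal(0.0, jitter_sd, (n_matched, 2))
    extra = rng.uniform([0, 0], field, size=(n_marker - n_matched, 2))
    marker = np.vstack([matched, extra]) if n_marker else np.empty((0, 2))
    return (PointSet(points=nuclei, label="NeuN"),
            PointSet(points=marker, label="Peripherin"))
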