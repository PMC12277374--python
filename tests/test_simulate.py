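"""Synthetic session generator: layout, population statistics, rendering."""

import numpy as np
import pytest

from meaburst.core import Periods
from meaburst.params import ActivitySpec
from meaburst.simulate import (generate_colocalization_points, generate_layout,
                               generate_population, synthesize_recording)


class TestLayout:
    def test_single_unit(self):
        lay = generate_layout(1)
        assert lay.n_electrodes == 9
        assert np.all(lay.unit_id == 0)

    def test_paper_scale_unit_count(self):
        lay = generate_layout(110)
        assert lay.n_electrodes == 990
        assert lay.n_units == 110

    def test_deterministic(self):
        a, b = generate_layout(4, seed=7), generate_layout(4, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.unit_id, b.unit_id)

    def test_unit_membership_invariants(self):
        lay = generate_layout(12)
        for u in range(12):
            ids = lay.electrodes_of_unit(u)
            assert len(ids) == 9
            pos = lay.positions[np.searchsorted(lay.electrode_id, ids)]
            assert len(np.unique(pos, axis=0)) == 9  # mutually distinct

    @pytest.mark.parametrize("n_units,pitch", [(0, 17.5), (-1, 17.5), (3, 0.0)])
    def test_invalid_arguments(self, n_units, pitch):
        with pytest.raises(ValueError):
            generate_layout(n_units, pitch=pitch)


class TestPopulation:
    def test_zero_rates_give_empty_trains(self):
        lay = generate_layout(3)
        spec = ActivitySpec(baseline_rate=0.0, burst_rate_pre=0.0,
                            burst_rate_in=0.0, burst_rate_post=0.0,
                            stim_response_prob=0.0)
        per = Periods.from_durations(30, 45, 30)
        _, truth, _ = generate_population(lay, 3, spec, seed=0, periods=per)
        assert truth.n_spikes == 0

    def test_stimulation_pulse_count_30min_at_0p2hz(self):
        # 0.2 Hz over an 1800 s stimulation period -> 360 pulses
        lay = generate_layout(2)
        per = Periods.from_durations(60, 1800, 60)
        _, _, stim = generate_population(lay, 2, ActivitySpec(), seed=0,
                                         periods=per)
        assert len(stim) == 360
        assert np.allclose(stim.offsets - stim.onsets, 0.005)
        a, b = per.span("in")
        assert stim.onsets[0] >= a and stim.offsets[-1] <= b

    def test_leader_first_spike_precedes_members(self):
        lay = generate_layout(5)
        spec = ActivitySpec(baseline_rate=0.0, propagation_delay=0.005,
                            burst_rate_pre=6, burst_rate_in=6,
                            burst_rate_post=6, stim_response_prob=0.0,
                            inactive_ids=())
        per = Periods.from_durations(60, 60, 60)
        _, truth, _ = generate_population(lay, 5, spec, seed=3, periods=per)
        assert len(truth.burst_events) > 0
        for ev in truth.burst_events:
            firsts = {}
            for m in ev.members:
                t = truth.spike_times[m]
                sel = t[(t >= ev.onset - 1e-9)]
                firsts[m] = sel[0]
            leader_first = firsts.pop(ev.leader)
            for m, ft in firsts.items():
                assert ft >= leader_first + 0.005 - 1e-9

    def test_inactive_neurons_silent_before_stimulation(self):
        lay = generate_layout(6)
        spec = ActivitySpec(baseline_rate=1.0, inactive_ids=(4, 5))
        per = Periods.from_durations(60, 90, 60)
        _, truth, _ = generate_population(lay, 6, spec, seed=4, periods=per)
        for nid in (4, 5):
            assert np.all(truth.spike_times[nid] >= per.bounds[1])
        for nid in (0, 1, 2, 3):
            assert np.any(truth.spike_times[nid] < per.bounds[1])

    def test_spike_trains_sorted_within_session_and_refractory(self):
        lay = generate_layout(4)
        per = Periods.from_durations(60, 90, 60)
        _, truth, _ = generate_population(lay, 4, ActivitySpec(
            baseline_rate=2.0), seed=5, periods=per)
        for t in truth.spike_times.values():
            assert np.all(np.diff(t) >= 0.0025 - 1e-12)
            if len(t):
                assert t[0] >= 0 and t[-1] <= per.total

    def test_deterministic_given_seed(self):
        lay = generate_layout(4)
        per = Periods.from_durations(30, 45, 30)
        out = []
        for _ in range(2):
            _, truth, stim = generate_population(lay, 4, ActivitySpec(),
                                                 seed=9, periods=per)
            out.append((truth, stim))
        for nid in out[0][0].spike_times:
            assert np.array_equal(out[0][0].spike_times[nid],
                                  out[1][0].spike_times[nid])
        assert np.array_equal(out[0][1].onsets, out[1][1].onsets)

    def test_poisson_counts_within_four_sigma(self):
        # burst_rate = 0: per-neuron counts ~ Poisson(rate * T)
        lay = generate_layout(20)
        spec = ActivitySpec(baseline_rate=2.0, burst_rate_pre=0,
                            burst_rate_in=0, burst_rate_post=0,
                            stim_response_prob=0.0, inactive_ids=())
        per = Periods.from_durations(20, 30, 20)
        lam = 2.0 * per.total
        bad = total = 0
        for seed in range(5):
            _, truth, _ = generate_population(lay, 20, spec, seed=seed,
                                              periods=per)
            for t in truth.spike_times.values():
                total += 1
                bad += abs(len(t) - lam) > 4 * np.sqrt(lam)
        assert bad / total <= 0.01

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            ActivitySpec(propagation_delay=-0.001)


class TestSynthesize:
    def _tiny(self, **spec_kw):
        lay = generate_layout(2)
        per = Periods.from_durations(5, 5, 5)
        spec = ActivitySpec(**spec_kw)
        tpl, truth, stim = generate_population(lay, 2, spec, seed=1,
                                               periods=per)
        return lay, per, tpl, truth, stim

    def test_silence_renders_zero(self):
        lay, per, tpl, truth, stim = self._tiny(
            baseline_rate=0, burst_rate_pre=0, burst_rate_in=0,
            burst_rate_post=0, stim_response_prob=0, stim_rate=0)
        rec = synthesize_recording(tpl, truth, stim, lay, noise_sd=0,
                                   artifact_amp=0, seed=1, periods=per)
        assert np.all(rec.traces == 0)

    def test_single_spike_minimum_at_spike_time(self):
        lay, per, tpl, truth, stim = self._tiny(
            baseline_rate=0, burst_rate_pre=0, burst_rate_in=0,
            burst_rate_post=0, stim_response_prob=0, stim_rate=0)
        t_spike = 2.0
        truth.spike_times[0] = np.array([t_spike])
        rec = synthesize_recording(tpl, truth, stim, lay, noise_sd=0,
                                   artifact_amp=0, seed=1, periods=per,
                                   amp_jitter=0.0)
        peak_el = lay.electrodes_of_unit(0)[tpl[0].peak_electrode_index]
        row = int(np.searchsorted(rec.layout.electrode_id, peak_el))
        tmin = np.argmin(rec.traces[row]) / rec.sampling_rate
        assert abs(tmin - t_spike) <= 0.001

    def test_artifact_ramp_peaks_at_pulse_boundary(self):
        lay, per, tpl, truth, stim = self._tiny(
            baseline_rate=0, burst_rate_pre=0, burst_rate_in=0,
            burst_rate_post=0, stim_response_prob=0)
        for nid in truth.spike_times:
            truth.spike_times[nid] = np.empty(0)
        rec = synthesize_recording(tpl, truth, stim, lay, noise_sd=0,
                                   artifact_amp=200.0, seed=1, periods=per)
        fs = rec.sampling_rate
        for on, off in zip(stim.onsets, stim.offsets):
            a, b = int(round(on * fs)), int(round(off * fs))
            seg = rec.traces[0, a:b]
            assert np.isclose(np.abs(seg).max(), 200.0)
            assert np.isclose(seg[0], 200.0)     # step at onset
            assert np.isclose(seg[-1], -200.0)   # step at offset
            # zero strictly outside the pulse
            assert rec.traces[0, a - 1] == 0 and rec.traces[0, b] == 0

    def test_unit_subset_is_bit_identical_to_full_render(self):
        lay = generate_layout(3)
        per = Periods.from_durations(4, 4, 4)
        tpl, truth, stim = generate_population(lay, 3, ActivitySpec(
            baseline_rate=3.0), seed=6, periods=per)
        full = synthesize_recording(tpl, truth, stim, lay, seed=6,
                                    periods=per)
        sub = synthesize_recording(tpl, truth, stim, lay, seed=6,
                                   periods=per, units=[1])
        ids = lay.electrodes_of_unit(1)
        rows = np.searchsorted(full.layout.electrode_id, ids)
        assert np.array_equal(full.traces[rows], sub.traces)

    def test_template_insertion_count_matches_truth(self):
        # conservation: with zero noise every negative excursion below half
        # the template peak on the peak electrode is one inserted spike
        lay = generate_layout(1)
        per = Periods.from_durations(4, 4, 4)
        spec = ActivitySpec(baseline_rate=4.0, burst_rate_pre=0,
                            burst_rate_in=0, burst_rate_post=0,
                            stim_response_prob=0, stim_rate=0,
                            inactive_ids=())
        tpl, truth, stim = generate_population(lay, 1, spec, seed=8,
                                               periods=per)
        rec = synthesize_recording(tpl, truth, stim, lay, noise_sd=0,
                                   artifact_amp=0, seed=8, periods=per,
                                   amp_jitter=0.0)
        row = tpl[0].peak_electrode_index
        x = rec.traces[row]
        below = x < tpl[0].waveform.min() / 2
        n_excursions = int(np.sum(np.diff(below.astype(int)) == 1)
                           + (1 if below[0] else 0))
        assert n_excursions == len(truth.spike_times[0]) == truth.n_spikes


class TestColocalizationGenerator:
    def test_zero_fraction_no_markers(self):
        nuc, mrk = generate_colocalization_points(50, 0, 0.0, seed=0)
        assert len(nuc) == 50 and len(mrk) == 0

    def test_full_fraction_zero_jitter_coincides(self):
        nuc, mrk = generate_colocalization_points(40, 40, 1.0, jitter_sd=0.0,
                                                  seed=1)
        assert np.allclose(np.sort(nuc.points, axis=0),
                           np.sort(mrk.points, axis=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_colocalization_points(-1, 0, 0.5)

    def test_deterministic(self):
        a = generate_colocalization_points(30, 40, 0.5, seed=3)
        b = generate_colocalization_points(30, 40, 0.5, seed=3)
        assert np.array_equal(a[0].points, b[0].points)
        assert np.array_equal(a[1].points, b[1].points)
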