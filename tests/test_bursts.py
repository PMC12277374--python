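"""Network bursts: detection, initiator attribution, propagation order."""

import numpy as np
import pytest

from meaburst.core import Periods
from meaburst.params import ActivitySpec, BurstParams
from meaburst.bursts import (assign_periods, attribute_initiators,
                             detect_bursts, detect_bursts_per_cluster,
                             initiation_point_counts, initiation_point_map,
                             order_similarity, pooled_raster,
                             propagation_order)
from meaburst.simulate import generate_layout, generate_population

from conftest import clusters_from_trains


def brute_force_bursts(times, window=0.100, min_spikes=50):
    """Independent O(n^2) oracle: for every spike count companions in its
    closed window, merge overlapping qualifying windows, report
    (onset, offset, count) per merged region."""
    t = np.sort(np.asarray(times, float))
    qual = []
    for i in range(len(t)):
        cnt = sum(1 for u in t if t[i] <= u <= t[i] + window)
        if cnt > min_spikes:
            qual.append((t[i], t[i] + window))
    if not qual:
        return []
    merged = [list(qual[0])]
    for a, b in qual[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        inside = [u for u in t if a <= u <= b]
        out.append((inside[0], inside[-1], len(inside)))
    return out


class TestDetectBursts:
    def test_dense_packet_is_one_burst(self):
        t = np.linspace(5.0, 5.05, 60)  # 60 spikes in 50 ms
        bursts = detect_bursts(t)
        assert len(bursts) == 1
        assert bursts[0].spike_count == 60
        assert bursts[0].onset == t[0] and bursts[0].offset == t[-1]

    def test_exactly_50_spikes_is_not_a_burst(self):
        t = np.linspace(1.0, 1.099, 50)
        assert detect_bursts(t) == []

    def test_two_packets_give_two_bursts(self):
        t = np.concatenate([np.linspace(1.0, 1.05, 60),
                            np.linspace(2.0, 2.05, 60)])
        bursts = detect_bursts(t)
        assert len(bursts) == 2
        assert all(b.spike_count == 60 for b in bursts)

    def test_matches_exhaustive_oracle_on_random_rasters(self, rng):
        params = BurstParams(window=0.1, min_spikes=20)
        for _ in range(30):
            n_bg = int(rng.integers(50, 200))
            t = rng.uniform(0, 20, n_bg)
            for _ in range(int(rng.integers(0, 4))):
                c = rng.uniform(1, 19)
                t = np.concatenate([t, rng.uniform(c, c + 0.08,
                                                   rng.integers(15, 60))])
            t = np.sort(t)
            got = [(b.onset, b.offset, b.spike_count)
                   for b in detect_bursts(t, params)]
            exp = brute_force_bursts(t, params.window, params.min_spikes)
            assert np.allclose(np.asarray(got, float).reshape(-1, 3),
                               np.asarray(exp, float).reshape(-1, 3))

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([2.0, 1.0]))

    def test_per_cluster_mode(self):
        dense = np.linspace(0.0, 0.05, 60)
        sparse = np.linspace(0.0, 50.0, 60)
        clusters = clusters_from_trains({0: dense, 1: sparse})
        per = detect_bursts_per_cluster(clusters)
        assert len(per[0]) == 1 and per[1] == []


def _leader_raster(n_clusters=5, n_bursts=6, delay=0.005, spikes_each=15,
                   isi=0.002, leader=2, spacing=2.0):
    """Deterministic raster: every burst led by `leader`, members following
    at multiples of `delay`."""
    trains = {c: [] for c in range(n_clusters)}
    onsets = []
    for k in range(n_bursts):
        t0 = 1.0 + k * spacing
        onsets.append(t0)
        order = [leader] + [c for c in range(n_clusters) if c != leader]
        for rank, c in enumerate(order):
            start = t0 + rank * delay
            trains[c].extend(start + np.arange(spikes_each) * isi)
    return clusters_from_trains(trains), onsets


class TestAttribution:
    def test_earliest_spike_wins(self):
        clusters, _ = _leader_raster(n_clusters=3, n_bursts=4, leader=1,
                                     spikes_each=20)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(clusters), params)
        bursts, table = attribute_initiators(bursts, clusters, params)
        assert all(b.initiator == 1 for b in bursts)
        assert table["n_initiated"].sum() == len(bursts)

    def test_tie_at_onset_goes_to_lowest_cluster_id(self):
        t = np.linspace(0, 0.05, 40)
        clusters = clusters_from_trains({3: t, 7: t})
        params = BurstParams(min_spikes=50)
        bursts = detect_bursts(pooled_raster(clusters), params)
        bursts, _ = attribute_initiators(bursts, clusters, params)
        assert bursts[0].initiator == 3

    def test_three_burst_minimum_for_initiator_table(self):
        cl_a, _ = _leader_raster(n_clusters=3, n_bursts=3, leader=0,
                                 spikes_each=20)
        # cluster 0 initiates exactly 3 bursts -> retained in the table
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl_a), params)
        bursts, table = attribute_initiators(bursts, cl_a, params)
        assert list(table["cluster_id"]) == [0]
        assert not any(b.initiator_below_threshold for b in bursts)

    def test_below_three_bursts_flagged(self):
        cl, _ = _leader_raster(n_clusters=3, n_bursts=2, leader=0,
                               spikes_each=20)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        bursts, table = attribute_initiators(bursts, cl, params)
        assert len(table) == 0
        assert all(b.initiator_below_threshold for b in bursts)

    def test_count_conservation(self):
        # sum of per-cluster initiated bursts (pre-filter) = attributed bursts
        cl, _ = _leader_raster(n_clusters=4, n_bursts=7, leader=3,
                               spikes_each=20)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        bursts, _ = attribute_initiators(bursts, cl, params)
        from collections import Counter
        counts = Counter(b.initiator for b in bursts)
        assert sum(counts.values()) == len(bursts)

    def test_generated_session_leaders_recovered_exactly(self):
        # noise-free simulator bursts: attribution = ground-truth leader
        lay = generate_layout(8)
        spec = ActivitySpec(baseline_rate=0.0, stim_response_prob=0.0,
                            burst_rate_pre=4, burst_rate_in=4,
                            burst_rate_post=4, inactive_ids=(),
                            propagation_delay=0.003, within_burst_spikes=8)
        per = Periods.from_durations(60, 60, 60)
        _, truth, _ = generate_population(lay, 8, spec, seed=11, periods=per)
        clusters = clusters_from_trains(truth.spike_times)
        bursts = detect_bursts(pooled_raster(clusters))
        assert len(bursts) == len(truth.burst_events)
        bursts, _ = attribute_initiators(bursts, clusters)
        for b, ev in zip(bursts, truth.burst_events):
            assert b.initiator == ev.leader


class TestPropagation:
    def test_order_follows_first_spikes(self):
        trains = {0: [10.000, 10.02], 1: [10.005], 2: [10.010]}
        clusters = clusters_from_trains(trains)
        from meaburst.core import Burst
        b = Burst(onset=10.0, offset=10.02, spike_count=4,
                  participants=(0, 1, 2), initiator=0)
        order = propagation_order(b, clusters)
        assert [cid for cid, _ in order] == [0, 1, 2]

    def test_identical_orders_correlate_perfectly(self):
        o = [(0, 1.0), (1, 1.005), (2, 1.01)]
        assert order_similarity(o, o) == 1.0

    def test_reversed_order_of_five_clusters(self):
        fwd = [(c, 1.0 + 0.005 * i) for i, c in enumerate(range(5))]
        rev = [(c, 2.0 + 0.005 * i) for i, c in enumerate(reversed(range(5)))]
        assert order_similarity(fwd, rev) == pytest.approx(-1.0)


class TestInitiationMap:
    def test_single_initiator_single_unit(self, short_periods):
        cl, _ = _leader_raster(n_clusters=3, n_bursts=4, leader=1,
                               spikes_each=20)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        bursts, _ = attribute_initiators(bursts, cl, params)
        lay = generate_layout(3)
        table = initiation_point_map(bursts, short_periods, lay)
        nonzero = table[table["n_initiated"] > 0]
        assert nonzero["unit_id"].nunique() == 1
        assert nonzero["unit_id"].iloc[0] == 1

    def test_period_without_bursts_absent_from_map(self, short_periods):
        cl, _ = _leader_raster(n_clusters=3, n_bursts=2, leader=0,
                               spikes_each=20, spacing=1.5)  # all in "pre"
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        bursts, _ = attribute_initiators(bursts, cl, params)
        lay = generate_layout(3)
        table = initiation_point_map(bursts, short_periods, lay)
        assert set(table["period"]) == {"pre"}
        counts = initiation_point_counts(table)
        assert counts == {"pre": 1, "in": 0, "post": 0}

    def test_additional_stim_leader_raises_count_by_one(self, short_periods):
        # one leader before stimulation, two during -> map gains one unit
        trains = {c: [] for c in range(4)}
        def add_burst(t0, leader):
            order = [leader] + [c for c in range(4) if c != leader]
            for rank, c in enumerate(order):
                trains[c].extend(t0 + rank * 0.004
                                 + np.arange(10) * 0.002)
        for k in range(3):
            add_burst(5.0 + 10 * k, leader=0)          # pre
        for k in range(3):
            add_burst(65.0 + 10 * k, leader=0)         # in, original leader
        for k in range(3):
            add_burst(70.0 + 10 * k, leader=2)         # in, recruited leader
        cl = clusters_from_trains(trains)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        bursts, _ = attribute_initiators(bursts, cl, params)
        lay = generate_layout(4)
        counts = initiation_point_counts(
            initiation_point_map(bursts, short_periods, lay))
        assert counts["in"] - counts["pre"] == 1

    def test_bursts_partition_by_onset_period(self, short_periods):
        cl, _ = _leader_raster(n_clusters=4, n_bursts=30, leader=0,
                               spikes_each=20, spacing=6.5)
        params = BurstParams(min_spikes=30)
        bursts = detect_bursts(pooled_raster(cl), params)
        pers = assign_periods(bursts, short_periods)
        assert len(pers) == len(bursts)
        # each onset in exactly one period and totals conserved
        from collections import Counter
        c = Counter(pers)
        assert sum(c.values()) == len(bursts)
        assert set(c) <= {"pre", "in", "post"}
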