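"""Burst segmentation, unit/response classification and windowed rates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caspike import (
    BurstCriteria,
    BurstSegmenter,
    ResponseClassifier,
    SpikeTrain,
    UnitClassifier,
    classify_response,
    classify_unit,
    compute_rates,
    fraction_by_class,
    relative_change,
    segment_bursts,
    simulate_spike_train,
)
from caspike.datatypes import FormatError, ParameterError
from caspike.simulate import SimProfile


def brute_force_bursts(times, max_isi=0.015, min_spikes=3, min_gap=0.100):
    """Independent oracle: test every contiguous subsequence against the
    three criteria, keep maximal ones, then merge across short gaps."""
    times = list(times)
    n = len(times)
    runs = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            if all(times[k + 1] - times[k] < max_isi for k in range(i, j)):
                left_max = i == 0 or not times[i] - times[i - 1] < max_isi
                right_max = j == n - 1 or not times[j + 1] - times[j] < max_isi
                if left_max and right_max:
                    runs.append([i, j])
    runs.sort()
    merged = []
    for a, b in runs:
        if merged and times[a] - times[merged[-1][1]] <= min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    out = []
    for a, b in merged:
        count = sum(1 for t in times if times[a] <= t <= times[b])
        out.append((times[a], times[b], count))
    return out


class TestSegmentBursts:
    def test_empty_train_gives_empty_set(self):
        assert segment_bursts(np.array([])).bursts == []

    def test_three_spike_burst_with_distant_follower(self):
        # ISIs 10 ms < 15 ms, count 3 > 2, next spike 480 ms away > 100 ms
        bs = segment_bursts(np.array([0.0, 0.010, 0.020, 0.500]))
        assert bs.bursts == [(0.0, 0.010 + 0.010, 3)]

    def test_two_spike_runs_are_not_bursts(self):
        bs = segment_bursts(np.array([0.0, 0.010, 0.200, 0.210]))
        assert bs.bursts == []

    def test_isi_boundary_is_strict(self):
        # exactly 15 ms fails "less than 15 ms"
        assert segment_bursts(np.array([0.0, 0.015, 0.030])).bursts == []
        assert len(segment_bursts(np.array([0.0, 0.0149, 0.0298])).bursts) == 1

    def test_close_runs_merge_into_one_burst(self):
        # two valid runs 90 ms apart (< 100 ms) merge; a stray spike between
        # them is absorbed into the burst count
        times = np.array([0.0, 0.005, 0.010, 0.060, 0.100, 0.105, 0.110])
        bs = segment_bursts(times)
        assert len(bs.bursts) == 1
        start, end, count = bs.bursts[0]
        assert (start, end) == (0.0, 0.110)
        assert count == 7

    def test_unsorted_input_rejected(self):
        with pytest.raises(FormatError):
            segment_bursts(np.array([0.2, 0.1]))

    def test_agrees_with_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(2000):
            n = int(rng.integers(0, 21))
            gaps = np.where(rng.random(n) < 0.5,
                            rng.exponential(0.008, n),
                            rng.exponential(0.15, n))
            # sprinkle exact boundary gaps to probe the strict inequalities
            exact = rng.random(n) < 0.05
            gaps[exact] = rng.choice([0.015, 0.100], size=exact.sum())
            times = np.cumsum(gaps)
            got = segment_bursts(times).bursts
            want = brute_force_bursts(times.tolist())
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g[0] == pytest.approx(w[0])
                assert g[1] == pytest.approx(w[1])
                assert g[2] == w[2]

    def test_ground_truth_recovery_on_low_rate_profile(self):
        # at 1 Hz singles, chance triplets are negligible and detected bursts
        # should match the generator's windows almost one-to-one
        p = SimProfile(label="rec", single_rate=1.0, burst_rate=0.1,
                       duration=3600.0, injection_time=3600.0, n_units=1,
                       rate_cv=0.0, seed=31)
        train, truth = simulate_spike_train(p, unit_seed=0)
        got = segment_bursts(train).bursts
        want = truth.true_burst_windows
        matched = 0
        wi = {i: (w[0], w[1]) for i, w in enumerate(want)}
        for s, e, _ in got:
            hit = [i for i, (ws, we) in wi.items() if s <= we and e >= ws]
            if hit:
                matched += 1
                del wi[hit[0]]
        jaccard = matched / (len(got) + len(want) - matched)
        assert jaccard >= 0.9
        assert abs(len(got) / len(want) - 1.0) <= 0.10

    @given(
        isis=st.lists(st.floats(1e-4, 0.5), min_size=0, max_size=60),
        max_isi=st.sampled_from([0.005, 0.010, 0.015, 0.030]),
    )
    def test_widening_isi_rule_never_frees_burst_spikes(self, isis, max_isi):
        times = np.cumsum(np.asarray(isis))

        def n_in_burst(mx):
            bs = segment_bursts(times, BurstCriteria(max_intra_isi=mx))
            return sum(b[2] for b in bs.bursts)

        assert n_in_burst(max_isi) <= n_in_burst(max_isi * 2)

    def test_transformer_over_spike_table(self):
        df = pd.DataFrame(
            {"unit_id": ["a"] * 4 + ["b"] * 2,
             "time_s": [0.0, 0.01, 0.02, 0.5, 0.0, 0.01]}
        )
        out = BurstSegmenter().fit_transform(df)
        assert out.to_dict(orient="records") == [
            {"unit_id": "a", "start_s": 0.0, "end_s": 0.02, "n_spikes": 3}
        ]


class TestClassification:
    @pytest.mark.parametrize(
        "rate,expected",
        [(15.0, "fast_spiking"), (10.0, "regular_spiking"),
         (10.0001, "fast_spiking"), (0.0, "regular_spiking")],
    )
    def test_fast_spiking_cutoff_strict(self, rate, expected):
        assert classify_unit(rate) == expected

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            classify_unit(-1.0)

    def test_unit_classifier_estimator(self):
        got = UnitClassifier().fit().predict([15.0, 10.0, 3.0])
        assert list(got) == ["fast_spiking", "regular_spiking",
                             "regular_spiking"]

    @pytest.mark.parametrize(
        "before,after,expected",
        [(8.0, 20.0, 250.0), (10.0, 10.0, 100.0), (10.0, 5.0, 50.0)],
    )
    def test_relative_change_formula(self, before, after, expected):
        assert relative_change(before, after) == pytest.approx(expected)

    def test_zero_baseline_flagged_as_nan(self, caplog):
        with caplog.at_level("WARNING"):
            assert np.isnan(relative_change(0.0, 5.0))
        assert "undefined-baseline" in caplog.text

    @pytest.mark.parametrize(
        "sr,expected",
        [(79.0, "decrease"), (80.0, "decrease"), (80.01, "no_change"),
         (100.0, "no_change"), (119.99, "no_change"), (120.0, "increase"),
         (250.0, "increase")],
    )
    def test_response_bounds(self, sr, expected):
        assert classify_response(sr) == expected

    def test_response_classifier_estimator(self):
        got = ResponseClassifier().fit().predict([79.0, 100.0, 120.0])
        assert list(got) == ["decrease", "no_change", "increase"]

    def test_fraction_by_class(self):
        all_nc = fraction_by_class(["no_change"] * 5)
        assert all_nc == {"decrease": 0.0, "no_change": 1.0, "increase": 0.0}
        mixed = fraction_by_class(["decrease"] * 2 + ["no_change"] * 8)
        assert mixed["decrease"] == pytest.approx(0.20)
        assert sum(mixed.values()) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            fraction_by_class([])


class TestComputeRates:
    def test_pure_single_spikes(self):
        times = np.arange(600) * 0.1 + 0.05  # 10 Hz over 60 s
        train = SpikeTrain("u", times, (0.0, 60.0))
        r = compute_rates(train, segment_bursts(times), [(0.0, 60.0)])[0]
        assert r.mean_rate == pytest.approx(10.0)
        assert r.single_rate == pytest.approx(10.0)
        assert r.burst_rate == 0.0

    def test_single_burst_only_train(self):
        times = np.array([5.0, 5.005, 5.010])
        train = SpikeTrain("u", times, (0.0, 10.0))
        r = compute_rates(train, segment_bursts(times), [(0.0, 10.0)])[0]
        assert r.mean_rate == pytest.approx(0.3)
        assert r.single_rate == 0.0
        assert r.burst_rate == pytest.approx(0.1)
        assert r.in_burst_spike_rate == pytest.approx(0.3)

    def test_empty_window_gives_zero_rates(self):
        train = SpikeTrain("u", np.array([1.0]), (0.0, 100.0))
        r = compute_rates(train, segment_bursts(train.spike_times),
                          [(50.0, 60.0)])[0]
        assert (r.mean_rate, r.single_rate, r.burst_rate) == (0.0, 0.0, 0.0)

    def test_zero_length_window_rejected(self):
        train = SpikeTrain("u", np.array([1.0]), (0.0, 10.0))
        with pytest.raises(ParameterError):
            compute_rates(train, segment_bursts(train.spike_times),
                          [(2.0, 2.0)])

    @given(seed=st.integers(0, 10_000))
    def test_single_plus_burst_spikes_conserve_total(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 200))
        gaps = np.where(rng.random(n) < 0.3, rng.exponential(0.006, n),
                        rng.exponential(0.3, n))
        times = np.cumsum(gaps)
        span = float(times[-1] + 1.0) if n else 1.0
        train = SpikeTrain("u", times, (0.0, span))
        bursts = segment_bursts(times)
        windows = [(0.0, span / 2), (span / 2, span)]
        total = 0.0
        for r, (w0, w1) in zip(compute_rates(train, bursts, windows), windows):
            total += (r.single_rate + r.in_burst_spike_rate) * (w1 - w0)
        assert total == pytest.approx(float(n), abs=1e-6)
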