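"""ΔF/F computation, event detection, activity metrics, normalisation."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caspike import (
    CaEventDetector,
    DeltaFOverF,
    FluorescenceTrace,
    compute_dff,
    detect_events,
    normalize_to_baseline,
    simulate_fluorescence,
    simulate_spike_train,
    summarize_activity,
)
from caspike.datatypes import (
    DegenerateBaselineError,
    DegenerateNoiseError,
    InsufficientBaselineError,
    ParameterError,
    ROIError,
)
from caspike.imaging import extract_roi_traces

FRAME = 1.109


def trace(values, background=0.0, **kw) -> FluorescenceTrace:
    values = np.asarray(values, dtype=float)
    return FluorescenceTrace(
        roi_id=kw.pop("roi_id", "r0"),
        frame_times=np.arange(values.size) * FRAME,
        raw_f=values,
        background=background,
    )


class TestComputeDff:
    def test_constant_trace_gives_zero_dff_and_f0(self):
        d = compute_dff(trace(np.full(50, 7.0)))
        assert d.f0 == pytest.approx(7.0)
        assert np.allclose(d.dff, 0.0)

    def test_direct_formula_evaluation(self):
        # F0 = 100 from the quiet baseline; one frame at 104 -> dff = 0.04
        f = np.full(100, 100.0)
        f[60] = 104.0
        d = compute_dff(trace(f), baseline_window=(0.0, 40 * FRAME))
        assert d.f0 == pytest.approx(100.0)
        assert d.dff[60] == pytest.approx(0.04)

    def test_offset_invariance_of_background_subtraction(self):
        rng = np.random.default_rng(1)
        f = 100.0 + rng.normal(0, 2, 200)
        d0 = compute_dff(trace(f, background=0.0))
        d1 = compute_dff(trace(f + 55.0, background=55.0))
        assert np.allclose(d0.dff, d1.dff)

    @given(gain=st.floats(0.1, 50.0))
    def test_affine_gain_invariance(self, gain):
        rng = np.random.default_rng(7)
        f = 100.0 + rng.normal(0, 2, 120)
        bg = 10.0
        d0 = compute_dff(trace(f, background=bg))
        d1 = compute_dff(trace(f * gain, background=bg * gain))
        assert np.allclose(d0.dff, d1.dff, atol=1e-10)
        assert d1.noise_sd == pytest.approx(d0.noise_sd, abs=1e-12)

    def test_short_baseline_rejected(self):
        with pytest.raises(InsufficientBaselineError):
            compute_dff(trace(np.full(30, 5.0)),
                        baseline_window=(0.0, 5 * FRAME))

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            compute_dff(trace(np.full(30, 4.0), background=10.0))


class TestDetectEvents:
    def test_flat_zero_trace_has_no_events(self, dff_factory):
        assert detect_events(dff_factory(np.zeros(40))) == []

    def test_single_transient_at_five_sd(self, calibration_profile,
                                         calibration_kernel):
        # forward-model one isolated burst; peak 6x noise SD -> 1 event with
        # amplitude within one frame-sample of the kernel peak
        p = dataclasses.replace(calibration_profile, burst_rate=0.0)
        train, truth = simulate_spike_train(p, unit_seed=0)
        truth.true_burst_windows = [(300.0, 300.01, 3)]
        kernel = dataclasses.replace(calibration_kernel, noise_sd=0.0)
        amp = kernel.amp_per_burst
        tr, truth = simulate_fluorescence(train, truth, kernel, seed=0)
        d = compute_dff(tr)
        d = dataclasses.replace(d, noise_sd=amp / 5.0, noise_mean=0.0)
        events = detect_events(d, k_sd=3.0)
        assert len(events) == 1
        assert events[0].amplitude <= amp + 1e-9
        assert events[0].amplitude >= amp * min(
            kernel.kernel(np.array([kernel.peak_time + FRAME / 2]))[0], 1.0
        ) - 1e-9
        assert abs(events[0].peak_time - (300.0 + kernel.peak_time)) <= FRAME

    def test_gap_splits_and_merges_events(self, dff_factory):
        x = np.zeros(30)
        x[5:8] = 5.0
        x[12:15] = 5.0
        d = dff_factory(x, noise_sd=1.0)
        assert len(detect_events(d, k_sd=3.0)) == 2
        x2 = x.copy()
        x2[8:12] = 5.0  # remove the sub-threshold gap
        assert len(detect_events(dff_factory(x2), k_sd=3.0)) == 1

    def test_event_count_monotone_in_threshold(self, dff_factory):
        rng = np.random.default_rng(3)
        x = np.clip(rng.normal(0, 1, 500), 0, None)
        x[::50] += 6.0
        d = dff_factory(x, noise_sd=1.0)
        counts = [len(detect_events(d, k_sd=k)) for k in (1, 2, 3, 4, 6, 9)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_noise_on_varying_trace_rejected(self, dff_factory):
        with pytest.raises(DegenerateNoiseError):
            detect_events(dff_factory(np.r_[np.zeros(10), 1.0], noise_sd=0.0))

    def test_run_detection_matches_per_frame_oracle(self, dff_factory):
        # exhaustive per-frame labeling oracle on seeded random traces
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 1000))
            x = rng.normal(0, 1, n) + 4.0 * (rng.random(n) < 0.05)
            d = dff_factory(x, noise_sd=1.0)
            events = detect_events(d, k_sd=3.0)
            above = x > 3.0
            # oracle: label each frame, then group contiguous labels
            frames = set()
            for ev in events:
                i0 = int(round(ev.onset_time / FRAME))
                i1 = int(round(ev.offset_time / FRAME))
                frames.update(range(i0, i1 + 1))
                assert above[i0 - 1] is not np.True_ if i0 > 0 else True
            assert frames == set(np.flatnonzero(above))
            # event count equals number of contiguous supra-threshold blocks
            blocks = np.sum(np.diff(np.r_[0, above.astype(int)]) == 1)
            assert len(events) == blocks


class TestSummarizeAndNormalize:
    def test_empty_events_give_zero_metrics(self, dff_factory):
        d = dff_factory(np.zeros(120))
        m = summarize_activity([], d, window_s=60.0)
        assert all(mi.frequency == 0 and mi.total_activity == 0 for mi in m)
        assert all(np.isnan(mi.amplitude_mean) for mi in m)

    def test_three_events_in_one_minute_window(self, dff_factory):
        x = np.zeros(60)
        for i in (5, 20, 35):
            x[i : i + 2] = 4.0
        d = dff_factory(x)
        events = detect_events(d, k_sd=3.0)
        m = summarize_activity(events, d, window_s=60.0)
        assert m[0].frequency == pytest.approx(3.0)
        assert m[0].n_events == 3

    def test_partial_terminal_window_dropped(self, dff_factory):
        d = dff_factory(np.zeros(100))  # 110.9 s -> one 60 s window
        assert len(summarize_activity([], d, window_s=60.0)) == 1

    def test_window_smaller_than_frame_rejected(self, dff_factory):
        with pytest.raises(ParameterError):
            summarize_activity([], dff_factory(np.zeros(50)), window_s=0.5)

    def test_doubling_dff_scales_amplitude_and_area_not_frequency(self):
        rng = np.random.default_rng(5)
        f0 = 100.0
        base = rng.normal(0, 1.0, 300)
        bursts = np.zeros(300)
        bursts[np.arange(20, 300, 40)] = 25.0
        raw1 = f0 + base + bursts
        raw2 = f0 + 2.0 * (base + bursts)  # dff doubled, threshold doubles too
        m1, m2 = [], []
        for raw, out in ((raw1, m1), (raw2, m2)):
            d = compute_dff(trace(raw))
            ev = detect_events(d, k_sd=3.0)
            out.extend(summarize_activity(ev, d, window_s=60.0))
        for a, b in zip(m1, m2):
            assert b.frequency == pytest.approx(a.frequency)
            if not np.isnan(a.amplitude_mean):
                assert b.amplitude_mean == pytest.approx(
                    2.0 * a.amplitude_mean, rel=0.05
                )
                assert b.total_activity == pytest.approx(
                    2.0 * a.total_activity, rel=0.05
                )

    def test_normalization_identity_and_arithmetic(self):
        from caspike.datatypes import CaMetrics

        base = [CaMetrics("r", (0, 60), amplitude_mean=0.5, frequency=2.0,
                          total_activity=1.0, n_events=2)]
        post = [CaMetrics("r", (60, 120), amplitude_mean=0.2, frequency=2.0,
                          total_activity=0.5, n_events=2)]
        same = normalize_to_baseline(base, base)
        assert same["amplitude_pct"] == pytest.approx(100.0)
        assert same["frequency_pct"] == pytest.approx(100.0)
        mixed = normalize_to_baseline(post, base)
        assert mixed["amplitude_pct"] == pytest.approx(40.0)
        assert mixed["total_activity_pct"] == pytest.approx(50.0)

    def test_zero_baseline_flagged_not_raised(self):
        from caspike.datatypes import CaMetrics

        base = [CaMetrics("r", (0, 60), amplitude_mean=np.nan, frequency=0.0,
                          total_activity=0.0, n_events=0)]
        out = normalize_to_baseline(base, base)
        assert np.isnan(out["frequency_pct"])
        assert any("undefined-normalization" in f for f in out["flags"])


class TestExtractRoiTraces:
    def test_uniform_frame_recovers_value(self):
        stack = np.full((5, 8, 8), 42.0)
        mask = np.zeros((8, 8), bool)
        mask[2:5, 2:5] = True
        tr = extract_roi_traces(stack, mask, background=0.0)[0]
        assert np.allclose(tr.raw_f, 42.0)

    def test_mask_outside_soma_tracks_background(self):
        stack = np.full((4, 16, 16), 10.0)
        stack[:, 4:8, 4:8] = 90.0
        far = np.zeros((16, 16), bool)
        far[12:15, 12:15] = True
        tr = extract_roi_traces(stack, far, background=None)[0]
        assert np.allclose(tr.raw_f, 10.0)
        assert np.allclose(np.asarray(tr.background), 10.0)

    def test_empty_mask_and_shape_mismatch_rejected(self):
        stack = np.zeros((3, 8, 8))
        with pytest.raises(ROIError):
            extract_roi_traces(stack, np.zeros((8, 8), bool))
        from caspike.datatypes import FormatError

        with pytest.raises(FormatError):
            extract_roi_traces(stack, np.zeros((9, 9), bool))


class TestEstimators:
    def test_delta_f_over_f_fit_transform_roundtrip(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {f"roi{i}": 100.0 + rng.normal(0, 2, 200) for i in range(3)},
            index=np.arange(200) * FRAME,
        )
        est = DeltaFOverF(min_fraction=0.1).fit(X)
        dff = est.transform(X)
        assert dff.shape == X.shape
        assert (est.f0_ > 0).all()
        # per-column result matches the functional path
        d0 = compute_dff(trace(X["roi0"].to_numpy()))
        assert np.allclose(dff["roi0"].to_numpy(), d0.dff)

    def test_sklearn_params_and_pipeline_compose(self):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline

        est = DeltaFOverF(min_fraction=0.2)
        assert clone(est).get_params()["min_fraction"] == 0.2
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": 100.0 + rng.normal(0, 2, 150)},
                         index=np.arange(150) * FRAME)
        pipe = Pipeline([("dff", DeltaFOverF()),
                         ("events", CaEventDetector(k_sd=3.0))])
        out = pipe.fit_transform(X)
        assert list(out.columns) == ["roi_id", "onset_s", "peak_s",
                                     "offset_s", "amplitude", "area"]

    def test_event_detector_accepts_pinned_noise(self):
        x = np.zeros(50)
        x[10:13] = 1.0
        X = pd.DataFrame({"r": x}, index=np.arange(50) * FRAME)
        det = CaEventDetector(k_sd=3.0, noise_sd=0.1, noise_mean=0.0).fit(X)
        ev = det.transform(X)
        assert len(ev) == 1
        assert ev.loc[0, "amplitude"] == pytest.approx(1.0)
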