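"""Event detection on force-distance curves and height-clamp traces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bondscape import (
    CurveSynthesisSpec,
    DetectionParams,
    ForceCurve,
    analyze_curve,
    classify_specific,
    detect_rupture_events,
    estimate_baseline,
    extract_clamp_events,
    select_single_event,
    synthesize_clamp_trace,
    synthesize_retract_curve,
)
from bondscape.core import DomainError, InsufficientDataError, RuptureEvent
from bondscape.detection import event_loading_rate


def _flat_curve(noise_sd=3.0, offset=0.0, seed=0, n=512):
    rng = np.random.default_rng(seed)
    sep = np.linspace(0, 40, n)
    force = offset + rng.normal(0, noise_sd, n) if noise_sd > 0 else np.full(n, offset)
    return ForceCurve(separation=sep, force=force)


class TestBaseline:
    def test_flat_noisy_curve(self):
        offset, sd = estimate_baseline(_flat_curve(noise_sd=3.0))
        assert offset == pytest.approx(0.0, abs=0.7)
        assert sd == pytest.approx(3.0, abs=0.6)

    def test_shifted_curve(self):
        offset, _ = estimate_baseline(_flat_curve(noise_sd=3.0, offset=5.0))
        assert offset == pytest.approx(5.0, abs=0.7)

    def test_noiseless_curve_zero_sd(self):
        offset, sd = estimate_baseline(_flat_curve(noise_sd=0.0, offset=2.0))
        assert offset == pytest.approx(2.0, abs=1e-9)
        assert sd == 0.0

    def test_too_few_baseline_samples(self):
        curve = ForceCurve(separation=np.linspace(0, 40, 20), force=np.zeros(20))
        with pytest.raises(InsufficientDataError):
            estimate_baseline(curve)


class TestRuptureDetection:
    def test_noise_only_curve_yields_no_specific_events(self):
        n_specific = 0
        for seed in range(20):
            curve = _flat_curve(noise_sd=3.0, seed=seed)
            events, noise_sd = detect_rupture_events(curve)
            n_specific += sum(classify_specific(e, noise_sd) for e in events)
        assert n_specific == 0

    def test_two_well_separated_ruptures(self, curve_spec):
        rng = np.random.default_rng(8)
        curve, _ = synthesize_retract_curve([(10.0, 60.0), (18.0, 45.0)], curve_spec, rng)
        events, noise_sd = detect_rupture_events(curve)
        specific = [e for e in events if classify_specific(e, noise_sd)]
        assert len(specific) == 2
        assert specific[0].rupture_distance < specific[1].rupture_distance
        assert specific[0].rupture_distance == pytest.approx(10.0, abs=1.0)
        assert specific[1].rupture_distance == pytest.approx(18.0, abs=1.0)

    def test_offset_invariance(self, curve_spec):
        rng = np.random.default_rng(9)
        curve, _ = synthesize_retract_curve([(12.0, 50.0)], curve_spec, rng)
        shifted = ForceCurve(
            separation=curve.separation, force=curve.force + 7.0,
            curve_id=curve.curve_id,
        )
        e1, r1 = analyze_curve(curve)
        e2, r2 = analyze_curve(shifted)
        assert r1 == r2 == "ok"
        assert e2.rupture_force == pytest.approx(e1.rupture_force, abs=0.3)
        assert e2.rupture_distance == pytest.approx(e1.rupture_distance, abs=0.2)


class TestClassifySpecific:
    @pytest.mark.parametrize(
        "distance, force, mode, expected",
        [
            (12.0, 50.0, "binding", True),
            (2.0, 80.0, "binding", False),  # inside the contact region
            (12.0, 10.0, "binding", False),  # below the 5x-sd (15 pN) threshold
            (7.0, 50.0, "extraction", False),  # outside the 10-25 nm window
            (12.0, 50.0, "extraction", True),
        ],
    )
    def test_window_and_threshold(self, distance, force, mode, expected):
        event = RuptureEvent(rupture_distance=distance, rupture_force=force)
        assert classify_specific(event, noise_sd=3.0, mode=mode) is expected

    @given(
        force=st.floats(min_value=0, max_value=200),
        bump=st.floats(min_value=0, max_value=100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_force(self, force, bump):
        lo = RuptureEvent(rupture_distance=12.0, rupture_force=force)
        hi = RuptureEvent(rupture_distance=12.0, rupture_force=force + bump)
        if classify_specific(lo, noise_sd=3.0):
            assert classify_specific(hi, noise_sd=3.0)


class TestSingleEventRule:
    def _event(self, specific):
        return RuptureEvent(rupture_distance=12.0, rupture_force=50.0, specific=specific)

    def test_exactly_one_kept(self):
        event, reason = select_single_event([self._event(True), self._event(False)])
        assert reason == "ok" and event is not None

    def test_multiple_discarded(self):
        event, reason = select_single_event([self._event(True), self._event(True)])
        assert event is None and reason == "multiple"

    def test_empty_discarded(self):
        event, reason = select_single_event([])
        assert event is None and reason == "empty"


class TestLoadingRate:
    def _ramp_curve(self, slope_pn_per_s, velocity=3.1, noise_sd=0.0, seed=0, peak=60.0):
        # force rises linearly with time until `peak`, then detaches
        n = 512
        sep = np.linspace(0, 40, n)
        v_nm_s = velocity * 1000.0
        time = sep / v_nm_s
        force = np.minimum(slope_pn_per_s * time, peak)
        force[force >= peak] = 0.0  # rupture
        if noise_sd > 0:
            force += np.random.default_rng(seed).normal(0, noise_sd, n)
        return ForceCurve(separation=sep, force=force, pulling_velocity=velocity)

    def test_noiseless_ramp_exact(self):
        curve = self._ramp_curve(1e4)
        det = curve.force.copy()
        peak = int(np.argmax(det))
        assert event_loading_rate(curve, peak, det) == pytest.approx(1e4, rel=1e-9)

    def test_noisy_ramp_within_five_percent(self):
        curve = self._ramp_curve(1e4, noise_sd=3.0, seed=4)
        events, noise_sd = detect_rupture_events(curve)
        assert len(events) == 1
        assert events[0].loading_rate == pytest.approx(1e4, rel=0.05)

    def test_flat_rise_flagged_missing(self):
        n = 512
        sep = np.linspace(0, 40, n)
        force = np.zeros(n)
        force[100:160] = 30.0  # step with no rise
        curve = ForceCurve(separation=sep, force=force)
        peak = 159
        assert math.isnan(event_loading_rate(curve, peak, force))


class TestClampExtraction:
    def test_oscillating_event_discarded(self):
        rng = np.random.default_rng(6)
        trace, _ = synthesize_clamp_trace([(0.5, 0.2, 30.0)], noise_sd=1.0, rng=rng)
        # superimpose a 3 pN-amplitude (6 pN peak-to-trough) slow oscillation
        inside = (trace.time >= 0.5) & (trace.time < 0.7)
        trace.force[inside] += 3.0 * np.sin(2 * np.pi * 25 * trace.time[inside])
        assert extract_clamp_events(trace) == []

    def test_time_translation_invariance(self):
        rng = np.random.default_rng(13)
        trace, _ = synthesize_clamp_trace([(0.4, 0.15, 25.0)], noise_sd=1.0, rng=rng)
        shifted_time = trace.time + 3.0
        from bondscape import ClampTrace

        shifted = ClampTrace(time=shifted_time, force=trace.force.copy())
        ev0 = extract_clamp_events(trace)
        ev1 = extract_clamp_events(shifted)
        assert len(ev0) == len(ev1) == 1
        assert ev1[0].lifetime == pytest.approx(ev0[0].lifetime, rel=1e-9)
        assert ev1[0].force_step == pytest.approx(ev0[0].force_step, rel=1e-9)


class TestRecallPrecision:
    def test_specific_event_recovery_on_synthetic_batch(self):
        """Detection recovers >=95% of true 25+ pN events in the 5-25 nm window,
        with >=95% precision, at the 3 pN noise level (15 pN threshold)."""
        rng = np.random.default_rng(21)
        spec = CurveSynthesisSpec()
        tp = fp = fn = 0
        for i in range(300):
            if rng.uniform() < 0.8:
                truth_events = [(rng.uniform(6, 20), rng.uniform(25, 90))]
            else:
                truth_events = []
            curve, truth = synthesize_retract_curve(truth_events, spec, rng, curve_id=f"c{i}")
            detected, _ = analyze_curve(curve)
            true_specific = [
                t for t in truth
                if t["kind"] == "specific" and 5 <= t["distance"] <= 25 and t["force"] >= 25
            ]
            if detected is not None:
                if any(abs(detected.rupture_distance - t["distance"]) < 1.5 for t in true_specific):
                    tp += 1
                else:
                    fp += 1
            elif true_specific:
                fn += 1
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95
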