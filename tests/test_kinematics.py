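"""Kinematic features: histogram, correlation, regression slope, foot range."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frogswim import kinematics as kin
from frogswim._geometry import unit_from_angle
from frogswim.kinematics import (
    AnglePair,
    UndefinedFeatureError,
    build_histogram,
    extract_features,
    foot_range,
    normalize_heatmap,
    symmetry,
    synchronization,
)


def pairs_from(r, l):
    return [AnglePair(a, b) for a, b in zip(r, l)]


class TestHistogram:
    def test_worked_example_bins(self):
        """Angle-pairs (49, 88) and (52, 45) increment exactly those bins."""
        hist = build_histogram([AnglePair(49.0, 88.0), AnglePair(52.0, 45.0)])
        assert hist.counts[49, 88] == 1
        assert hist.counts[52, 45] == 1
        assert hist.total == 2

    def test_empty_input_all_zero(self):
        hist = build_histogram([])
        assert hist.counts.shape == (180, 180)
        assert hist.total == 0

    def test_repeated_pair_conserved(self):
        hist = build_histogram([AnglePair(30.2, 40.8)] * 1000)
        assert hist.counts[30, 40] == 1000
        assert hist.total == 1000

    def test_invalid_pairs_skipped(self):
        hist = build_histogram([AnglePair(10, 10), AnglePair(20, 20, valid=False)])
        assert hist.total == 1

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 179.999), st.floats(0, 179.999), st.booleans()
            ),
            max_size=60,
        )
    )
    def test_count_conservation_matches_brute_force(self, rows):
        """Total count equals the number of valid pairs; bins match a direct loop."""
        pairs = [AnglePair(r, l, valid=v) for r, l, v in rows]
        hist = build_histogram(pairs)
        brute = np.zeros((180, 180), dtype=int)
        for r, l, v in rows:
            if v:
                brute[min(int(r), 179), min(int(l), 179)] += 1
        assert hist.total == sum(v for _, _, v in rows)
        assert np.array_equal(hist.counts, brute)


class TestNormalizeHeatmap:
    def test_single_hot_bin(self):
        counts = np.zeros((180, 180), dtype=int)
        counts[10, 20] = 10
        img = normalize_heatmap(kin.AngleHistogram2D(counts))
        assert img[10, 20] == 1.0
        assert img.sum() == 1.0

    def test_all_zero_degenerate(self):
        img = normalize_heatmap(build_histogram([]))
        assert (img == 0).all()

    def test_order_preserving_against_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(180, 180))
        hist = kin.AngleHistogram2D(counts)
        img = normalize_heatmap(hist)
        oracle = (counts - counts.min()) / (counts.max() - counts.min())
        assert np.allclose(img, oracle)
        assert img.min() == 0.0 and img.max() == 1.0


class TestSynchronization:
    def test_identical_traces_one(self):
        t = 90 + 40 * np.sin(np.linspace(0, 4 * np.pi, 120, endpoint=False))
        assert synchronization(pairs_from(t, t)) == pytest.approx(1.0)

    def test_anti_phase_minus_one(self):
        x = np.linspace(0, 4 * np.pi, 120, endpoint=False)
        assert synchronization(pairs_from(90 - 40 * np.sin(x), 90 + 40 * np.sin(x))) == pytest.approx(-1.0)

    def test_quadrature_zero(self):
        x = np.linspace(0, 6 * np.pi, 180, endpoint=False)
        r = synchronization(pairs_from(90 + 40 * np.sin(x), 90 + 40 * np.cos(x)))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_errors_on_degenerate_input(self):
        with pytest.raises(UndefinedFeatureError):
            synchronization([AnglePair(10, 10)])
        with pytest.raises(UndefinedFeatureError, match="motionless"):
            synchronization(pairs_from([50, 50, 50], [10, 20, 30]))

    @settings(deadline=None, max_examples=30)
    @given(
        st.integers(3, 40),
        st.floats(-50, 50),
        st.integers(0, 2**31 - 1),
    )
    def test_shift_invariance_and_symmetry(self, n, shift, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(10, 170, n)
        l = rng.uniform(10, 170, n)
        if np.ptp(r) == 0 or np.ptp(l) == 0:
            return
        f1 = synchronization(pairs_from(r, l))
        assert -1.0 <= f1 <= 1.0
        assert synchronization(pairs_from(l, r)) == pytest.approx(f1, abs=1e-9)
        assert synchronization(pairs_from(r + shift, l)) == pytest.approx(f1, abs=1e-7)


class TestSymmetry:
    def test_equal_traces_slope_one(self):
        t = 90 + 30 * np.sin(np.linspace(0, 4 * np.pi, 100))
        assert symmetry(pairs_from(t, t)) == pytest.approx(1.0)

    def test_halved_trace_slope_half(self):
        t = 90 + 30 * np.sin(np.linspace(0, 4 * np.pi, 100))
        assert symmetry(pairs_from(0.5 * t, t)) == pytest.approx(0.5)

    def test_through_origin_formula(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 179, 50)
        l = rng.uniform(1, 179, 50)
        assert symmetry(pairs_from(r, l)) == pytest.approx(np.sum(r * l) / np.sum(l * l))

    def test_scaling_property(self):
        rng = np.random.default_rng(2)
        r = rng.uniform(10, 170, 50)
        l = rng.uniform(10, 170, 50)
        base = symmetry(pairs_from(r, l))
        for c in (0.25, 2.0):
            assert symmetry(pairs_from(c * r, l)) == pytest.approx(c * base)

    def test_zero_left_trace_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            symmetry(pairs_from([1.0, 2.0], [0.0, 0.0]))

    def test_intercept_variant_reports_slope(self):
        l = np.linspace(10, 170, 50)
        r = 0.5 * l + 20.0
        assert symmetry(pairs_from(r, l), fit_intercept=True) == pytest.approx(0.5)
        # through-origin slope differs once an offset is present
        assert symmetry(pairs_from(r, l)) != pytest.approx(0.5, abs=0.01)


class TestFootRange:
    def test_identical_positions_zero(self):
        pts = np.tile([[0.0, 70.0]], (50, 1))
        assert foot_range(pts, side="right") == pytest.approx(0.0)

    def test_arc_matches_raw_extremes_oracle(self):
        """A tight noiseless arc of half-angle A spans ~2A, like its raw extremes."""
        for half in (20.0, 45.0):
            alphas = 90 + half * np.sin(np.linspace(0, 6 * np.pi, 300))
            pts = np.array([75.0 * unit_from_angle(a, "right") for a in alphas])
            raw = alphas.max() - alphas.min()
            measured = foot_range(pts, side="right", kde_bandwidth=1.0)
            assert measured == pytest.approx(raw, abs=5.0)

    def test_rotation_of_body_frame_is_invariant(self):
        """Rotating positions together with the convention axes changes nothing.

        Positions enter in the oriented body frame, so a rigid rotation of
        the scene is absorbed before this function; feeding the same
        body-frame offsets must give the same range bit-for-bit.
        """
        rng = np.random.default_rng(3)
        alphas = 80 + 30 * np.sin(np.linspace(0, 4 * np.pi, 100)) + rng.normal(0, 2, 100)
        pts = np.array([70.0 * unit_from_angle(a, "right") for a in alphas])
        assert foot_range(pts, side="right") == foot_range(pts.copy(), side="right")

    def test_threshold_too_high_raises(self):
        with pytest.raises(ValueError):
            foot_range(np.array([[0.0, 70.0], [1.0, 71.0]]), density_threshold_fraction=1.5)


class TestExtractFeatures:
    def test_noiseless_synchronized_traces(self):
        alphas = 90 + 40 * np.sin(np.linspace(0, 4 * np.pi, 200, endpoint=False))
        pairs = pairs_from(alphas, alphas)
        feats = extract_features(pairs)
        assert feats.f1_synchronization == pytest.approx(1.0)
        assert feats.f2_symmetry == pytest.approx(1.0)
        assert feats.n_valid_frames == 200
        assert not any(feats.missing.values())

    def test_hemisected_pattern(self):
        """Right amplitude half of left with independent phase: f2 ~ 0.5, f1 ~ 0."""
        from frogswim.kinematics import features_from_traces
        from frogswim.synth import default_motion_model, generate_traces

        model = default_motion_model("hemisected", seed=11)
        traces = generate_traces(model, n_frames=900, fps=60, seed=12)
        feats = features_from_traces(traces)
        assert abs(feats.f1_synchronization) < 0.35
        assert feats.f2_symmetry == pytest.approx(0.5, abs=0.12)

    def test_transected_range_below_uninjured(self):
        from frogswim.kinematics import features_from_traces
        from frogswim.synth import default_motion_model, generate_traces

        f = {}
        for label in ("uninjured", "transected"):
            traces = generate_traces(default_motion_model(label, seed=4), n_frames=300, fps=60, seed=5)
            f[label] = features_from_traces(traces)
        assert f["transected"].f3_range_right < f["uninjured"].f3_range_right
        assert f["transected"].f4_range_left < f["uninjured"].f4_range_left

    def test_motionless_limb_flagged_missing(self):
        pairs = pairs_from([50.0] * 30, np.linspace(40, 140, 30))
        feats = extract_features(pairs)
        assert feats.missing["f1"]
        assert feats.f1_synchronization is None
        assert not feats.missing["f2"]
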