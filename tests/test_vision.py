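"""Vision branch: landmark geometry, temporal voting, Transformer contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nightfall.vision import (FEATURE_DIM, FRAMES_PER_SEGMENT, OCCLUDED, PRONE,
                              UPRIGHT, BoundingBox, LandmarkFrame,
                              PoseTransformer, aspect_ratio, bounding_box,
                              make_segments, prone_streak, streak_membership,
                              to_pixels, vision_probability)


def frame_from(points, visibilities, dims=(1920, 1080)):
    """Build a LandmarkFrame with the first len(points) landmarks placed at
    normalized `points` and the rest at the centroid with zero visibility."""
    lm = np.zeros((33, 3))
    lm[:, :2] = 0.5
    for i, (p, v) in enumerate(zip(points, visibilities)):
        lm[i] = (p[0], p[1], v)
    return LandmarkFrame(timestamp=0.0, landmarks=lm, frame_dims=dims)


class TestToPixels:
    @pytest.mark.parametrize("xn,yn,w,h,expected", [
        (0.5, 0.5, 1920, 1080, (960.0, 540.0)),
        (0.0, 0.0, 640, 480, (0.0, 0.0)),
        (0.25, 0.8, 640, 480, (160.0, 384.0)),
    ])
    def test_known_values(self, xn, yn, w, h, expected):
        assert to_pixels(xn, yn, w, h) == pytest.approx(expected)

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            to_pixels(0.5, 0.5, 0, 1080)


class TestBoundingBox:
    def test_known_extremes(self):
        pts = [(10 / 100, 20 / 100), (30 / 100, 5 / 100), (15 / 100, 40 / 100)]
        fr = frame_from(pts, [0.9, 0.9, 0.9], dims=(100, 100))
        box = bounding_box(fr)
        assert (box.x_min, box.x_max) == (10, 30)
        assert (box.y_min, box.y_max) == (5, 40)

    def test_low_visibility_outlier_excluded(self):
        pts = [(0.9, 0.9), (0.4, 0.4), (0.45, 0.45), (0.5, 0.5)]
        fr = frame_from(pts, [0.4, 0.9, 0.9, 0.9], dims=(1000, 1000))
        box = bounding_box(fr)
        assert box.x_max <= 500.0

    def test_all_invisible_is_occluded(self):
        fr = frame_from([(0.5, 0.5)], [0.0])
        assert bounding_box(fr) is None

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_min_max_oracle(self, data):
        n = data.draw(st.integers(3, 33))
        coords = data.draw(st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)),
            min_size=n, max_size=n))
        vis = data.draw(st.lists(st.floats(0, 1), min_size=n, max_size=n))
        lm = np.zeros((33, 3))
        lm[:, :2] = 0.5
        for i, ((x, y), v) in enumerate(zip(coords, vis)):
            lm[i] = (x, y, v)
        fr = LandmarkFrame(0.0, lm, (640, 480))
        box = bounding_box(fr, 0.5)
        # brute-force oracle over the same filtered set
        kept = [(lm[i, 0] * 640, lm[i, 1] * 480) for i in range(33)
                if lm[i, 2] > 0.5]
        if len(kept) < 2:
            assert box is None
        else:
            xs = [p[0] for p in kept]
            ys = [p[1] for p in kept]
            assert box.x_min == pytest.approx(min(xs))
            assert box.x_max == pytest.approx(max(xs))
            assert box.y_min == pytest.approx(min(ys))
            assert box.y_max == pytest.approx(max(ys))


class TestAspectRatio:
    def test_wide_box_is_prone(self):
        rho, prone = aspect_ratio(BoundingBox(0, 30, 0, 10, 5))
        assert rho == pytest.approx(3.0)
        assert prone

    def test_tall_box_is_upright(self):
        rho, prone = aspect_ratio(BoundingBox(0, 20, 0, 35, 5))
        assert rho == pytest.approx(20 / 35)
        assert not prone

    def test_square_box_is_not_prone(self):
        rho, prone = aspect_ratio(BoundingBox(0, 10, 0, 10, 5))
        assert rho == 1.0
        assert not prone   # strict inequality at the boundary

    def test_zero_height_undefined(self):
        assert aspect_ratio(BoundingBox(0, 10, 5, 5, 3)) is None

    @given(dx=st.floats(-500, 500), dy=st.floats(-500, 500),
           k=st.floats(0.1, 10))
    @settings(max_examples=60, deadline=None)
    def test_translation_and_uniform_scale_invariance(self, dx, dy, k):
        box = BoundingBox(10, 40, 20, 35, 4)
        moved = BoundingBox(10 + dx, 40 + dx, 20 + dy, 35 + dy, 4)
        scaled = BoundingBox(10 * k, 40 * k, 20 * k, 35 * k, 4)
        assert aspect_ratio(moved)[0] == pytest.approx(aspect_ratio(box)[0])
        assert aspect_ratio(scaled)[0] == pytest.approx(aspect_ratio(box)[0])


def rle_confirmed(flags, required):
    """Run-length-encoding oracle for the temporal vote."""
    runs, cur = [], 0
    for f in flags:
        if f == PRONE:
            cur += 1
        else:
            runs.append(cur)
            cur = 0
    runs.append(cur)
    return (max(runs) >= required, max(runs))


class TestProneStreak:
    def test_thirty_adjacent_confirms(self):
        assert prone_streak([PRONE] * 30)[0]

    def test_interrupted_run_does_not_confirm(self):
        flags = [PRONE] * 29 + [UPRIGHT] + [PRONE] * 29
        confirmed, best = prone_streak(flags)
        assert not confirmed
        assert best == 29

    def test_occlusion_splits_but_long_runs_still_confirm(self):
        flags = [PRONE] * 50 + [OCCLUDED] + [PRONE] * 49
        confirmed, best = prone_streak(flags)
        assert confirmed
        assert best == 50

    def test_occlusion_gap_tolerance(self):
        flags = [PRONE] * 20 + [OCCLUDED] + [PRONE] * 20
        assert not prone_streak(flags, occlusion_gap=0)[0]
        assert prone_streak(flags, occlusion_gap=1)[0]

    def test_empty_sequence_not_confirmed(self):
        assert prone_streak([]) == (False, 0)

    @given(flags=st.lists(st.sampled_from([PRONE, UPRIGHT, OCCLUDED]),
                          max_size=200),
           required=st.integers(1, 40))
    @settings(max_examples=150, deadline=None)
    def test_matches_run_length_oracle(self, flags, required):
        assert prone_streak(flags, required) == rle_confirmed(flags, required)

    @given(flags=st.lists(st.sampled_from([PRONE, UPRIGHT, OCCLUDED]),
                          max_size=120),
           required=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_membership_consistent_with_confirmation(self, flags, required):
        member = streak_membership(np.array(flags, dtype=np.int8), required)
        assert member.any() == prone_streak(flags, required)[0]


class TestSegments:
    def test_tiling_and_feature_shape(self):
        frames = [LandmarkFrame(i / 30.0, np.full((33, 3), 0.5))
                  for i in range(75)]
        segs = make_segments(frames)
        assert len(segs) == 2      # incomplete trailing segment dropped
        assert segs[0].features.shape == (FRAMES_PER_SEGMENT, FEATURE_DIM)
        assert segs[1].interval[0] == pytest.approx(1.0)

    def test_feature_dim_is_66(self):
        assert FEATURE_DIM == 33 * 2 == 66


class TestVisionProbability:
    def test_gate_passes_when_confirmed(self):
        assert vision_probability(0.9, True) == 0.9

    def test_gate_attenuates_when_not_confirmed(self):
        assert vision_probability(0.9, False) == pytest.approx(0.45)

    def test_raw_mode_ignores_flags(self):
        assert vision_probability(0.9, False, mode="raw") == 0.9

    def test_hard_and_mode(self):
        assert vision_probability(0.9, False, mode="hard_and") == 0.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            vision_probability(1.2, True)


class TestPoseTransformerEstimator:
    def test_sklearn_params_roundtrip(self):
        est = PoseTransformer(d_model=16, n_layers=1, n_heads=2)
        assert PoseTransformer(**est.get_params()).get_params() == est.get_params()

    def test_stratified_split_sizes(self, rng):
        X = np.clip(rng.normal(0.5, 0.1, (100, 30, 66)), 0, 1)
        y = np.arange(100) % 2
        X[y == 1] += 0.2
        X = np.clip(X, 0, 1)
        est = PoseTransformer(d_model=16, n_layers=1, n_heads=2, epochs=1,
                              random_state=0)
        est.fit(X, y)
        assert est.split_sizes_ == (70, 15, 15)

    def test_probabilities_valid(self, rng):
        X = np.clip(rng.normal(0.5, 0.1, (24, 30, 66)), 0, 1)
        y = np.arange(24) % 2
        X[y == 1, :, 1::2] += 0.2
        X = np.clip(X, 0, 1)
        est = PoseTransformer(d_model=16, n_layers=1, n_heads=2, epochs=2,
                              val_frac=0.15, test_frac=0.0, random_state=0)
        est.fit(X, y)
        p = est.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.min() >= 0.0

    def test_single_class_rejected(self, rng):
        est = PoseTransformer(d_model=16, n_layers=1, n_heads=2)
        with pytest.raises(ValueError):
            est.fit(np.zeros((10, 30, 66)), np.zeros(10))
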