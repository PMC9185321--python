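"""Angular scoring, frame mapping, normalization and threshold search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallgan.networks import Generator, GeneratorConfig
from fallgan.scoring import (
    ScoreTrack,
    ScoringError,
    angular_score,
    grid_search_threshold,
    mse_track,
    normalize_track,
    score_clip,
    score_sample,
)
from fallgan.video_io import SequenceSample
from conftest import make_clip

TINY = GeneratorConfig(base_channels=4, depth=2, latent_dim=8)


class TestAngularScore:
    def test_identical_vectors_zero(self):
        assert angular_score([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0)

    def test_orthogonal_half_pi(self):
        assert angular_score([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_antipodal_pi(self):
        assert angular_score([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(np.pi)

    def test_zero_vector_rejected(self):
        with pytest.raises(ScoringError, match="zero-norm"):
            angular_score([0.0, 0.0], [1.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ScoringError):
            angular_score([1.0, 0.0], [1.0, 0.0, 0.0])

    def test_symmetry_and_scale_invariance_1000_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            c = float(rng.uniform(0.01, 100.0))
            t1 = angular_score(a, b)
            assert t1 == pytest.approx(angular_score(b, a), abs=1e-12)
            assert t1 == pytest.approx(angular_score(a, c * b), abs=1e-9)
            assert 0.0 <= t1 <= np.pi


class TestScoreSample:
    def test_identity_reconstruction_zero(self, rng):
        # if the "reconstruction" is the authentic target itself, theta = 0
        gen = Generator(TINY, seed=0)
        target = rng.uniform(-1, 1, size=(8, 16, 16))
        v1 = gen.encode(target)
        v2 = gen.encode(target)
        # arccos is sqrt-sensitive near 1, so exact-zero becomes ~1e-8
        assert angular_score(v1, v2) == pytest.approx(0.0, abs=1e-6)

    def test_theta_in_range(self, rng):
        gen = Generator(TINY, seed=1)
        for seed in range(5):
            r = np.random.default_rng(seed)
            sample = SequenceSample(
                input_window=r.uniform(-1, 1, size=(8, 16, 16)),
                target_window=r.uniform(-1, 1, size=(8, 16, 16)),
                anchor_index=7,
            )
            theta = score_sample(gen, sample)
            assert 0.0 <= theta <= np.pi


def brute_force_frame_scores(gen, clip, stride):
    """Oracle: accumulate each window's angle onto its future frames."""
    from fallgan.video_io import window_sequences

    per_frame = {i: [] for i in range(len(clip))}
    for s in window_sequences(clip, stride=stride):
        theta = score_sample(gen, s)
        for idx in s.future_frame_indices:
            per_frame[idx].append(theta)
    out = np.full(len(clip), np.nan)
    for i, vals in per_frame.items():
        if vals:
            out[i] = np.mean(vals)
    return out


class TestScoreClip:
    def test_12_frame_clip_scores_frames_8_to_11(self):
        gen = Generator(TINY, seed=0)
        clip = make_clip(n_frames=12, side=16)
        track = score_clip(gen, clip, inference_stride=1)
        covered = np.where(track.covered)[0]
        np.testing.assert_array_equal(covered, [8, 9, 10, 11])

    def test_16_frame_overlap_averaging_matches_oracle(self):
        gen = Generator(TINY, seed=0)
        clip = make_clip(n_frames=16, side=16)
        track = score_clip(gen, clip, inference_stride=1)
        oracle = brute_force_frame_scores(gen, clip, 1)
        np.testing.assert_allclose(track.frame_scores, oracle, atol=1e-12)

    def test_stride3_coverage_matches_enumeration(self):
        gen = Generator(TINY, seed=0)
        clip = make_clip(n_frames=60, side=16)
        track = score_clip(gen, clip, inference_stride=3)
        oracle = brute_force_frame_scores(gen, clip, 3)
        np.testing.assert_array_equal(track.covered, ~np.isnan(oracle))
        np.testing.assert_allclose(
            track.frame_scores[track.covered], oracle[~np.isnan(oracle)], atol=1e-12
        )

    def test_short_clip_empty_track(self):
        gen = Generator(TINY, seed=0)
        track = score_clip(gen, make_clip(n_frames=10, side=16), 1)
        assert not track.covered.any()

    def test_labels_attached(self):
        gen = Generator(TINY, seed=0)
        labels = np.zeros(14, dtype=int)
        labels[9] = 1
        clip = make_clip(n_frames=14, side=16, labels=labels)
        track = score_clip(gen, clip, 1)
        np.testing.assert_array_equal(track.labels, labels)


class TestNormalizeTrack:
    def _track(self, scores, labels=None):
        return ScoreTrack("c", np.asarray(scores, dtype=float), labels=labels)

    def test_minmax_example(self):
        out = normalize_track(self._track([0.2, 0.5, 0.8]))
        np.testing.assert_allclose(out.normalized_scores, [0.0, 0.5, 1.0])

    def test_constant_track_maps_to_zero(self):
        out = normalize_track(self._track([0.4, 0.4, 0.4]))
        np.testing.assert_array_equal(out.normalized_scores, [0.0, 0.0, 0.0])

    def test_nan_frames_stay_nan(self):
        out = normalize_track(self._track([np.nan, 0.1, 0.3]))
        assert np.isnan(out.normalized_scores[0])
        np.testing.assert_allclose(out.normalized_scores[1:], [0.0, 1.0])

    def test_empty_track_rejected(self):
        with pytest.raises(ScoringError):
            normalize_track(self._track([np.nan, np.nan]))

    def test_rank_preservation_single_clip_auc_unchanged(self, rng):
        from fallgan.evaluation import frame_auc

        scores = rng.uniform(0.1, 2.0, size=40)
        labels = (rng.random(40) < 0.3).astype(int)
        labels[:2] = [0, 1]  # both classes present
        track = self._track(scores, labels)
        norm = normalize_track(track)
        assert frame_auc(scores, labels) == pytest.approx(
            frame_auc(norm.normalized_scores, labels), abs=1e-12
        )

    @given(
        scores=st.lists(st.floats(0, 3), min_size=2, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalized_range_property(self, scores):
        out = normalize_track(self._track(scores))
        assert np.nanmin(out.normalized_scores) >= 0.0
        assert np.nanmax(out.normalized_scores) <= 1.0


def youden_oracle(scores, labels, grid):
    """Exhaustive objective evaluation, ties toward larger threshold."""
    best = (-np.inf, None)
    for t in sorted(grid):
        sens = np.mean(scores[labels == 1] > t)
        spec = np.mean(scores[labels == 0] <= t)
        j = sens + spec - 1
        if j >= best[0]:
            best = (j, t)
    return best[1]


class TestGridSearchThreshold:
    def _tracks(self, scores, labels):
        return [ScoreTrack("c", np.asarray(scores, float),
                           labels=np.asarray(labels, int))]

    def test_separable_case_picks_largest_valid(self):
        scores = [0.1, 0.2, 0.15, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1]
        grid = [round(0.1 * i, 1) for i in range(1, 10)]
        t = grid_search_threshold(self._tracks(scores, labels), grid)
        assert t == pytest.approx(0.7)  # largest grid value below min fall score

    def test_single_class_rejected(self):
        with pytest.raises(ScoringError, match="both classes"):
            grid_search_threshold(self._tracks([0.1, 0.2], [0, 0]), [0.1, 0.5])

    def test_empty_grid_rejected(self):
        with pytest.raises(ScoringError, match="empty"):
            grid_search_threshold(self._tracks([0.1, 0.9], [0, 1]), [])

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            scores = r.uniform(0, 1, size=50)
            labels = (r.random(50) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            grid = np.round(np.linspace(0.05, 0.95, 19), 2)
            got = grid_search_threshold(self._tracks(scores, labels), grid)
            assert got == pytest.approx(youden_oracle(scores, labels, grid))

    def test_normal_quantile_fallback(self):
        scores = np.linspace(0, 1, 101)
        labels = np.zeros(101, dtype=int)
        t = grid_search_threshold(
            self._tracks(scores, labels), [0.5, 0.9, 0.95, 1.0],
            objective="normal_quantile", quantile=0.9,
        )
        assert t == pytest.approx(0.9)

    def test_normal_quantile_works_without_labels(self):
        track = ScoreTrack("c", np.linspace(0, 1, 11))
        t = grid_search_threshold(
            [track], [0.25, 0.75], objective="normal_quantile", quantile=0.5
        )
        assert t == pytest.approx(0.75)


class TestMseBaseline:
    def test_same_coverage_as_angular(self):
        gen = Generator(TINY, seed=0)
        clip = make_clip(n_frames=20, side=16)
        a = score_clip(gen, clip, 1)
        m = mse_track(gen, clip, 1)
        np.testing.assert_array_equal(a.covered, m.covered)
        assert (m.frame_scores[m.covered] >= 0).all()
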