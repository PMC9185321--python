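"""Encoded-feature angular anomaly scoring.

A window's anomaly score is the angle between the bottleneck encoding of
the generator's reconstructed sequence and that of the authentic target
sequence.  Window scores are spread onto the 4 predicted-future frames
(overlaps averaged); per-clip min-max normalization gives the offline
("normalized") variant, raw angles the online variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .networks import EncodedFeature, Generator
from .video_io import VideoClip, SequenceSample, window_sequences

logger = logging.getLogger(__name__)

SCORE_CSV_HEADER = "frame_index,raw_theta,normalized_score,label"


class ScoringError(ValueError):
    pass


@dataclass
class ScoreTrack:
    """Per-frame anomaly scores aligned to a clip's frame indices.

    ``frame_scores`` holds raw angles in radians with NaN for frames not
    covered by any window; ``normalized_scores`` (if set) holds per-clip
    min-max rescaled values in [0, 1].
    """

    clip_id: str
    frame_scores: np.ndarray
    normalized_scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self):
        self.frame_scores = np.asarray(self.frame_scores, dtype=np.float64)
        if self.normalized_scores is not None:
            self.normalized_scores = np.asarray(self.normalized_scores, np.float64)
            covered = ~np.isnan(self.normalized_scores)
            if covered.any() and (
                (self.normalized_scores[covered] < 0).any()
                or (self.normalized_scores[covered] > 1).any()
            ):
                raise ScoringError("normalized scores must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.frame_scores):
                raise ScoringError(
                    f"track {self.clip_id!r}: label/score length mismatch"
                )

    @property
    def covered(self) -> np.ndarray:
        return ~np.isnan(self.frame_scores)

    def scores(self, mode: str = "online") -> np.ndarray:
        if mode == "online":
            return self.frame_scores
        if mode == "offline":
            if self.normalized_scores is None:
                raise ScoringError(f"track {self.clip_id!r} is not normalized")
            return self.normalized_scores
        raise ValueError(f"unknown mode {mode!r}")


def _as_vector(v) -> np.ndarray:
    if isinstance(v, EncodedFeature):
        return v.vector
    return np.asarray(v, dtype=np.float64).ravel()


def angular_score(v1, v2) -> float:
    """Included angle (radians, in [0, pi]) between two feature vectors."""
    a, b = _as_vector(v1), _as_vector(v2)
    if a.shape != b.shape:
        raise ScoringError(f"vector length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ScoringError("angular score undefined for zero-norm vectors")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def _v1_window(recon: np.ndarray, target: np.ndarray, v1_mode: str) -> np.ndarray:
    """Window re-encoded as V1: the full reconstruction, or the 4 predicted
    future frames with the 4 authentic overlap frames prepended."""
    if v1_mode == "full":
        return recon
    if v1_mode == "future_only":
        return np.concatenate([target[..., :4, :, :], recon[..., 4:, :, :]], axis=-3)
    raise ValueError(f"unknown v1_mode {v1_mode!r}")


def score_sample(
    gen: Generator, sample: SequenceSample, v1_mode: str = "full"
) -> float:
    """Angle between encodings of reconstructed and authentic sequences."""
    recon = gen.generate(sample.input_window)
    v1 = gen.encode(_v1_window(recon, sample.target_window, v1_mode))
    v2 = gen.encode(sample.target_window)
    return angular_score(v1, v2)


def score_clip(
    gen: Generator,
    clip: VideoClip,
    inference_stride: int = 3,
    v1_mode: str = "full",
) -> ScoreTrack:
    """Score every window of a clip and map angles onto future frames.

    Windows are anchored every ``inference_stride`` frames; each window's
    angle is assigned to its four predicted-future frame indices, with
    overlaps averaged.  Frames no window covers stay NaN.
    """
    samples = window_sequences(clip, stride=inference_stride)
    n = len(clip)
    if not samples:
        logger.info("clip %r too short to score", clip.clip_id)
        return ScoreTrack(clip.clip_id, np.full(n, np.nan), labels=clip.labels)

    inputs = np.stack([s.input_window for s in samples])
    targets = np.stack([s.target_window for s in samples])
    recon = gen.generate(inputs)
    v1 = gen.encode(_v1_window(recon, targets, v1_mode))
    v2 = gen.encode(targets)
    thetas = [angular_score(a, b) for a, b in zip(v1, v2)]

    acc = np.zeros(n)
    counts = np.zeros(n)
    for sample, theta in zip(samples, thetas):
        idx = sample.future_frame_indices
        acc[idx] += theta
        counts[idx] += 1
    scores = np.full(n, np.nan)
    covered = counts > 0
    scores[covered] = acc[covered] / counts[covered]
    return ScoreTrack(clip.clip_id, scores, labels=clip.labels)


def normalize_track(track: ScoreTrack) -> ScoreTrack:
    """Per-clip min-max rescaling of raw angles to [0, 1].

    Constant tracks map to all-zero (no anomaly evidence).
    """
    covered = track.covered
    if not covered.any():
        raise ScoringError(f"track {track.clip_id!r} has no scored frames")
    raw = track.frame_scores
    lo, hi = np.nanmin(raw), np.nanmax(raw)
    normalized = np.full_like(raw, np.nan)
    if hi > lo:
        normalized[covered] = (raw[covered] - lo) / (hi - lo)
    else:
        normalized[covered] = 0.0
    return ScoreTrack(
        track.clip_id, raw.copy(), normalized,
        None if track.labels is None else track.labels.copy(),
        track.threshold,
    )


def _pooled(tracks: list[ScoreTrack], mode: str) -> tuple[np.ndarray, np.ndarray]:
    scores, labels = [], []
    for t in tracks:
        if t.labels is None:
            raise ScoringError(f"track {t.clip_id!r} has no labels")
        s = t.scores(mode)
        keep = ~np.isnan(s)
        scores.append(s[keep])
        labels.append(t.labels[keep])
    return np.concatenate(scores), np.concatenate(labels)


def grid_search_threshold(
    tracks: list[ScoreTrack],
    grid,
    objective: str = "youden",
    mode: str = "online",
    quantile: float = 0.99,
) -> float:
    """Pick the grid threshold maximizing an objective over pooled frames.

    ``youden`` maximizes sensitivity + specificity - 1 and needs both
    classes; ``normal_quantile`` ignores labels and returns the smallest
    grid value at or above the given quantile of the pooled scores (a
    fallback when no fall-labeled validation data exists).  Ties break
    toward the larger threshold (fewer alarms).
    """
    grid = np.asarray(list(grid), dtype=np.float64)
    if grid.size == 0:
        raise ScoringError("threshold grid is empty")

    if objective == "normal_quantile":
        # label-free fallback: tracks are assumed normal-only
        pooled = []
        for t in tracks:
            s = t.scores(mode)
            pooled.append(s[~np.isnan(s)])
        scores = np.concatenate(pooled)
        cut = np.quantile(scores, quantile)
        at_or_above = grid[grid >= cut]
        return float(at_or_above.min() if at_or_above.size else grid.max())
    if objective != "youden":
        raise ValueError(f"unknown objective {objective!r}")
    scores, labels = _pooled(tracks, mode)

    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ScoringError(
            "youden objective requires both classes among pooled frames"
        )
    best_j, best_t = -np.inf, None
    for t in np.sort(grid):
        alarm = scores > t
        sens = (alarm & (labels == 1)).sum() / n_pos
        spec = (~alarm & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j >= best_j:  # >= : ties go to the larger threshold
            best_j, best_t = j, float(t)
    return best_t


def mse_track(gen: Generator, clip: VideoClip, inference_stride: int = 3) -> ScoreTrack:
    """Per-pixel MSE reconstruction-error baseline, same frame mapping.

    Scores each window by the mean squared error between its predicted
    future frames and the authentic ones; used as the comparison
    baseline for the angular (denoised) scoring scheme.
    """
    samples = window_sequences(clip, stride=inference_stride)
    n = len(clip)
    if not samples:
        return ScoreTrack(clip.clip_id, np.full(n, np.nan), labels=clip.labels)
    inputs = np.stack([s.input_window for s in samples])
    targets = np.stack([s.target_window for s in samples])
    recon = gen.generate(inputs)
    errors = ((recon[:, 4:] - targets[:, 4:]) ** 2).mean(axis=(1, 2, 3))
    acc = np.zeros(n)
    counts = np.zeros(n)
    for sample, err in zip(samples, errors):
        idx = sample.future_frame_indices
        acc[idx] += err
        counts[idx] += 1
    scores = np.full(n, np.nan)
    covered = counts > 0
    scores[covered] = acc[covered] / counts[covered]
    return ScoreTrack(clip.clip_id, scores, labels=clip.labels)


def write_score_csv(path, track: ScoreTrack) -> None:
    lines = [SCORE_CSV_HEADER]
    norm = track.normalized_scores
    for i, raw in enumerate(track.frame_scores):
        nval = "" if norm is None or np.isnan(norm[i]) else repr(float(norm[i]))
        rval = "" if np.isnan(raw) else repr(float(raw))
        label = "" if track.labels is None else str(int(track.labels[i]))
        lines.append(f"{i},{rval},{nval},{label}")
    from pathlib import Path as _P

    _P(path).write_text("\n".join(lines) + "\n")
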