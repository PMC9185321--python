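"""Depth-frame hole filling, resizing and intensity normalization.

Hole pixels (undefined depth readings stored as a sentinel value) are
repaired by iterative diffusion: each hole is repeatedly replaced by the
mean of its valid 8-neighbours until none remain or an iteration cap is
hit, at which point any stragglers take their nearest valid neighbour's
value.  Frames are then resized to the network's square input size and
affinely rescaled to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .video_io import VideoClip


class FrameValidationError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    target_size: int = 64
    invalid_value: float = 0.0
    fill_max_iters: int = 100
    source_range: tuple[float, float] | None = None  # None: use clip.value_range
    fill_enabled: bool = True

    def __post_init__(self):
        if self.target_size < 16:
            raise ValueError("target_size must be >= 16")
        if self.fill_max_iters < 1:
            raise ValueError("fill_max_iters must be >= 1")


_NEIGHBOR_KERNEL = np.ones((3, 3))


def fill_holes(
    frame: np.ndarray, invalid_value: float = 0.0, max_iters: int = 100
) -> np.ndarray:
    """Replace every pixel equal to ``invalid_value`` by diffused valid values.

    Valid pixels are returned bit-identical; filled values are convex
    combinations of valid neighbours and therefore stay inside the valid
    pixels' [min, max] range.
    """
    frame = np.asarray(frame, dtype=np.float64)
    hole = frame == invalid_value
    if not hole.any():
        return frame.copy()
    if hole.all():
        raise FrameValidationError("frame contains no valid pixel to fill from")

    out = frame.copy()
    out[hole] = 0.0
    valid = ~hole
    for _ in range(max_iters):
        if not hole.any():
            break
        weights = ndimage.convolve(
            valid.astype(np.float64), _NEIGHBOR_KERNEL, mode="constant"
        )
        sums = ndimage.convolve(out * valid, _NEIGHBOR_KERNEL, mode="constant")
        fillable = hole & (weights > 0)
        out[fillable] = sums[fillable] / weights[fillable]
        valid = valid | fillable
        hole = hole & ~fillable
    if hole.any():
        # nearest-valid-neighbour fallback for isolated regions
        _, (ri, ci) = ndimage.distance_transform_edt(
            ~valid, return_indices=True
        )
        out[hole] = out[ri[hole], ci[hole]]
    # a filled value may coincide with the sentinel; nudge it off
    collision = (out == invalid_value) & (frame == invalid_value)
    if collision.any():
        vmin, vmax = frame[frame != invalid_value].min(), frame[frame != invalid_value].max()
        eps = max(1e-9, 1e-9 * max(abs(vmin), abs(vmax)))
        out[collision] = invalid_value + (eps if invalid_value < vmax else -eps)
    return out


def resize_normalize(
    frame: np.ndarray,
    config: PreprocessConfig,
    source_range: tuple[float, float],
) -> np.ndarray:
    """Resize to (target_size, target_size) and map source_range -> [-1, 1]."""
    lo, hi = source_range
    if hi <= lo:
        raise FrameValidationError(f"degenerate source range ({lo}, {hi})")
    frame = np.asarray(frame, dtype=np.float64)
    s = config.target_size
    if frame.shape != (s, s):
        frame = _sk_resize(
            frame, (s, s), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    scaled = (frame - lo) / (hi - lo) * 2.0 - 1.0
    return np.clip(scaled, -1.0, 1.0)


def preprocess_clip(clip: VideoClip, config: PreprocessConfig) -> VideoClip:
    """Hole-fill then resize/normalize every frame; carry labels and fps."""
    if len(clip) == 0:
        raise FrameValidationError("empty clip")
    source_range = config.source_range or clip.value_range
    out_frames = np.empty(
        (len(clip), config.target_size, config.target_size), dtype=np.float64
    )
    for i, frame in enumerate(clip.frames):
        if config.fill_enabled:
            try:
                frame = fill_holes(frame, config.invalid_value, config.fill_max_iters)
            except FrameValidationError as err:
                raise FrameValidationError(
                    f"clip {clip.clip_id!r} frame {i}: {err}"
                ) from err
        out_frames[i] = resize_normalize(frame, config, source_range)
    return VideoClip(
        frames=out_frames,
        labels=None if clip.labels is None else clip.labels.copy(),
        fps=clip.fps,
        clip_id=clip.clip_id,
        value_range=(-1.0, 1.0),
    )
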