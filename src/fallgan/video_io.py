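"""Frame-stack clip I/O and sequence windowing.

A clip is a directory of single-channel PNG frames whose zero-padded
numeric filenames sort into temporal order, optionally accompanied by a
``labels.txt`` file with one 0/1 flag per line (1 = fall frame).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: frames needed for one sample: 8 input + 4 new future frames
WINDOW_INPUT = 8
WINDOW_SHIFT = 4
WINDOW_SPAN = WINDOW_INPUT + WINDOW_SHIFT

LABEL_FILENAME = "labels.txt"


class ClipStructureError(ValueError):
    """Raised when a clip directory violates structural invariants."""


@dataclass
class VideoClip:
    """An ordered stack of single-channel frames with optional fall labels.

    frames: array of shape (T, H, W), real-valued.
    labels: optional (T,) int array, 1 marking fall frames.
    value_range: declared (lo, hi) pixel range of the stored frames.
    """

    frames: np.ndarray
    labels: np.ndarray | None = None
    fps: float = 25.0
    clip_id: str = ""
    value_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ClipStructureError(
                f"frames must be (T, H, W); got shape {self.frames.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.frames):
                raise ClipStructureError(
                    f"clip {self.clip_id!r}: {len(self.labels)} labels for "
                    f"{len(self.frames)} frames"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def has_fall_frames(self) -> bool:
        return self.labels is not None and bool((self.labels == 1).any())


@dataclass
class SequenceSample:
    """One training/inference unit.

    input_window holds frames F[t-7..t]; target_window holds F[t-3..t+4]
    (the input window shifted forward by 4); ``anchor_index`` is t in the
    source clip.  The last 4 input frames coincide with the first 4
    target frames.
    """

    input_window: np.ndarray
    target_window: np.ndarray
    anchor_index: int
    clip_id: str = ""
    frame_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.input_window.shape[0] != WINDOW_INPUT:
            raise ValueError("input_window must contain exactly 8 frames")
        if self.target_window.shape[0] != WINDOW_INPUT:
            raise ValueError("target_window must contain exactly 8 frames")

    @property
    def future_frame_indices(self) -> np.ndarray:
        """Clip indices of the 4 predicted future frames (t+1 .. t+4)."""
        return np.arange(self.anchor_index + 1, self.anchor_index + 5)


def _frame_files(path: Path) -> list[Path]:
    exts = {".png"}
    return sorted(p for p in path.iterdir() if p.suffix.lower() in exts)


def load_clip(
    path: str | Path,
    label_path: str | Path | None = None,
    fps: float = 25.0,
) -> VideoClip:
    """Load a directory of single-channel PNG frames into a :class:`VideoClip`.

    Filenames are sorted lexicographically to give temporal order.  If
    ``label_path`` is None, a ``labels.txt`` next to the frames is used
    when present.
    """
    path = Path(path)
    files = _frame_files(path)
    if not files:
        raise ClipStructureError(f"no PNG frames found in {path}")
    frames = []
    shape = None
    sixteen_bit = False
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise ClipStructureError(f"{f} is not single-channel (shape {img.shape})")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ClipStructureError(
                f"{f} has shape {img.shape}, expected {shape} (inconsistent clip)"
            )
        sixteen_bit = sixteen_bit or img.dtype == np.uint16
        frames.append(img.astype(np.float64))
    stack = np.stack(frames)
    hi = 65535.0 if sixteen_bit else 255.0

    labels = None
    if label_path is None:
        candidate = path / LABEL_FILENAME
        label_path = candidate if candidate.exists() else None
    if label_path is not None:
        labels = read_labels(label_path)
        if len(labels) != len(stack):
            raise ClipStructureError(
                f"{label_path}: {len(labels)} labels for {len(stack)} frames"
            )
    return VideoClip(
        frames=stack,
        labels=labels,
        fps=fps,
        clip_id=path.name,
        value_range=(0.0, hi),
    )


def read_labels(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text().split()
    labels = np.array([int(x) for x in lines], dtype=np.int64)
    if not np.isin(labels, (0, 1)).all():
        raise ClipStructureError(f"{path}: labels must be 0 or 1")
    return labels


def write_clip(clip: VideoClip, path: str | Path, bit_depth: int = 8) -> None:
    """Write one PNG per frame (zero-padded 6-digit names) plus labels.

    Frame values are mapped affinely from ``clip.value_range`` to the
    full integer range of the chosen bit depth.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if len(clip) == 0:
        raise ClipStructureError("refusing to write an empty clip")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lo, hi = clip.value_range
    if hi <= lo:
        raise ClipStructureError(f"degenerate value_range {clip.value_range}")
    vmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scaled = (clip.frames - lo) / (hi - lo) * vmax
    quantized = np.clip(np.rint(scaled), 0, vmax).astype(dtype)
    for i, frame in enumerate(quantized):
        iio.imwrite(path / f"{i:06d}.png", frame)
    if clip.labels is not None:
        (path / LABEL_FILENAME).write_text(
            "\n".join(str(int(x)) for x in clip.labels) + "\n"
        )


def window_sequences(clip: VideoClip, stride: int = 1) -> list[SequenceSample]:
    """Cut a clip into 8-in / 8-target sequence samples.

    Anchors start at frame index 7 and advance by ``stride`` while the
    4-frame future horizon stays inside the clip.  Windows never cross
    the clip boundary; clips shorter than 12 frames yield no samples.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    n = len(clip)
    if n < WINDOW_SPAN:
        logger.info(
            "clip %r has %d frames (< %d); no sequence samples",
            clip.clip_id,
            n,
            WINDOW_SPAN,
        )
        return []
    samples = []
    for anchor in range(WINDOW_INPUT - 1, n - WINDOW_SHIFT, stride):
        start = anchor - WINDOW_INPUT + 1
        labels = None
        if clip.labels is not None:
            labels = clip.labels[start : anchor + WINDOW_SHIFT + 1]
        samples.append(
            SequenceSample(
                input_window=clip.frames[start : anchor + 1],
                target_window=clip.frames[start + WINDOW_SHIFT : anchor + WINDOW_SHIFT + 1],
                anchor_index=anchor,
                clip_id=clip.clip_id,
                frame_labels=labels,
            )
        )
    return samples
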