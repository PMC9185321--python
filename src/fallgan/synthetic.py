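"""Synthetic depth-like fall / daily-activity video generator.

Scenes are a dark static background ramp with a bright elliptical
subject.  Normal behaviours (walk, sit, idle) move the subject smoothly;
falls rotate the ellipse from vertical to horizontal while its centroid
drops rapidly, optionally followed by partial occlusion behind a
furniture rectangle.  Depth-sensor artefacts are modelled as per-pixel
hole dropouts (value 0) and additive frame jitter.  All randomness is
seeded and regeneration is bit-identical.

Pixel values live in [0, 1]; 0 is reserved for hole pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .video_io import VideoClip

BEHAVIORS = ("walk", "sit", "idle")

#: floor of rendered intensities so jitter never collides with hole value 0
_MIN_VALID = 0.02

def _walk_speed(frame_size: int) -> float:
    """Peak walking speed in px/frame for normal clips (capped at 2 px).

    Deliberately brisk: wide, fast walks give the training set enough
    motion diversity that the encoder learns position/velocity-sensitive
    features -- with only near-static training data the bottleneck codes
    collapse and the angular score loses its fall contrast.
    """
    return min(2.0, 0.028 * frame_size)


def _prefall_walk_speed(frame_size: int) -> float:
    """Gentler pre-fall walking so the fall outlier dominates its clip."""
    return min(1.0, 0.0125 * frame_size)


@dataclass
class SceneParams:
    frame_size: int = 64
    background_range: tuple[float, float] = (0.1, 0.4)
    furniture: tuple[int, int, int, int, float] | None = None  # (row, col, h, w, value)
    subject_value: float = 0.8
    second_subject: bool = False  # extra independently moving person
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.background_range
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("background_range must satisfy 0 < lo < hi <= 1")
        if lo <= self.subject_value <= hi:
            raise ValueError("subject_value must lie outside the background range")
        if self.furniture is not None:
            r, c, h, w, _ = self.furniture
            s = self.frame_size
            if not (0 <= r and 0 <= c and r + h <= s and c + w <= s):
                raise ValueError("furniture rectangle must lie inside the frame")


@dataclass
class NoiseParams:
    p_hole: float = 0.0
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_hole <= 0.3:
            raise ValueError("p_hole must lie in [0, 0.3]")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass
class _Pose:
    """Ellipse pose: centre (row, col), semi-axes (vertical, horizontal), tilt."""

    cy: float
    cx: float
    ry: float
    rx: float
    angle: float = 0.0  # radians; 0 = upright


def _background(scene: SceneParams) -> np.ndarray:
    lo, hi = scene.background_range
    s = scene.frame_size
    ramp = np.linspace(lo, hi, s)[:, None]
    return np.broadcast_to(ramp, (s, s)).copy()


def _ellipse_alpha(size: int, pose: _Pose, supersample: int = 2) -> np.ndarray:
    """Anti-aliased coverage mask of a rotated ellipse, via supersampling."""
    n = size * supersample
    coords = (np.arange(n) + 0.5) / supersample - 0.5
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    dy, dx = yy - pose.cy, xx - pose.cx
    ca, sa = np.cos(pose.angle), np.sin(pose.angle)
    u = ca * dy - sa * dx
    v = sa * dy + ca * dx
    inside = (u / pose.ry) ** 2 + (v / pose.rx) ** 2 <= 1.0
    mask = inside.astype(np.float64)
    return mask.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


def _render(scene: SceneParams, poses) -> np.ndarray:
    if isinstance(poses, _Pose):
        poses = [poses]
    frame = _background(scene)
    for pose in poses or []:
        alpha = _ellipse_alpha(scene.frame_size, pose)
        frame = frame * (1.0 - alpha) + scene.subject_value * alpha
    if scene.furniture is not None:
        r, c, h, w, value = scene.furniture
        frame[r : r + h, c : c + w] = value
    return frame


def _apply_noise(frames: np.ndarray, noise: NoiseParams) -> np.ndarray:
    if noise.p_hole == 0.0 and noise.jitter_sigma == 0.0:
        return frames
    rng = np.random.default_rng(noise.seed)
    out = frames.copy()
    if noise.jitter_sigma > 0:
        out = out + rng.normal(0.0, noise.jitter_sigma, size=out.shape)
    out = np.clip(out, _MIN_VALID, 1.0)
    if noise.p_hole > 0:
        holes = rng.random(size=out.shape) < noise.p_hole
        out[holes] = 0.0
    return out


def _standing_pose(scene: SceneParams, cx: float) -> _Pose:
    s = scene.frame_size
    return _Pose(cy=0.55 * s, cx=cx, ry=0.22 * s, rx=0.09 * s, angle=0.0)


def _normal_poses(
    scene: SceneParams, behavior: str, n_frames: int, rng: np.random.Generator
) -> list[_Pose]:
    s = scene.frame_size
    cx0 = s / 2 + rng.uniform(-0.05 * s, 0.05 * s)
    if behavior == "idle":
        pose = _standing_pose(scene, cx0)
        return [pose] * n_frames
    if behavior == "walk":
        period = 60.0
        # max per-frame displacement = amplitude * 2*pi/period, kept < 2 px
        amplitude = min(0.28 * s, _walk_speed(s) * period / (2 * np.pi))
        phase = rng.uniform(0, 2 * np.pi)
        poses = []
        for t in range(n_frames):
            cx = s / 2 + amplitude * np.sin(2 * np.pi * t / period + phase)
            poses.append(_standing_pose(scene, cx))
        return poses
    if behavior == "sit":
        descent_frames = max(20, n_frames // 2)
        stand = _standing_pose(scene, cx0)
        poses = []
        for t in range(n_frames):
            u = min(1.0, t / descent_frames)
            poses.append(
                _Pose(
                    cy=stand.cy + u * 0.15 * s,
                    cx=cx0,
                    ry=stand.ry * (1 - 0.35 * u),
                    rx=stand.rx * (1 + 0.4 * u),
                    angle=0.0,
                )
            )
        return poses
    raise ValueError(f"unknown behavior {behavior!r}; expected one of {BEHAVIORS}")


def generate_normal_clip(
    scene: SceneParams,
    behavior: str,
    n_frames: int,
    noise: NoiseParams | None = None,
    clip_id: str = "",
    fps: float = 25.0,
) -> VideoClip:
    """Render a normal-activity clip (all labels 0)."""
    if n_frames < 12:
        raise ValueError("n_frames must be >= 12")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(scene.seed)
    poses = [[p] for p in _normal_poses(scene, behavior, n_frames, rng)]
    if scene.second_subject:
        other = BEHAVIORS[(BEHAVIORS.index(behavior) + 1) % len(BEHAVIORS)]
        s = scene.frame_size
        for group, extra in zip(poses, _normal_poses(scene, other, n_frames, rng)):
            # mirror across the vertical midline: smooth and mostly disjoint
            mirrored = dataclasses.replace(
                extra, cx=float(np.clip(0.95 * s - extra.cx, 0.12 * s, 0.88 * s))
            )
            group.append(mirrored)
    frames = np.stack([_render(scene, p) for p in poses])
    frames = _apply_noise(frames, noise)
    return VideoClip(
        frames=frames,
        labels=np.zeros(n_frames, dtype=np.int64),
        fps=fps,
        clip_id=clip_id or f"normal_{behavior}_{scene.seed}",
        value_range=(0.0, 1.0),
    )


def generate_fall_clip(
    scene: SceneParams,
    n_frames: int,
    fall_onset: int,
    fall_duration: int,
    noise: NoiseParams | None = None,
    occlude_after: bool = False,
    pre_behavior: str = "walk",
    label_post_fall: bool = False,
    clip_id: str = "",
    fps: float = 25.0,
) -> VideoClip:
    """Render a clip with a rapid fall event.

    During the fall the ellipse rotates from vertical to horizontal and
    its centroid drops by about a third of the frame height; afterwards
    the subject lies still.  Labels are 1 exactly for the fall-motion
    frames unless ``label_post_fall`` extends them to the end.
    """
    if not 3 <= fall_duration <= 6:
        raise ValueError("fall_duration must lie in [3, 6]")
    if fall_onset < 8 or fall_onset + fall_duration >= n_frames:
        raise ValueError(
            f"infeasible fall window: onset {fall_onset}, duration {fall_duration}, "
            f"clip length {n_frames}"
        )
    noise = noise or NoiseParams()
    s = scene.frame_size
    rng = np.random.default_rng(scene.seed)

    # pre-fall walk: same form as normal walking, gentler pace
    period = 80.0
    amplitude = min(0.28 * s, _prefall_walk_speed(s) * period / (2 * np.pi))
    phase = rng.uniform(0, 2 * np.pi)

    def pre_pose(t: int) -> _Pose:
        if pre_behavior == "idle":
            return _standing_pose(scene, s / 2)
        cx = s / 2 + amplitude * np.sin(2 * np.pi * t / period + phase)
        return _standing_pose(scene, cx)

    stand = pre_pose(fall_onset - 1)
    drop = 0.33 * s
    side = rng.choice((-1.0, 1.0)) * 0.15 * s
    lying = _Pose(
        cy=min(stand.cy + drop, 0.92 * s - stand.rx),
        cx=float(np.clip(stand.cx + side, 0.25 * s, 0.75 * s)),
        ry=stand.ry,
        rx=stand.rx,
        angle=np.pi / 2,
    )

    poses: list[_Pose] = []
    for t in range(n_frames):
        if t < fall_onset:
            poses.append(pre_pose(t))
        elif t < fall_onset + fall_duration:
            u = (t - fall_onset + 1) / fall_duration
            poses.append(
                _Pose(
                    cy=stand.cy + u * (lying.cy - stand.cy),
                    cx=stand.cx + u * (lying.cx - stand.cx),
                    ry=stand.ry,
                    rx=stand.rx,
                    angle=u * np.pi / 2,
                )
            )
        else:
            poses.append(lying)

    post_scene = scene
    if occlude_after:
        # opaque slab over the lower half of the lying subject
        h = int(round(1.2 * stand.rx))
        w = int(round(1.4 * stand.ry))
        r = int(np.clip(round(lying.cy - 0.2 * h), 0, s - h))
        c = int(np.clip(round(lying.cx - w / 2), 0, s - w))
        post_scene = dataclasses.replace(scene, furniture=(r, c, h, w, 0.55))

    frames = []
    for t, pose in enumerate(poses):
        sc = post_scene if (occlude_after and t >= fall_onset + fall_duration) else scene
        frames.append(_render(sc, pose))
    frames = _apply_noise(np.stack(frames), noise)

    labels = np.zeros(n_frames, dtype=np.int64)
    end = n_frames if label_post_fall else fall_onset + fall_duration
    labels[fall_onset:end] = 1
    return VideoClip(
        frames=frames,
        labels=labels,
        fps=fps,
        clip_id=clip_id or f"fall_{scene.seed}",
        value_range=(0.0, 1.0),
    )


def make_dataset(
    n_train_clips: int,
    n_test_normal: int,
    n_test_fall: int,
    scene: SceneParams,
    noise: NoiseParams,
    master_seed: int,
    n_frames: int = 40,
) -> tuple[list[VideoClip], list[VideoClip]]:
    """Deterministically generate a normal-only train set and a mixed test set."""
    if min(n_train_clips, n_test_normal, n_test_fall) < 1:
        raise ValueError("all clip counts must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(
        n_train_clips + n_test_normal + n_test_fall
    )]

    def clip_params(seed: int) -> tuple[SceneParams, NoiseParams]:
        return (
            dataclasses.replace(scene, seed=seed),
            dataclasses.replace(noise, seed=seed + 1),
        )

    train: list[VideoClip] = []
    for i in range(n_train_clips):
        sc, nz = clip_params(seeds[i])
        behavior = BEHAVIORS[i % len(BEHAVIORS)]
        train.append(
            generate_normal_clip(
                sc, behavior, n_frames, nz, clip_id=f"train_{i:03d}_{behavior}"
            )
        )

    test: list[VideoClip] = []
    for i in range(n_test_normal):
        seed = seeds[n_train_clips + i]
        sc, nz = clip_params(seed)
        behavior = BEHAVIORS[i % len(BEHAVIORS)]
        test.append(
            generate_normal_clip(
                sc, behavior, n_frames, nz, clip_id=f"test_normal_{i:03d}"
            )
        )
    for i in range(n_test_fall):
        seed = seeds[n_train_clips + n_test_normal + i]
        sc, nz = clip_params(seed)
        rng = np.random.default_rng(seed + 2)
        onset = int(rng.integers(12, n_frames - 14))
        duration = int(rng.integers(4, 7))
        test.append(
            generate_fall_clip(
                sc, n_frames, onset, duration, nz, clip_id=f"test_fall_{i:03d}"
            )
        )
    return train, test
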