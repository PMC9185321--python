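"""Network definitions: frame-sequence generator, patch discriminator, flow.

The generator is a 2-D convolutional encoder-decoder that treats the 8
frames of a sequence as input channels and emits the 8-frame target
window through a tanh.  There are deliberately no skip connections: the
anomaly score compares bottleneck encodings, so the bottleneck must
summarize the whole sequence.  ``encode`` returns the global-average-
pooled bottleneck activation (the vector compared angularly at scoring
time) and shares all weights with ``generate``.

The discriminator is a patch classifier: a stack of 4x4 convolutions
whose scalar outputs each judge one receptive-field patch of a single
frame; outputs are linear because the adversarial objective is
least-squares.

The flow estimator is pluggable; the default is classical variational
(Horn-Schunck) flow expressed entirely in autograd ops, so the flow
loss is differentiable with respect to predicted frames without any
pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

FRAMES_PER_WINDOW = 8


@dataclass
class GeneratorConfig:
    frames_in: int = 8
    frames_out: int = 8
    base_channels: int = 16
    depth: int = 3
    latent_dim: int = 32

    def __post_init__(self):
        if self.frames_in != FRAMES_PER_WINDOW or self.frames_out != FRAMES_PER_WINDOW:
            raise ValueError("frames_in and frames_out must both be 8")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.latent_dim < 8:
            raise ValueError("latent_dim must be >= 8")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class DiscriminatorConfig:
    patch_receptive_field: int = 34
    base_channels: int = 16

    def __post_init__(self):
        if self.patch_receptive_field < 16:
            raise ValueError("patch_receptive_field must be >= 16")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class EncodedFeature:
    """Flattened bottleneck vector used for angular anomaly scoring."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.isfinite(self.vector).all():
            raise ValueError("encoded feature contains non-finite entries")


def receptive_field(layers: list[tuple[int, int]]) -> int:
    """Receptive field of a conv stack given (kernel, stride) per layer."""
    rf, jump = 1, 1
    for k, s in layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


def _ensure_batched(window: np.ndarray) -> tuple[np.ndarray, bool]:
    window = np.asarray(window, dtype=np.float64)
    if window.ndim == 3:
        return window[None], True
    if window.ndim == 4:
        return window, False
    raise ValueError(f"expected (8, S, S) or (B, 8, S, S); got shape {window.shape}")


class Generator:
    """Encoder-decoder over stacked frame sequences, exposing its bottleneck."""

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        bc, depth = config.base_channels, config.depth
        enc_ch = [bc * 2**i for i in range(depth)]
        self.encoder = []
        in_ch = config.frames_in
        for out_ch in enc_ch:
            self.encoder.append(nn.Conv2d(in_ch, out_ch, 4, stride=2, pad=1, rng=rng))
            in_ch = out_ch
        self.project = nn.Conv2d(in_ch, config.latent_dim, 1, rng=rng)
        self.decoder = []
        ch = config.latent_dim
        for i in reversed(range(depth)):
            out_ch = enc_ch[i - 1] if i > 0 else bc
            self.decoder.append(nn.Conv2d(ch, out_ch, 3, stride=1, pad=1, rng=rng))
            ch = out_ch
        self.head = nn.Conv2d(ch, config.frames_out, 3, stride=1, pad=1, rng=rng)

    @property
    def parameters(self) -> list[Tensor]:
        params = []
        for layer in [*self.encoder, self.project, *self.decoder, self.head]:
            params.extend(layer.parameters)
        return params

    def _check_size(self, side: int) -> None:
        if side % 2**self.config.depth != 0:
            raise ValueError(
                f"frame side {side} must be divisible by 2^depth = {2**self.config.depth}"
            )

    def _encode_tensor(self, x: Tensor) -> Tensor:
        """(B, 8, S, S) -> bottleneck map (B, latent_dim, s, s)."""
        h = x
        for layer in self.encoder:
            h = layer(h).leaky_relu(0.2)
        return self.project(h).leaky_relu(0.2)

    def forward(self, x: Tensor) -> Tensor:
        """(B, 8, S, S) in [-1, 1] -> reconstructed (B, 8, S, S) in [-1, 1]."""
        if x.ndim != 4 or x.shape[1] != self.config.frames_in:
            raise ValueError(
                f"generator input must be (B, {self.config.frames_in}, S, S); "
                f"got {x.shape}"
            )
        self._check_size(x.shape[2])
        z = self._encode_tensor(x)
        h = z
        for layer in self.decoder:
            h = layer(nn.upsample2x(h)).leaky_relu(0.2)
        return self.head(h).tanh()

    def generate(self, input_window: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper around :meth:`forward` (no gradients)."""
        batched, squeeze = _ensure_batched(input_window)
        out = self.forward(Tensor(batched)).free_graph().data
        return out[0] if squeeze else out

    def encode(self, window: np.ndarray) -> EncodedFeature | list[EncodedFeature]:
        """Flattened, spatially averaged bottleneck activation of a window."""
        batched, squeeze = _ensure_batched(window)
        z = self._encode_tensor(Tensor(batched))
        pooled = nn.global_avg_pool(z).free_graph().data
        feats = [EncodedFeature(v) for v in pooled]
        return feats[0] if squeeze else feats


class Discriminator:
    """Patch-wise least-squares discriminator over single frames.

    The layer stack is derived from the requested patch receptive field:
    m stride-2 4x4 convs followed by two stride-1 4x4 convs give an
    exact receptive field of 9 * 2**m - 2 pixels (70 at m = 3, matching
    the full-scale setting; 34 at m = 2 for desk-scale inputs).
    """

    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        m = max(1, int(round(np.log2((config.patch_receptive_field + 2) / 9.0))))
        self.n_downsample = m
        bc = config.base_channels
        self.layers = []
        in_ch = 1
        for i in range(m):
            out_ch = bc * 2**i
            self.layers.append(nn.Conv2d(in_ch, out_ch, 4, stride=2, pad=1, rng=rng))
            in_ch = out_ch
        self.layers.append(nn.Conv2d(in_ch, in_ch, 4, stride=1, pad=1, rng=rng))
        self.head = nn.Conv2d(in_ch, 1, 4, stride=1, pad=1, rng=rng)

    @property
    def parameters(self) -> list[Tensor]:
        params = []
        for layer in [*self.layers, self.head]:
            params.extend(layer.parameters)
        return params

    def layer_spec(self) -> list[tuple[int, int]]:
        return [(l.kernel, l.stride) for l in [*self.layers, self.head]]

    def receptive_field(self) -> int:
        return receptive_field(self.layer_spec())

    def forward(self, x: Tensor) -> Tensor:
        """(B, 1, S, S) -> patch score map (B, 1, h, w), linear outputs."""
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"discriminator input must be (B, 1, S, S); got {x.shape}")
        h = x
        for layer in self.layers:
            h = layer(h).leaky_relu(0.2)
        return self.head(h)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def score_frames(self, frames: np.ndarray) -> np.ndarray:
        """Numpy wrapper: (B, S, S) frames -> (B, h, w) patch score maps."""
        frames = np.asarray(frames, dtype=np.float64)
        out = self.forward(Tensor(frames[:, None])).free_graph().data
        return out[:, 0]


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Construct a generator with deterministic seeded initialization."""
    return Generator(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    """Construct a patch discriminator with deterministic seeded initialization."""
    return Discriminator(config, seed=seed)


def count_parameters(net: Generator | Discriminator) -> int:
    return sum(p.data.size for p in net.parameters)


# ---------------------------------------------------------------------------
# optical flow
# ---------------------------------------------------------------------------

_DX = np.array([[[[0.0, 0.0, 0.0], [-0.5, 0.0, 0.5], [0.0, 0.0, 0.0]]]])
_DY = np.array([[[[0.0, -0.5, 0.0], [0.0, 0.0, 0.0], [0.0, 0.5, 0.0]]]])
_HS_AVG = np.array(
    [[[[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]]]
)


class HornSchunckFlow:
    """Classical variational dense optical flow, differentiable end-to-end.

    Implements Horn-Schunck with a fixed number of Jacobi iterations, all
    expressed as autograd convolutions, so gradients flow from the flow
    field back to the input frames.  The estimator holds no trainable
    parameters and is treated as a fixed function during GAN training.
    """

    def __init__(self, alpha: float = 0.5, n_iters: int = 80):
        if alpha <= 0 or n_iters < 1:
            raise ValueError("alpha must be > 0 and n_iters >= 1")
        self.alpha = alpha
        self.n_iters = n_iters
        self._dx = Tensor(_DX)
        self._dy = Tensor(_DY)
        self._avg = Tensor(_HS_AVG)

    def _conv(self, x: Tensor, k: Tensor) -> Tensor:
        return nn.conv2d(x, k, None, stride=1, pad=1)

    def flow_tensors(self, frame_a: Tensor, frame_b: Tensor) -> tuple[Tensor, Tensor]:
        """Flow from frame_b to frame_a; inputs (B, 1, S, S).

        Returns (u, v): column-wise and row-wise displacement maps.
        """
        mean = (frame_a + frame_b) * 0.5
        ix = self._conv(mean, self._dx)
        iy = self._conv(mean, self._dy)
        it = frame_a - frame_b
        denom = Tensor(np.full_like(ix.data, self.alpha**2)) + ix * ix + iy * iy
        u = Tensor(np.zeros_like(ix.data))
        v = Tensor(np.zeros_like(ix.data))
        for _ in range(self.n_iters):
            u_avg = self._conv(u, self._avg)
            v_avg = self._conv(v, self._avg)
            t = (ix * u_avg + iy * v_avg + it) / denom
            u = u_avg - ix * t
            v = v_avg - iy * t
        return u, v

    def __call__(self, frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
        return flow_estimate(self, frame_a, frame_b)


def flow_estimate(
    estimator: HornSchunckFlow, frame_a: np.ndarray, frame_b: np.ndarray
) -> np.ndarray:
    """Dense per-pixel displacement from ``frame_b`` to ``frame_a``.

    Returns an (S, S, 2) field: channel 0 is row (vertical) displacement,
    channel 1 is column (horizontal) displacement.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape or frame_a.ndim != 2:
        raise ValueError("frames must be two identically shaped 2-D images")
    a = Tensor(frame_a[None, None])
    b = Tensor(frame_b[None, None])
    u, v = estimator.flow_tensors(a, b)
    u.free_graph()
    v.free_graph()
    return np.stack([v.data[0, 0], u.data[0, 0]], axis=-1)
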