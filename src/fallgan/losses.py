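"""Training loss terms and their weighted combination.

Four generator-side terms: per-pixel L2, gradient-difference magnitude,
optical-flow consistency, and a least-squares adversarial term, plus the
discriminator's own least-squares objective.  All losses are reported as
per-element means so their magnitudes are resolution-independent; the
weighting absorbs the difference from sum-form definitions.

Every function accepts either plain numpy arrays (returning a float) or
autograd :class:`~fallgan.nn.Tensor` inputs (returning a scalar Tensor
through which gradients flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor


class TrainingError(RuntimeError):
    pass


@dataclass
class LossWeights:
    w_l2: float = 1.0
    w_gradient: float = 1.0
    w_flow: float = 2.0
    w_adversarial: float = 0.05
    flow_norm: str = "l1"

    def __post_init__(self):
        if self.flow_norm not in ("l1", "l2"):
            raise ValueError("flow_norm must be 'l1' or 'l2'")
        weights = (self.w_l2, self.w_gradient, self.w_flow, self.w_adversarial)
        if any(w < 0 for w in weights):
            raise ValueError("loss weights must be non-negative")
        if all(w == 0 for w in weights):
            raise ValueError("at least one loss weight must be positive")


def _check_shapes(a, b, name: str) -> None:
    sa = a.shape if hasattr(a, "shape") else np.shape(a)
    sb = b.shape if hasattr(b, "shape") else np.shape(b)
    if sa != sb:
        raise ValueError(f"{name}: shape mismatch {sa} vs {sb}")


def l2_loss(target, prediction):
    """Mean squared error over all elements."""
    _check_shapes(target, prediction, "l2_loss")
    if isinstance(prediction, Tensor) or isinstance(target, Tensor):
        diff = Tensor.as_tensor(prediction) - Tensor.as_tensor(target)
        return (diff * diff).mean()
    diff = np.asarray(prediction, dtype=np.float64) - np.asarray(target, np.float64)
    return float(np.mean(diff**2))


def gradient_loss(prediction, target):
    """Mean absolute difference of adjacent-pixel gradient magnitudes.

    Acts on the last two axes (any leading batch/frame axes allowed);
    border pixels without an in-range neighbour are skipped.  The sum is
    divided by the total pixel count.
    """
    _check_shapes(prediction, target, "gradient_loss")
    tensor_mode = isinstance(prediction, Tensor) or isinstance(target, Tensor)
    p = Tensor.as_tensor(prediction) if tensor_mode else np.asarray(prediction, np.float64)
    y = Tensor.as_tensor(target) if tensor_mode else np.asarray(target, np.float64)
    if p.shape[-1] < 2 or p.shape[-2] < 2:
        raise ValueError("gradient_loss needs side >= 2")
    n = int(np.prod(p.shape))
    if tensor_mode:
        gy_t = (y[..., 1:, :] - y[..., :-1, :]).abs()
        gy_p = (p[..., 1:, :] - p[..., :-1, :]).abs()
        gx_t = (y[..., :, 1:] - y[..., :, :-1]).abs()
        gx_p = (p[..., :, 1:] - p[..., :, :-1]).abs()
        total = (gy_t - gy_p).abs().sum() + (gx_t - gx_p).abs().sum()
        return total / n
    gy = np.abs(np.abs(np.diff(y, axis=-2)) - np.abs(np.diff(p, axis=-2)))
    gx = np.abs(np.abs(np.diff(y, axis=-1)) - np.abs(np.diff(p, axis=-1)))
    return float((gy.sum() + gx.sum()) / n)


def _as_flow_batch(x) -> Tensor:
    """(S, S) or (K, S, S) or Tensor -> (K, 1, S, S) Tensor."""
    t = Tensor.as_tensor(x)
    if t.ndim == 2:
        return t.reshape(1, 1, *t.shape)
    if t.ndim == 3:
        return t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    raise ValueError(f"expected (S, S) or (K, S, S) frames; got {t.shape}")


def flow_loss(estimator, pred_next, true_next, current, norm: str = "l1"):
    """Discrepancy between predicted-frame flow and true-frame flow.

    Both flows are taken against the same preceding frame(s); stacks of
    K frames are averaged over the K triples as well as over pixels and
    the two flow components.  ``norm`` selects mean-absolute ("l1") or
    mean-squared ("l2") aggregation of the per-pixel differences.
    """
    _check_shapes(pred_next, true_next, "flow_loss")
    _check_shapes(pred_next, current, "flow_loss")
    tensor_mode = isinstance(pred_next, Tensor)
    p = _as_flow_batch(pred_next)
    t = _as_flow_batch(true_next)
    c = _as_flow_batch(current)
    u_p, v_p = estimator.flow_tensors(p, c)
    # the authentic-frame flow is a constant; keep its graph out of backward
    u_t, v_t = estimator.flow_tensors(t.detach(), c.detach())
    u_t, v_t = u_t.free_graph().detach(), v_t.free_graph().detach()
    du, dv = u_p - u_t, v_p - v_t
    if norm == "l1":
        loss = (du.abs().mean() + dv.abs().mean()) * 0.5
    elif norm == "l2":
        loss = ((du * du).mean() + (dv * dv).mean()) * 0.5
    else:
        raise ValueError("norm must be 'l1' or 'l2'")
    return loss if tensor_mode else loss.free_graph().item()


def _patch_scores(d, window) -> Tensor:
    """Apply the patch discriminator to every frame of a window stack."""
    t = Tensor.as_tensor(window)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    elif t.ndim == 4:  # (B, F, S, S): frames judged individually
        b, f, s1, s2 = t.shape
        t = t.reshape(b * f, 1, s1, s2)
    else:
        raise ValueError(f"cannot interpret window of shape {t.shape}")
    return Tensor.as_tensor(d(t))


def adversarial_d_loss(d, real_window, fake_window):
    """Least-squares discriminator loss: reals toward 1, fakes toward 0."""
    _check_shapes(real_window, fake_window, "adversarial_d_loss")
    tensor_mode = isinstance(real_window, Tensor) or isinstance(fake_window, Tensor)
    s_real = _patch_scores(d, real_window)
    s_fake = _patch_scores(d, fake_window)
    one = Tensor(np.ones(()))
    loss = ((s_real - one) ** 2).mean() * 0.5 + (s_fake**2).mean() * 0.5
    return loss if tensor_mode else loss.free_graph().item()


def adversarial_g_loss(d, fake_window):
    """Least-squares generator loss: fakes pushed toward label 1."""
    s_fake = _patch_scores(d, fake_window)
    one = Tensor(np.ones(()))
    loss = ((s_fake - one) ** 2).mean() * 0.5
    return loss if isinstance(fake_window, Tensor) else loss.free_graph().item()


def hybrid_g_loss(weights: LossWeights, terms: dict):
    """Weighted sum of the four generator terms.

    ``terms`` maps {"l2", "gradient", "flow", "adversarial"} to scalars
    (floats or Tensors).  Returns (total, breakdown) where breakdown is
    a dict of plain floats for logging.
    """
    expected = {"l2": weights.w_l2, "gradient": weights.w_gradient,
                "flow": weights.w_flow, "adversarial": weights.w_adversarial}
    unknown = set(terms) - set(expected)
    if unknown:
        raise ValueError(f"unknown loss terms: {sorted(unknown)}")
    breakdown = {}
    total = None
    for name, weight in expected.items():
        term = terms.get(name, 0.0)
        value = term.item() if isinstance(term, Tensor) else float(term)
        if not np.isfinite(value):
            raise TrainingError(f"non-finite {name} loss term: {value}")
        breakdown[name] = value
        if weight == 0.0:
            continue
        contrib = term * weight
        total = contrib if total is None else total + contrib
    if total is None:
        total = 0.0
    return total, breakdown
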