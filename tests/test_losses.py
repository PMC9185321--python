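"""Loss terms against independent brute-force double-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from fallgan.losses import (
    LossWeights,
    TrainingError,
    adversarial_d_loss,
    adversarial_g_loss,
    flow_loss,
    gradient_loss,
    hybrid_g_loss,
    l2_loss,
)
from fallgan.networks import HornSchunckFlow, flow_estimate
from fallgan.nn import Tensor


# ---------------------------------------------------------------------------
# independent oracles (explicit python loops, no numpy vectorization)
# ---------------------------------------------------------------------------


def l2_oracle(target, prediction):
    total, count = 0.0, 0
    for yp, pp in zip(target.ravel(), prediction.ravel()):
        total += (yp - pp) ** 2
        count += 1
    return total / count


def gradient_oracle(prediction, target):
    h, w = target.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            if i >= 1:
                total += abs(
                    abs(target[i, j] - target[i - 1, j])
                    - abs(prediction[i, j] - prediction[i - 1, j])
                )
            if j >= 1:
                total += abs(
                    abs(target[i, j - 1] - target[i, j])
                    - abs(prediction[i, j - 1] - prediction[i, j])
                )
    return total / (h * w)


def adv_d_oracle(real_maps, fake_maps):
    vals = []
    for m in real_maps:
        for v in m.ravel():
            vals.append(0.5 * (v - 1.0) ** 2)
    total_real = sum(vals) / len(vals)
    vals = []
    for m in fake_maps:
        for v in m.ravel():
            vals.append(0.5 * v**2)
    return total_real + sum(vals) / len(vals)


def adv_g_oracle(fake_maps):
    vals = []
    for m in fake_maps:
        for v in m.ravel():
            vals.append(0.5 * (v - 1.0) ** 2)
    return sum(vals) / len(vals)


class StubDiscriminator:
    """Maps each input frame to a fixed-size patch map via a function."""

    def __init__(self, fn, map_side=3):
        self.fn = fn
        self.map_side = map_side

    def __call__(self, x):
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        n = data.shape[0]
        out = np.stack([self.fn(data[i]) for i in range(n)])
        return out.reshape(n, 1, self.map_side, self.map_side)


def const_d(value, map_side=3):
    return StubDiscriminator(
        lambda frame: np.full((map_side, map_side), float(value)), map_side
    )


class TestL2Loss:
    def test_identity_zero(self, rng):
        x = rng.normal(size=(5, 5))
        assert l2_loss(x, x) == 0.0

    def test_unit_example(self):
        assert l2_loss(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_matches_oracle(self, rng):
        t = rng.normal(size=(5, 5))
        p = rng.normal(size=(5, 5))
        assert l2_loss(t, p) == pytest.approx(l2_oracle(t, p), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            l2_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_tensor_path_matches_numpy(self, rng):
        t = rng.normal(size=(4, 4))
        p = rng.normal(size=(4, 4))
        tensor_val = l2_loss(Tensor(t), Tensor(p)).item()
        assert tensor_val == pytest.approx(l2_loss(t, p), abs=1e-12)


class TestGradientLoss:
    def test_identity_zero(self, rng):
        x = rng.normal(size=(6, 6))
        assert gradient_loss(x, x) == 0.0

    def test_constant_offset_invariance(self, rng):
        y = rng.normal(size=(6, 6))
        assert gradient_loss(y + 3.7, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self, rng):
        y = rng.normal(size=(6, 6))
        p = rng.normal(size=(6, 6))
        assert gradient_loss(p, y) == pytest.approx(gradient_oracle(p, y), abs=1e-12)

    def test_tensor_path_matches_oracle(self, rng):
        y = rng.normal(size=(6, 6))
        p = rng.normal(size=(6, 6))
        val = gradient_loss(Tensor(p), Tensor(y)).item()
        assert val == pytest.approx(gradient_oracle(p, y), abs=1e-12)

    @given(
        img=arrays(np.float64, (5, 5), elements=st.floats(-10, 10)),
        offset=st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_offset_invariance_property(self, img, offset):
        # invariant both when shifting both images and when shifting one
        assert gradient_loss(img + offset, img) == pytest.approx(0.0, abs=1e-9)
        other = np.roll(img, 1, axis=0)
        base = gradient_loss(other, img)
        assert gradient_loss(other + offset, img + offset) == pytest.approx(
            base, abs=1e-9
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gradient_loss(np.zeros((1, 5)), np.zeros((1, 5)))


class TestFlowLoss:
    def test_identical_prediction_zero(self, rng):
        est = HornSchunckFlow(n_iters=10)
        cur = rng.normal(size=(16, 16))
        nxt = np.roll(cur, 1, axis=1)
        assert flow_loss(est, nxt, nxt, cur) == pytest.approx(0.0, abs=1e-12)

    def test_missed_motion_positive(self):
        est = HornSchunckFlow(n_iters=30)
        xx = np.meshgrid(np.arange(24), np.arange(24))[0].astype(float)
        cur = np.sin(2 * np.pi * xx / 12)
        true_next = np.roll(cur, 2, axis=1)
        assert flow_loss(est, cur, true_next, cur) > 0.01

    def test_compositional_oracle(self, rng):
        # flow_loss equals direct recomputation from two flow_estimate calls
        est = HornSchunckFlow(n_iters=20)
        base = rng.normal(size=(12, 12))
        from scipy.ndimage import gaussian_filter

        cur = gaussian_filter(base, 2.0)
        pred = gaussian_filter(rng.normal(size=(12, 12)), 2.0)
        true = np.roll(cur, 1, axis=0)
        f_pred = flow_estimate(est, pred, cur)
        f_true = flow_estimate(est, true, cur)
        expected = np.abs(f_pred - f_true).mean()
        assert flow_loss(est, pred, true, cur) == pytest.approx(expected, abs=1e-12)

    def test_stack_averages_over_triples(self, rng):
        est = HornSchunckFlow(n_iters=10)
        pred = rng.normal(size=(3, 8, 8))
        true = rng.normal(size=(3, 8, 8))
        cur = rng.normal(size=(3, 8, 8))
        singles = [
            flow_loss(est, pred[i], true[i], cur[i]) for i in range(3)
        ]
        assert flow_loss(est, pred, true, cur) == pytest.approx(
            np.mean(singles), abs=1e-12
        )

    def test_l2_norm_option(self, rng):
        est = HornSchunckFlow(n_iters=10)
        pred, true, cur = (rng.normal(size=(8, 8)) for _ in range(3))
        f_pred = flow_estimate(est, pred, cur)
        f_true = flow_estimate(est, true, cur)
        expected = ((f_pred - f_true) ** 2).mean()
        assert flow_loss(est, pred, true, cur, norm="l2") == pytest.approx(
            expected, abs=1e-12
        )


class TestAdversarialLosses:
    def test_d_half_everywhere(self, rng):
        d = const_d(0.5)
        w = rng.normal(size=(2, 8, 8))
        assert adversarial_d_loss(d, w, w) == pytest.approx(0.25, abs=1e-12)

    def test_perfect_discriminator_zero(self, rng):
        real = rng.normal(size=(2, 8, 8))
        fake = real + 10.0
        d = StubDiscriminator(lambda f: np.full((3, 3), 1.0 if f.mean() < 5 else 0.0))
        assert adversarial_d_loss(d, real, fake) == pytest.approx(0.0, abs=1e-12)

    def test_d_matches_oracle(self, rng):
        maps = {}

        def fn(frame):
            key = frame.tobytes()
            if key not in maps:
                maps[key] = rng.normal(size=(3, 3))
            return maps[key]

        d = StubDiscriminator(fn)
        real = rng.normal(size=(4, 6, 6))
        fake = rng.normal(size=(4, 6, 6))
        real_maps = [fn(f) for f in real]
        fake_maps = [fn(f) for f in fake]
        assert adversarial_d_loss(d, real, fake) == pytest.approx(
            adv_d_oracle(real_maps, fake_maps), abs=1e-12
        )

    def test_g_perfect_confusion_zero(self, rng):
        assert adversarial_g_loss(const_d(1.0), rng.normal(size=(2, 8, 8))) == 0.0

    def test_g_rejected_half(self, rng):
        assert adversarial_g_loss(const_d(0.0), rng.normal(size=(2, 8, 8))) == pytest.approx(0.5)

    def test_g_matches_oracle(self, rng):
        cache = {}

        def fn(frame):
            key = frame.tobytes()
            if key not in cache:
                cache[key] = rng.normal(size=(3, 3))
            return cache[key]

        d = StubDiscriminator(fn)
        fake = rng.normal(size=(3, 6, 6))
        fake_maps = [fn(f) for f in fake]
        assert adversarial_g_loss(d, fake) == pytest.approx(
            adv_g_oracle(fake_maps), abs=1e-12
        )

    def test_d_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            adversarial_d_loss(const_d(0.5), np.zeros((2, 4, 4)), np.zeros((3, 4, 4)))


class TestHybrid:
    def test_l2_only(self):
        w = LossWeights(w_l2=1, w_gradient=0, w_flow=0, w_adversarial=0)
        total, breakdown = hybrid_g_loss(w, {"l2": 0.37})
        assert total == pytest.approx(0.37)
        assert breakdown["l2"] == 0.37

    def test_all_zero_terms(self):
        total, _ = hybrid_g_loss(
            LossWeights(), {"l2": 0.0, "gradient": 0.0, "flow": 0.0, "adversarial": 0.0}
        )
        assert (total.item() if isinstance(total, Tensor) else float(total)) == 0.0

    def test_weighted_arithmetic(self):
        w = LossWeights(w_l2=1, w_gradient=1, w_flow=2, w_adversarial=0.05)
        total, _ = hybrid_g_loss(
            w, {"l2": 0.1, "gradient": 0.2, "flow": 0.05, "adversarial": 0.4}
        )
        assert total == pytest.approx(0.42)

    def test_non_finite_named(self):
        with pytest.raises(TrainingError, match="gradient"):
            hybrid_g_loss(LossWeights(), {"l2": 0.1, "gradient": float("nan")})

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            hybrid_g_loss(LossWeights(), {"vgg": 0.1})


class TestLossWeights:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_l2=0, w_gradient=0, w_flow=0, w_adversarial=0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_l2=-1)

    def test_bad_flow_norm(self):
        with pytest.raises(ValueError):
            LossWeights(flow_norm="linf")


class TestNonNegativity:
    @given(
        t=arrays(np.float64, (4, 4), elements=st.floats(-5, 5)),
        p=arrays(np.float64, (4, 4), elements=st.floats(-5, 5)),
    )
    @settings(max_examples=40, deadline=None)
    def test_l2_and_gradient_nonnegative(self, t, p):
        assert l2_loss(t, p) >= 0.0
        assert gradient_loss(p, t) >= 0.0
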