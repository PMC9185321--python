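"""Alternating adversarial training on normal-only sequence samples.

Each iteration draws a batch of 8-in / 8-target windows, updates the
discriminator on real targets vs. detached reconstructions, then updates
the generator on the weighted hybrid loss.  The learning rate follows a
step schedule (decay by a fixed factor every N iterations).  Runs are
fully reproducible under a fixed seed, and checkpoints capture enough
state (parameters, Adam moments, RNG, epoch permutation) that a resumed
run is bit-identical to an unbroken one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from .losses import LossWeights, TrainingError
from .networks import (
    Discriminator,
    DiscriminatorConfig,
    Generator,
    GeneratorConfig,
    HornSchunckFlow,
)
from .nn import Adam, Tensor
from .video_io import VideoClip, window_sequences

logger = logging.getLogger(__name__)

LOG_COLUMNS = (
    "iteration", "lr", "loss_d", "loss_g",
    "l2", "gradient", "flow", "adversarial",
)


@dataclass
class TrainConfig:
    batch_size: int = 4
    lr_initial: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 1000
    max_iterations: int = 300
    seed: int = 0
    d_steps_per_g_step: int = 1
    flow_pairs: int = 4  # how many of the 4 future (pred, true, prev) triples to use
    checkpoint_every: int = 0  # 0: only final checkpoint
    log_every: int = 1

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.lr_decay_every < 1 or self.max_iterations < 0:
            raise ValueError("invalid schedule")
        if not 0 <= self.flow_pairs <= 4:
            raise ValueError("flow_pairs must lie in [0, 4]")


def learning_rate(config: TrainConfig, iteration: int) -> float:
    """lr at a (0-based) iteration: initial * factor ** (n // decay_every)."""
    return config.lr_initial * config.lr_decay_factor ** (
        iteration // config.lr_decay_every
    )


@dataclass
class TrainResult:
    generator: Generator
    discriminator: Discriminator
    log: list[dict]
    checkpoint_path: Path | None = None


@dataclass
class _WindowIndex:
    """Lazy index of all stride-1 training windows across clips."""

    clips: list[VideoClip]
    entries: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for ci, clip in enumerate(self.clips):
            samples = window_sequences(clip, stride=1)
            if not samples:
                logger.warning("clip %r yields no training windows", clip.clip_id)
            self.entries.extend((ci, s.anchor_index) for s in samples)
        if not self.entries:
            raise TrainingError("training clips yield no sequence samples")

    def batch(self, picks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        inputs, targets = [], []
        for k in picks:
            ci, anchor = self.entries[int(k)]
            frames = self.clips[ci].frames
            start = anchor - 7
            inputs.append(frames[start : anchor + 1])
            targets.append(frames[start + 4 : anchor + 5])
        return np.stack(inputs), np.stack(targets)


def _validate_normal_only(clips: list[VideoClip]) -> None:
    for clip in clips:
        if clip.has_fall_frames():
            raise TrainingError(
                f"clip {clip.clip_id!r} contains fall-labeled frames; "
                "training data must be normal-only"
            )


def _rng_state_json(rng: np.random.Generator) -> str:
    return json.dumps(rng.bit_generator.state)


def _rng_from_state(state_json: str) -> np.random.Generator:
    rng = np.random.default_rng()
    rng.bit_generator.state = json.loads(state_json)
    return rng


class _EpochSampler:
    """Shuffled pass over all windows, reshuffling when exhausted."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.perm = rng.permutation(n)
        self.pos = 0

    def draw(self, k: int) -> np.ndarray:
        out = []
        while len(out) < k:
            if self.pos >= self.n:
                self.perm = self.rng.permutation(self.n)
                self.pos = 0
            take = min(k - len(out), self.n - self.pos)
            out.extend(self.perm[self.pos : self.pos + take])
            self.pos += take
        return np.asarray(out)


def save_checkpoint(
    path: str | Path,
    gen: Generator,
    disc: Discriminator,
    opt_g: Adam,
    opt_d: Adam,
    iteration: int,
    sampler: _EpochSampler,
    train_config: TrainConfig,
    weights: LossWeights,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for tag, params in (("g", gen.parameters), ("d", disc.parameters)):
        for i, p in enumerate(params):
            arrays[f"{tag}_param_{i}"] = p.data
    for tag, opt in (("g", opt_g), ("d", opt_d)):
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            arrays[f"{tag}_adam_m_{i}"] = m
            arrays[f"{tag}_adam_v_{i}"] = v
    arrays["perm"] = sampler.perm
    meta = {
        "iteration": iteration,
        "opt_t": {"g": opt_g.t, "d": opt_d.t},
        "sampler_pos": sampler.pos,
        "rng_state": json.loads(_rng_state_json(sampler.rng)),
        "gen_config": dataclasses.asdict(gen.config),
        "disc_config": dataclasses.asdict(disc.config),
        "train_config": dataclasses.asdict(train_config),
        "weights": dataclasses.asdict(weights),
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)
    return path


def load_checkpoint(path: str | Path) -> dict:
    with np.load(Path(path), allow_pickle=False) as data:
        out = {k: data[k] for k in data.files}
    out["meta"] = json.loads(str(out["meta"]))
    return out


def load_generator(path: str | Path) -> Generator:
    """Rebuild just the generator from a checkpoint (for scoring)."""
    ck = load_checkpoint(path)
    gen = Generator(GeneratorConfig(**ck["meta"]["gen_config"]))
    for i, p in enumerate(gen.parameters):
        p.data = ck[f"g_param_{i}"].copy()
    return gen


def _restore(ck: dict, clips: list[VideoClip]) -> tuple:
    meta = ck["meta"]
    gen = Generator(GeneratorConfig(**meta["gen_config"]))
    disc = Discriminator(DiscriminatorConfig(**meta["disc_config"]))
    for tag, net in (("g", gen), ("d", disc)):
        for i, p in enumerate(net.parameters):
            p.data = ck[f"{tag}_param_{i}"].copy()
    opt_g, opt_d = Adam(gen.parameters), Adam(disc.parameters)
    for tag, opt in (("g", opt_g), ("d", opt_d)):
        opt.t = meta["opt_t"][tag]
        opt.m = [ck[f"{tag}_adam_m_{i}"].copy() for i in range(len(opt.params))]
        opt.v = [ck[f"{tag}_adam_v_{i}"].copy() for i in range(len(opt.params))]
    index = _WindowIndex(clips)
    rng = _rng_from_state(json.dumps(meta["rng_state"]))
    sampler = _EpochSampler.__new__(_EpochSampler)
    sampler.n = len(index.entries)
    sampler.rng = rng
    sampler.perm = ck["perm"].copy()
    sampler.pos = int(meta["sampler_pos"])
    return gen, disc, opt_g, opt_d, index, sampler, meta


def _train_loop(
    gen: Generator,
    disc: Discriminator,
    flow: HornSchunckFlow | None,
    index: _WindowIndex,
    sampler: _EpochSampler,
    opt_g: Adam,
    opt_d: Adam,
    config: TrainConfig,
    weights: LossWeights,
    start_iteration: int,
    out_dir: Path | None,
) -> TrainResult:
    log: list[dict] = []
    use_flow = weights.w_flow > 0 and config.flow_pairs > 0
    if use_flow and flow is None:
        flow = HornSchunckFlow(n_iters=20)
    ck_path: Path | None = None

    for it in range(start_iteration, config.max_iterations):
        lr = learning_rate(config, it)
        picks = sampler.draw(config.batch_size)
        inputs, targets = index.batch(picks)
        x = Tensor(inputs)
        target_t = Tensor(targets)

        recon = gen.forward(x)
        fake_const = recon.detach()

        # --- discriminator half-step(s): fakes detached --------------------
        loss_d_val = 0.0
        if weights.w_adversarial > 0:
            for _ in range(config.d_steps_per_g_step):
                opt_d.zero_grad()
                loss_d = L.adversarial_d_loss(disc, target_t, fake_const)
                loss_d.backward()
                opt_d.step(lr)
                loss_d_val = loss_d.item()
            opt_d.zero_grad()

        # --- generator step ------------------------------------------------
        terms: dict = {}
        if weights.w_l2 > 0:
            terms["l2"] = L.l2_loss(target_t, recon)
        if weights.w_gradient > 0:
            terms["gradient"] = L.gradient_loss(recon, target_t)
        if use_flow:
            k = config.flow_pairs
            b, _, s, _ = inputs.shape
            pred_next = recon[:, 4 : 4 + k].reshape(b * k, s, s)
            true_next = targets[:, 4 : 4 + k].reshape(b * k, s, s)
            current = targets[:, 3 : 3 + k].reshape(b * k, s, s)
            terms["flow"] = L.flow_loss(
                flow, pred_next, true_next, current, norm=weights.flow_norm
            )
        if weights.w_adversarial > 0:
            terms["adversarial"] = L.adversarial_g_loss(disc, recon)
        total, breakdown = L.hybrid_g_loss(weights, terms)
        if not isinstance(total, Tensor):
            raise TrainingError("generator loss has no trainable terms")
        if not np.isfinite(total.item()):
            raise TrainingError(
                f"non-finite generator loss at iteration {it}: {breakdown}"
            )
        opt_g.zero_grad()
        total.backward()
        opt_g.step(lr)
        opt_g.zero_grad()
        opt_d.zero_grad()

        if (it + 1) % config.log_every == 0 or it == config.max_iterations - 1:
            log.append(
                {
                    "iteration": it,
                    "lr": lr,
                    "loss_d": loss_d_val,
                    "loss_g": total.item(),
                    **{k: breakdown.get(k, 0.0) for k in ("l2", "gradient", "flow", "adversarial")},
                }
            )
        if (
            out_dir is not None
            and config.checkpoint_every
            and (it + 1) % config.checkpoint_every == 0
        ):
            ck_path = save_checkpoint(
                out_dir / f"checkpoint_{it + 1:06d}.npz",
                gen, disc, opt_g, opt_d, it + 1, sampler, config, weights,
            )

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        ck_path = save_checkpoint(
            out_dir / "checkpoint_final.npz",
            gen, disc, opt_g, opt_d, config.max_iterations, sampler, config, weights,
        )
        write_log_csv(out_dir / "training_log.csv", log)
    return TrainResult(gen, disc, log, ck_path)


def train(
    gen: Generator,
    disc: Discriminator,
    flow: HornSchunckFlow | None,
    train_clips: list[VideoClip],
    config: TrainConfig,
    weights: LossWeights | None = None,
    out_dir: str | Path | None = None,
) -> TrainResult:
    """Train the GAN on normal-only clips; see module docstring."""
    weights = weights or LossWeights()
    _validate_normal_only(train_clips)
    index = _WindowIndex(train_clips)
    rng = np.random.default_rng(config.seed)
    sampler = _EpochSampler(len(index.entries), rng)
    opt_g, opt_d = Adam(gen.parameters), Adam(disc.parameters)
    out = Path(out_dir) if out_dir is not None else None
    return _train_loop(
        gen, disc, flow, index, sampler, opt_g, opt_d, config, weights, 0, out
    )


def resume(
    checkpoint: str | Path,
    train_clips: list[VideoClip],
    config: TrainConfig,
    flow: HornSchunckFlow | None = None,
    out_dir: str | Path | None = None,
    gen_config: GeneratorConfig | None = None,
    disc_config: DiscriminatorConfig | None = None,
) -> TrainResult:
    """Continue training from a checkpoint until ``config.max_iterations``.

    Keys of ``config`` that change the data pipeline or optimizer
    semantics must match the checkpointed config; ``max_iterations``,
    checkpoint cadence and logging cadence may differ.  If model configs
    are supplied they are validated against the checkpointed ones.
    """
    _validate_normal_only(train_clips)
    ck = load_checkpoint(checkpoint)
    for name, requested, stored_dict in (
        ("model", gen_config, ck["meta"]["gen_config"]),
        ("discriminator", disc_config, ck["meta"]["disc_config"]),
    ):
        if requested is not None:
            diff = [
                k
                for k, v in dataclasses.asdict(requested).items()
                if stored_dict.get(k) != v
            ]
            if diff:
                raise ValueError(f"resume {name} config mismatch on keys: {diff}")
    gen, disc, opt_g, opt_d, index, sampler, meta = _restore(ck, train_clips)
    stored = TrainConfig(**meta["train_config"])
    mutable = {"max_iterations", "checkpoint_every", "log_every"}
    mismatched = [
        f.name
        for f in dataclasses.fields(TrainConfig)
        if f.name not in mutable
        and getattr(stored, f.name) != getattr(config, f.name)
    ]
    if mismatched:
        raise ValueError(f"resume config mismatch on keys: {mismatched}")
    weights = LossWeights(**meta["weights"])
    out = Path(out_dir) if out_dir is not None else None
    return _train_loop(
        gen, disc, flow, index, sampler, opt_g, opt_d,
        config, weights, int(meta["iteration"]), out,
    )


def write_log_csv(path: str | Path, log: list[dict]) -> None:
    lines = [",".join(LOG_COLUMNS)]
    for row in log:
        lines.append(",".join(repr(row[c]) for c in LOG_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")
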