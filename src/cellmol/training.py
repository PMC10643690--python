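"""Contrastive pre-training loop.

Optimization follows the recipe used throughout contrastive image/structure
pre-training: Adam with decoupled weight decay (0.1), a linear warm-up
followed by cosine annealing with hard restarts every few epochs, fixed
(not learned) inverse temperature, and in-batch Hopfield memories for the
InfoLOOB objective.  The warm-up length auto-scales to min(20000,
total_steps / 10) so that short desk-scale runs still see a ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import ContrastiveModel
from .nn import Tensor
from .objectives import infoloob_loss_t, infonce_loss_t

__all__ = ["TrainConfig", "AdamW", "lr_schedule", "train", "TrainResult"]


@dataclass
class TrainConfig:
    objective: str = "infonce"          # or "infoloob_hopfield"
    tau_inv: float = 14.3               # 14.3 retrieval regime, 30 activity
    beta: float = 22.0                  # Hopfield scaling (InfoLOOB only)
    base_lr: float = 1e-3
    weight_decay: float = 0.1
    warmup_steps: int = 20000           # auto-scaled down for short runs
    restart_period_epochs: int = 7
    steps_per_cycle: int | None = None  # overrides the epoch-based period
    batch_size: int = 256
    epochs: int = 1
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.objective not in ("infonce", "infoloob_hopfield"):
            raise ValueError(f"unknown objective: {self.objective}")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")
        if self.objective == "infoloob_hopfield" and self.batch_size < 2:
            raise ValueError("InfoLOOB requires batch_size >= 2")
        if self.tau_inv <= 0:
            raise ValueError("tau_inv must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def lr_schedule(step: int, base_lr: float, warmup_steps: int,
                steps_per_cycle: int) -> float:
    """Linear warm-up to base_lr, then cosine decay to 0 within each cycle
    with a hard reset at cycle boundaries."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if steps_per_cycle < 1:
        raise ValueError("steps_per_cycle must be >= 1")
    if step < warmup_steps:
        return base_lr * step / warmup_steps
    t = ((step - warmup_steps) % steps_per_cycle) / steps_per_cycle
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * t))


class AdamW(object):
    """Adam with decoupled weight decay: the decay step multiplies the
    weights directly and never enters the moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * update


@dataclass
class TrainResult:
    model: ContrastiveModel
    loss_trace: list[float] = field(default_factory=list)
    config: TrainConfig | None = None


def train(model: ContrastiveModel, images: np.ndarray,
          fingerprints: np.ndarray, config: TrainConfig) -> TrainResult:
    """Train the paired encoders on matched (image, fingerprint) batches.

    ``images`` is (N, C, H, W) already normalized; ``fingerprints`` is
    (N, fp_bits) binary, row-aligned with images.  A fixed seed reproduces
    the loss trace exactly on one device.  A non-finite loss aborts with a
    diagnostic rather than silently continuing.
    """
    images = np.asarray(images, dtype=np.float64)
    fingerprints = np.asarray(fingerprints, dtype=np.float64)
    n = images.shape[0]
    if fingerprints.shape[0] != n:
        raise ValueError("images and fingerprints must be row-aligned")
    if n < config.batch_size:
        raise ValueError("dataset smaller than one batch")

    rng = np.random.default_rng(config.seed)
    steps_per_epoch = n // config.batch_size
    total_steps = config.epochs * steps_per_epoch
    if config.max_steps is not None:
        total_steps = min(total_steps, config.max_steps)
    warmup = min(config.warmup_steps, max(total_steps // 10, 1))
    steps_per_cycle = config.steps_per_cycle if config.steps_per_cycle \
        else max(config.restart_period_epochs * steps_per_epoch, 1)

    params = model.parameters()
    opt = AdamW(params, lr=config.base_lr, weight_decay=config.weight_decay)
    model.train()
    trace: list[float] = []
    step = 0
    while step < total_steps:
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            if step >= total_steps:
                break
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            x_emb, _ = model.image_encoder(images[idx])
            z_emb, _ = model.structure_encoder(fingerprints[idx])
            if config.objective == "infonce":
                loss = infonce_loss_t(x_emb, z_emb, config.tau_inv)
            else:
                loss = infoloob_loss_t(x_emb, z_emb, config.beta,
                                       config.tau_inv)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value!r} at step {step}; "
                    "lower the learning rate or inverse temperature")
            opt.zero_grad()
            loss.backward()
            opt.lr = lr_schedule(step, config.base_lr, warmup,
                                 steps_per_cycle)
            opt.step()
            trace.append(value)
            step += 1
    model.eval()
    return TrainResult(model=model, loss_trace=trace, config=config)
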