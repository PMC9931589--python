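"""Self-supervised optimisation of the denoiser.

The only data the trainer ever sees is the noisy stack itself: pairs are built
by temporal deinterleaving, the loss is the arithmetic average of per-voxel L1
and L2 terms, the optimiser is Adam with moment decays (0.5, 0.9), and the
model of the last epoch is the final solution (no validation-based selection).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, UNet3D
from .io_formats import VideoStack, VolumeSeries
from .model import UNet3DConfig, build_unet
from .patches import TrainingPair, augment, extract_training_pairs

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainState", "preprocess", "loss", "loss_and_grad", "fit"]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    moment_decays: tuple[float, float] = (0.5, 0.9)
    epochs: int = 20
    batch_size: int = 1
    n_pairs: int = 3000
    patch: tuple[int, int, int] = (150, 150, 150)
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("rates must be positive and epochs/batch_size >= 1")
        if not all(0 < b < 1 for b in self.moment_decays):
            raise ValueError("moment decays must lie in (0, 1)")


@dataclass
class TrainState:
    stack_mean: float
    history: list[float]
    final_model: UNet3D
    model_config: UNet3DConfig


def preprocess(stack: VideoStack) -> tuple[VideoStack, float]:
    """Subtract the whole-stack average; return (centered stack, mean)."""
    mean = float(stack.data.mean())
    centered = stack.with_data(
        (stack.data.astype(np.float32) - np.float32(mean)),
        name=stack.name + "-centered",
    )
    return centered, mean


def loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Composite loss 0.5 * (mean|r| + mean r^2) with r = pred - target."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    r = pred - target
    return float(0.5 * (np.mean(np.abs(r)) + np.mean(r * r)))


def loss_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the prediction."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    r = (pred - target).astype(np.float32)
    n = r.size
    value = float(0.5 * (np.mean(np.abs(r)) + np.mean(r.astype(np.float64) ** 2)))
    grad = (0.5 / n) * (np.sign(r) + 2.0 * r)
    return value, grad


def _collect_pairs(
    source: VideoStack | VolumeSeries, cfg: TrainConfig
) -> list[TrainingPair]:
    if isinstance(source, VolumeSeries):
        stacks = source.planes
    else:
        stacks = [source]
    per = -(-cfg.n_pairs // len(stacks))  # spread the budget across planes
    pairs: list[TrainingPair] = []
    for i, st in enumerate(stacks):
        want = min(per, cfg.n_pairs - len(pairs))
        if want <= 0:
            break
        pairs.extend(extract_training_pairs(st, want, cfg.patch, seed=cfg.seed + i))
    return pairs


def fit(
    source: VideoStack | VolumeSeries,
    model_cfg: UNet3DConfig,
    train_cfg: TrainConfig,
) -> TrainState:
    """Train the denoiser on a noisy stack (or all planes of a volume series).

    One epoch is one pass over the extracted pairs; pair origins are fixed and
    each epoch re-draws the augmentation form of every pair from the seeded
    stream.  The model of the last epoch is returned.
    """
    if isinstance(source, VolumeSeries):
        centered_planes = []
        means = []
        for p in source.planes:
            c, m = preprocess(p)
            centered_planes.append(c)
            means.append(m)
        # a single model is trained on all planes; one global mean restores it
        stack_mean = float(np.mean(means))
        centered: VideoStack | VolumeSeries = VolumeSeries(
            planes=centered_planes, z_spacing=source.z_spacing
        )
    else:
        centered, stack_mean = preprocess(source)

    pairs = _collect_pairs(centered, train_cfg)
    net = build_unet(model_cfg, seed=train_cfg.seed)
    opt = Adam(net, lr=train_cfg.learning_rate, betas=train_cfg.moment_decays)
    rng = np.random.default_rng(train_cfg.seed + 1)

    history: list[float] = []
    for epoch in range(train_cfg.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(pairs))
        epoch_losses: list[float] = []
        batch_count = 0
        net.zero_grad()
        for j, idx in enumerate(order):
            pair = pairs[idx]
            if train_cfg.augment:
                pair = augment(pair, rng)
            pred = net.forward(pair.input.astype(np.float32))
            value, grad = loss_and_grad(pred, pair.target.astype(np.float32))
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {j}; try lowering "
                    f"the learning rate ({train_cfg.learning_rate:g})"
                )
            net.backward(grad / train_cfg.batch_size)
            epoch_losses.append(value)
            batch_count += 1
            if batch_count == train_cfg.batch_size or j == len(order) - 1:
                opt.step()
                net.zero_grad()
                batch_count = 0
        history.append(float(np.mean(epoch_losses)))
        logger.info(
            "epoch %d/%d: mean loss %.6g (%.1f s)",
            epoch + 1, train_cfg.epochs, history[-1], time.perf_counter() - t0,
        )
    return TrainState(
        stack_mean=stack_mean,
        history=history,
        final_model=net,
        model_config=model_cfg,
    )
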