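"""Lightweight all-3D encoder-decoder: configuration, construction, accounting.

The lightweight network (width multiplier 1) has exactly 1,020,337 trainable
scalars; the four-fold wider reference network has exactly 16,315,585.  The
multiplier scales hidden-to-hidden convolutions quadratically and the boundary
convolutions linearly, so the ratio between the two totals is ~16 (not exactly
16).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._nn import UNet3D

__all__ = [
    "UNet3DConfig",
    "build_unet",
    "count_params",
    "save_checkpoint",
    "load_checkpoint",
    "LIGHTWEIGHT_PARAMS",
    "REFERENCE_PARAMS",
]

LIGHTWEIGHT_PARAMS = 1_020_337
REFERENCE_PARAMS = 16_315_585


@dataclass
class UNet3DConfig:
    """Architecture of the all-3D U-Net.

    ``level_widths`` are the per-level hidden feature-map counts of the
    lightweight model, scaled by ``width_multiplier`` (1 = lightweight,
    4 = reference, 0.25 = the reduced model used for CPU-scale runs).
    Kernels are 3x3x3, pooling is 2x2x2 max, upsampling is trilinear.
    """

    in_channels: int = 1
    out_channels: int = 1
    level_widths: tuple[int, ...] = (16, 32, 64, 128)
    convs_per_block: int = 2
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.in_channels != 1 or self.out_channels != 1:
            raise ValueError("single-channel stacks only")
        if self.convs_per_block != 2:
            raise ValueError("this topology uses two convolutions per block")
        widths = self.scaled_widths()
        if list(widths) != sorted(set(widths)):
            raise ValueError(
                f"scaled level widths must be strictly increasing; got {widths}"
            )

    def scaled_widths(self) -> tuple[int, ...]:
        widths = tuple(
            max(1, int(round(w * self.width_multiplier))) for w in self.level_widths
        )
        return widths

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "level_widths": list(self.level_widths),
            "convs_per_block": self.convs_per_block,
            "width_multiplier": self.width_multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UNet3DConfig":
        return cls(
            in_channels=d["in_channels"],
            out_channels=d["out_channels"],
            level_widths=tuple(d["level_widths"]),
            convs_per_block=d["convs_per_block"],
            width_multiplier=d["width_multiplier"],
        )


def build_unet(config: UNet3DConfig, seed: int = 0) -> UNet3D:
    """Instantiate the network; deterministic initial weights given the seed."""
    return UNet3D(level_widths=config.scaled_widths(), seed=seed)


def count_params(network: UNet3D) -> int:
    """Total trainable scalars (weights + biases) of a built network."""
    return network.n_params


def save_checkpoint(
    path: str | os.PathLike,
    network: UNet3D,
    config: UNet3DConfig,
    stack_mean: float = 0.0,
    extra: dict | None = None,
) -> str:
    """Persist weights with the config embedded so accounting is reproducible."""
    path = os.fspath(path)
    meta = {
        "config": config.to_dict(),
        "stack_mean": float(stack_mean),
        "seed": network.seed,
        "extra": extra or {},
    }
    arrays = network.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path: str | os.PathLike) -> tuple[UNet3D, UNet3DConfig, float]:
    """Load (network, config, stack_mean) from a checkpoint file."""
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path_npz = path + ".npz" if os.path.exists(path + ".npz") else path
    else:
        path_npz = path
    with np.load(path_npz) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = UNet3DConfig.from_dict(meta["config"])
        net = build_unet(config, seed=meta.get("seed", 0))
        net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return net, config, float(meta["stack_mean"])
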