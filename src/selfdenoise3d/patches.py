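"""Training-pair construction and overlapped 3D tiling.

Self-supervised pairs come from temporal deinterleaving: a block of 2*st
consecutive frames is split into the even-index substream (input) and the
odd-index substream (target).  Because adjacent frames carry nearly identical
signal but independent shot noise, the pair is a valid Noise2Noise target.
The 12-fold augmentation group is {keep, swap input/target} x {identity,
horizontal flip, vertical flip, left 90deg, 180deg, right 90deg} in the x-y
plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import VideoStack

logger = logging.getLogger(__name__)

__all__ = [
    "TilingPlan",
    "TrainingPair",
    "plan_tiles",
    "total_voxels",
    "deinterleave",
    "reinterleave",
    "extract_training_pairs",
    "augment",
    "enumerate_forms",
    "N_FORMS",
    "FORM_NAMES",
]

Window = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

# geometric transforms in the x-y plane; arrays are (x, y, t)
_GEOMS = {
    0: ("identity", lambda a: a),
    1: ("hflip", lambda a: a[::-1, :, :]),
    2: ("vflip", lambda a: a[:, ::-1, :]),
    3: ("rot90_left", lambda a: np.rot90(a, k=1, axes=(0, 1))),
    4: ("rot180", lambda a: np.rot90(a, k=2, axes=(0, 1))),
    5: ("rot90_right", lambda a: np.rot90(a, k=-1, axes=(0, 1))),
}
_SHAPE_PRESERVING = (0, 1, 2, 4)   # usable when sx != sy
N_FORMS = 12
FORM_NAMES = tuple(
    f"{'swap' if s else 'keep'}+{_GEOMS[g][0]}" for s in (0, 1) for g in range(6)
)


@dataclass
class TilingPlan:
    """Ordered overlapping windows covering a stack; order is t-major, then y, then x."""

    windows: list[Window]
    patch: tuple[int, int, int]
    overlap_frac: tuple[float, float, float]
    source_shape: tuple[int, int, int]


def _axis_starts(n: int, p: int, frac: float) -> list[int]:
    if p > n:
        raise ValueError(
            f"patch extent {p} exceeds stack extent {n}; pad the stack or "
            f"reduce the patch size"
        )
    stride = max(1, round(p * (1.0 - frac)))
    starts = list(range(0, max(n - p, 0) + 1, stride))
    if starts[-1] != n - p:
        starts.append(n - p)  # clamp final window flush to the boundary
    return sorted(set(starts))


def plan_tiles(
    shape: tuple[int, int, int],
    patch: tuple[int, int, int],
    overlap_frac: float | tuple[float, float, float],
) -> TilingPlan:
    """Plan overlapping 3D windows that cover a stack of the given shape.

    Per-axis starts are 0, stride, 2*stride, ... with stride =
    round(p * (1 - overlap_frac)); the final start is clamped to n - p so
    every window lies fully inside the source.
    """
    if isinstance(overlap_frac, (int, float)):
        overlap_frac = (float(overlap_frac),) * 3
    for f in overlap_frac:
        if not 0.0 <= f < 1.0:
            raise ValueError(f"overlap fraction must be in [0, 1); got {f}")
    starts = [
        _axis_starts(n, p, f) for n, p, f in zip(shape, patch, overlap_frac)
    ]
    windows: list[Window] = []
    for t0 in starts[2]:
        for y0 in starts[1]:
            for x0 in starts[0]:
                windows.append(
                    (
                        (x0, x0 + patch[0]),
                        (y0, y0 + patch[1]),
                        (t0, t0 + patch[2]),
                    )
                )
    return TilingPlan(
        windows=windows,
        patch=tuple(patch),
        overlap_frac=overlap_frac,
        source_shape=tuple(shape),
    )


def total_voxels(plan: TilingPlan) -> int:
    """Voxels flowing through the network: window count x patch volume."""
    px, py, pt = plan.patch
    return len(plan.windows) * px * py * pt


def deinterleave(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a 2*st-frame block into (even-index input, odd-index target)."""
    block = np.asarray(block)
    if block.ndim != 3:
        raise ValueError("block must be 3D (x, y, t)")
    nt = block.shape[2]
    if nt < 2 or nt % 2 != 0:
        raise ValueError(f"t extent must be even and >= 2; got {nt}")
    return block[:, :, 0::2], block[:, :, 1::2]


def reinterleave(inp: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Inverse of :func:`deinterleave`: weave the two substreams back together."""
    if inp.shape != target.shape:
        raise ValueError("input and target shapes differ")
    out = np.empty(
        (inp.shape[0], inp.shape[1], 2 * inp.shape[2]), dtype=inp.dtype
    )
    out[:, :, 0::2] = inp
    out[:, :, 1::2] = target
    return out


@dataclass
class TrainingPair:
    """An interleaved (input, target) patch pair sharing underlying signal."""

    input: np.ndarray
    target: np.ndarray
    origin: Window
    form_id: int = 0

    def __post_init__(self) -> None:
        if self.input.shape != self.target.shape:
            raise ValueError("input and target must have identical shapes")


def extract_training_pairs(
    stack: VideoStack,
    n_pairs: int,
    patch: tuple[int, int, int],
    seed: int,
) -> list[TrainingPair]:
    """Extract deinterleaved training pairs from a noisy stack.

    ``patch`` is the post-split shape (sx, sy, st); each pair consumes a
    contiguous block of 2*st source frames.  Temporal block starts are evenly
    spaced so the requested count fits the stack (overlapping when necessary);
    spatial origins are sampled uniformly with the seed.
    """
    sx, sy, st = patch
    nx, ny, nt = stack.shape
    block = 2 * st
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if nx < sx or ny < sy:
        raise ValueError(
            f"stack extents {(nx, ny)} smaller than spatial patch {(sx, sy)}"
        )
    if nt < block:
        raise ValueError(
            f"stack has {nt} frames but one pair needs {block}; "
            f"maximum feasible n_pairs is 0"
        )
    if n_pairs == 1:
        t_starts = np.array([0])
    else:
        t_starts = np.round(np.linspace(0, nt - block, n_pairs)).astype(int)
    rng = np.random.default_rng(seed)
    x_starts = rng.integers(0, nx - sx + 1, size=n_pairs)
    y_starts = rng.integers(0, ny - sy + 1, size=n_pairs)
    pairs = []
    for x0, y0, t0 in zip(x_starts, y_starts, t_starts):
        blk = stack.data[x0 : x0 + sx, y0 : y0 + sy, t0 : t0 + block]
        inp, tgt = deinterleave(blk)
        pairs.append(
            TrainingPair(
                input=inp,
                target=tgt,
                origin=((int(x0), int(x0 + sx)), (int(y0), int(y0 + sy)), (int(t0), int(t0 + block))),
            )
        )
    return pairs


def _apply_form(pair: TrainingPair, form_id: int) -> TrainingPair:
    swap, geom = divmod(form_id, 6)
    a, b = (pair.target, pair.input) if swap else (pair.input, pair.target)
    _, fn = _GEOMS[geom]
    return TrainingPair(
        input=np.ascontiguousarray(fn(a)),
        target=np.ascontiguousarray(fn(b)),
        origin=pair.origin,
        form_id=form_id,
    )


def augment(pair: TrainingPair, rng: np.random.Generator) -> TrainingPair:
    """Apply one of the 12 equiprobable augmentation forms.

    For non-square x-y extents a 90 deg rotation would change the shape, so the
    draw is restricted to the shape-preserving forms with a logged warning.
    """
    sx, sy, _ = pair.input.shape
    if sx == sy:
        form_id = int(rng.integers(0, N_FORMS))
    else:
        logger.warning(
            "non-square x-y patch %s: restricting augmentation to "
            "shape-preserving forms", (sx, sy)
        )
        swap = int(rng.integers(0, 2))
        geom = int(rng.choice(_SHAPE_PRESERVING))
        form_id = swap * 6 + geom
    return _apply_form(pair, form_id)


def enumerate_forms(pair: TrainingPair) -> list[TrainingPair]:
    """Deterministically produce every augmentation form of a pair.

    Square x-y patches yield all 12 forms; non-square patches yield the 8
    shape-preserving ones.
    """
    sx, sy, _ = pair.input.shape
    if sx == sy:
        ids = range(N_FORMS)
    else:
        logger.warning(
            "non-square x-y patch %s: enumerating shape-preserving forms only",
            (sx, sy),
        )
        ids = [s * 6 + g for s in (0, 1) for g in _SHAPE_PRESERVING]
    return [_apply_form(pair, i) for i in ids]
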