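"""Whole-stack denoising: overlapped tiling, per-patch forward passes,
margin-discard stitching, and mean restoration.

Stitching keeps only the central region of each patch: at every interior face
the cut sits at the midpoint of the overlap ("half of the overlap is
discarded"), with the earlier window keeping the extra voxel when the overlap
is odd.  Kept regions are disjoint and tile the output exactly, so an identity
model makes tile -> forward -> stitch the identity map.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .io_formats import VideoStack
from .patches import TilingPlan, Window, plan_tiles

logger = logging.getLogger(__name__)

__all__ = ["StitchPolicy", "Denoiser", "stitch", "denoise_stack", "keep_regions"]


class Denoiser(Protocol):
    """Anything mapping an (x, y, t) patch to a same-shape patch."""

    def predict(self, vol: np.ndarray) -> np.ndarray: ...


@dataclass
class StitchPolicy:
    """Disjoint-keep stitching: discard half the overlap on each interior face."""

    overlap_frac: tuple[float, float, float] = (0.4, 0.4, 0.4)


def _axis_keep(starts: list[int], p: int, n: int) -> list[tuple[int, int]]:
    """Per-window kept interval along one axis; cuts at overlap midpoints."""
    bounds = [0]
    for s_prev, s_next in zip(starts, starts[1:]):
        overlap = s_prev + p - s_next
        assert overlap >= 0, "windows must overlap or abut"
        bounds.append(s_next + (overlap + 1) // 2)  # earlier keeps the extra voxel
    bounds.append(n)
    return list(zip(bounds[:-1], bounds[1:]))


def keep_regions(plan: TilingPlan) -> dict[Window, Window]:
    """Map each window of a plan to its kept (exactly-once) output region."""
    axis_starts = [
        sorted({w[ax][0] for w in plan.windows}) for ax in range(3)
    ]
    keeps = [
        _axis_keep(axis_starts[ax], plan.patch[ax], plan.source_shape[ax])
        for ax in range(3)
    ]
    keep_of_start = [
        dict(zip(axis_starts[ax], keeps[ax])) for ax in range(3)
    ]
    return {
        w: (keep_of_start[0][w[0][0]], keep_of_start[1][w[1][0]], keep_of_start[2][w[2][0]])
        for w in plan.windows
    }


def stitch(
    patches: list[tuple[Window, np.ndarray]],
    plan: TilingPlan,
    policy: StitchPolicy | None = None,
) -> np.ndarray:
    """Assemble denoised patches into a full stack with disjoint-keep stitching.

    Every output voxel is written exactly once (asserted).
    """
    out = np.empty(plan.source_shape, dtype=patches[0][1].dtype if patches else np.float32)
    written = np.zeros(plan.source_shape, dtype=bool)
    keeps = keep_regions(plan)
    for window, patch in patches:
        (x0, x1), (y0, y1), (t0, t1) = window
        if patch.shape != (x1 - x0, y1 - y0, t1 - t0):
            raise ValueError(
                f"patch shape {patch.shape} does not match window {window}"
            )
        (kx0, kx1), (ky0, ky1), (kt0, kt1) = keeps[window]
        out[kx0:kx1, ky0:ky1, kt0:kt1] = patch[
            kx0 - x0 : kx1 - x0, ky0 - y0 : ky1 - y0, kt0 - t0 : kt1 - t0
        ]
        region = written[kx0:kx1, ky0:ky1, kt0:kt1]
        assert not region.any(), "double-write in stitching"
        region[:] = True
    assert written.all(), "coverage gap in stitching"
    return out


def denoise_stack(
    model: Denoiser,
    stack: VideoStack,
    stack_mean: float = 0.0,
    patch: tuple[int, int, int] = (150, 150, 150),
    overlap_frac: float = 0.4,
) -> VideoStack:
    """Denoise a whole stack: subtract the training mean, tile, forward each
    window, stitch, and add the mean back.

    A patch extent larger than the stack is clamped to the stack, so a stack
    smaller than the patch is processed as a single window (the model pads
    internally as needed).
    """
    eff_patch = tuple(min(p, s) for p, s in zip(patch, stack.shape))
    plan = plan_tiles(stack.shape, eff_patch, overlap_frac)
    # centering in float64 keeps subtract -> add exact for float32 inputs,
    # making the identity-model round trip bit-exact
    centered = stack.data.astype(np.float64) - float(stack_mean)
    t0 = time.perf_counter()
    outputs = []
    for window in plan.windows:
        (x0, x1), (y0, y1), (tt0, tt1) = window
        block = centered[x0:x1, y0:y1, tt0:tt1]
        outputs.append((window, np.asarray(model.predict(block), dtype=np.float64)))
    denoised = (stitch(outputs, plan) + float(stack_mean)).astype(np.float32)
    logger.info(
        "denoised %s via %d windows of %s in %.1f s",
        stack.shape, len(plan.windows), eff_patch, time.perf_counter() - t0,
    )
    return stack.with_data(denoised, name=stack.name + "-denoised")
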