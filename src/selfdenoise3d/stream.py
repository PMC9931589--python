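"""Offline emulation of the real-time acquisition -> processing -> display
schedule.

The real system runs three concurrent threads; here they are three sequential
stages with the same observable contract: frames are packaged into overlapping
(x-y-t) batches, each batch is denoised, and at every junction between
consecutive batches half of the overlapping frames from each side is discarded
(the earlier batch keeps the extra frame when the overlap is odd).  The
assembled denoised stream has exactly as many frames as the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .infer import Denoiser
from .io_formats import VideoStack

logger = logging.getLogger(__name__)

__all__ = ["StreamBatch", "package_batches", "process_stream"]


@dataclass
class StreamBatch:
    frames: np.ndarray        # (x, y, batch_len)
    t_start: int              # global index of the first (unpadded) frame
    overlap_frames: int       # frames shared with the previous batch
    n_padded: int = 0         # trailing frames repeated to fill the last batch


def package_batches(
    frames: np.ndarray | VideoStack,
    batch_len: int,
    overlap_frames: int,
) -> Iterator[StreamBatch]:
    """Package an ordered frame stream into overlapping temporal batches.

    stride = batch_len - overlap_frames; the final short batch is padded by
    repeating the last frame (and trimmed again after processing).
    """
    data = np.asarray(getattr(frames, "data", frames))
    if data.ndim != 3:
        raise ValueError("expected an (x, y, t) frame stream")
    if not batch_len > overlap_frames >= 0:
        raise ValueError("need batch_len > overlap_frames >= 0")
    nt = data.shape[2]
    if nt == 0:
        return
    stride = batch_len - overlap_frames
    start = 0
    first = True
    while first or start < nt and start + overlap_frames < nt:
        end = start + batch_len
        block = data[:, :, start:min(end, nt)]
        n_padded = end - nt if end > nt else 0
        if n_padded:
            pad = np.repeat(block[:, :, -1:], n_padded, axis=2)
            block = np.concatenate([block, pad], axis=2)
        yield StreamBatch(
            frames=block,
            t_start=start,
            overlap_frames=0 if first else overlap_frames,
            n_padded=n_padded,
        )
        if end >= nt:
            break
        start += stride
        first = False


def process_stream(
    model: Denoiser,
    batches: Sequence[StreamBatch] | Iterator[StreamBatch],
) -> np.ndarray:
    """Denoise a batched stream and reassemble the causal output stream.

    For each interior junction with overlap v, the earlier batch contributes
    its trailing ceil(v/2) overlap frames and the later batch discards its
    leading ceil(v/2) frames (odd v: the earlier batch keeps the extra frame).
    """
    processed: list[tuple[int, np.ndarray]] = []
    for batch in batches:
        den = np.asarray(model.predict(batch.frames), dtype=np.float32)
        if batch.n_padded:
            den = den[:, :, : den.shape[2] - batch.n_padded]
        processed.append((batch.t_start, den))
    if not processed:
        return np.empty((0, 0, 0), dtype=np.float32)

    pieces: list[np.ndarray] = []
    prev_cut = 0
    for i, (t_start, den) in enumerate(processed):
        end = t_start + den.shape[2]
        if i + 1 < len(processed):
            next_start = processed[i + 1][0]
            v = end - next_start
            cut = next_start + (v + 1) // 2  # earlier batch keeps the extra frame
        else:
            cut = end
        pieces.append(den[:, :, prev_cut - t_start : cut - t_start])
        prev_cut = cut
    out = np.concatenate(pieces, axis=2)
    total = processed[-1][0] + processed[-1][1].shape[2]
    assert out.shape[2] == total, "frame-count mismatch after reassembly"
    return out
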