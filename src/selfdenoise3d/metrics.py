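"""Evaluation metrics: SNR (dB), Pearson R, slice-wise correlations, IoU,
majority-vote consensus masks, peak dF/F0 maps, and a paired-test helper."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "snr_db",
    "pearson",
    "slicewise_corr",
    "iou",
    "consensus_mask",
    "peak_dff",
    "paired_onesided_t",
    "SlicewiseResult",
]


def _as_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(getattr(x, "data", x), dtype=np.float64)
    y = np.asarray(getattr(y, "data", y), dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def snr_db(x, y) -> float:
    """Signal-to-noise ratio 10*log10(||y||^2 / ||x - y||^2) in dB.

    ``x`` is the evaluated stack, ``y`` the reference.  Returns +inf when
    x == y exactly.
    """
    x, y = _as_arrays(x, y)
    signal = float(np.sum(y * y))
    if signal == 0.0:
        raise ValueError("reference is identically zero; SNR undefined")
    err = float(np.sum((x - y) ** 2))
    if err == 0.0:
        return np.inf
    return 10.0 * np.log10(signal / err)


def pearson(x, y) -> float:
    """Pearson correlation E[(x-mu_x)(y-mu_y)] / (sigma_x sigma_y)."""
    x, y = _as_arrays(x, y)
    xf, yf = x.ravel(), y.ravel()
    sx, sy = xf.std(), yf.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.mean((xf - xf.mean()) * (yf - yf.mean())) / (sx * sy))


@dataclass
class SlicewiseResult:
    """Per-slice correlations along one axis; constant slices are skipped."""

    r: np.ndarray          # correlation for valid slices
    valid: np.ndarray      # boolean mask over slice index
    axis: str

    @property
    def mean(self) -> float:
        return float(self.r.mean())


def slicewise_corr(x, y, axis: str) -> SlicewiseResult:
    """Correlate 2D slices of two (x, y, t) stacks along one axis.

    ``axis='t'`` correlates x-y frames (one R per frame), ``'x'`` correlates
    y-t slices and ``'y'`` correlates x-t slices.  Slices where either stack
    is constant are skipped and flagged in the validity mask.
    """
    x, y = _as_arrays(x, y)
    ax = {"x": 0, "y": 1, "t": 2}[axis]
    n = x.shape[ax]
    r = []
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        xs = np.take(x, i, axis=ax).ravel()
        ys = np.take(y, i, axis=ax).ravel()
        if xs.std() == 0.0 or ys.std() == 0.0:
            continue
        valid[i] = True
        r.append(float(np.corrcoef(xs, ys)[0, 1]))
    return SlicewiseResult(r=np.array(r), valid=valid, axis=axis)


def _check_binary(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype != bool and not np.isin(m, (0, 1)).all():
        raise ValueError(f"{name} must be binary (bool or 0/1)")
    return m.astype(bool)


def iou(a, b) -> float:
    """Intersection over union |A∩B| / |A∪B| of two binary masks.

    Two empty masks agree vacuously and score 1.
    """
    a = _check_binary(a, "A")
    b = _check_binary(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def consensus_mask(masks, threshold: int | None = None) -> np.ndarray:
    """Majority-vote consensus: pixel true iff >= threshold annotators marked it.

    Default threshold is a strict majority, floor(n/2) + 1.
    """
    masks = [_check_binary(m, f"mask {i}") for i, m in enumerate(masks)]
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    if threshold is None:
        threshold = len(masks) // 2 + 1
    votes = np.sum(np.stack(masks, axis=0), axis=0)
    return votes >= threshold


def peak_dff(stack) -> tuple[np.ndarray, np.ndarray]:
    """Peak dF/F0 per pixel: max over t of (F - F0)/F0 with F0 the temporal mean.

    Pixels with nonpositive baseline are masked out; returns (map, valid_mask).
    """
    data = np.asarray(getattr(stack, "data", stack), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("expected an (x, y, t) stack")
    f0 = data.mean(axis=2)
    valid = f0 > 0
    out = np.full(f0.shape, np.nan)
    peak = data.max(axis=2)
    out[valid] = (peak[valid] - f0[valid]) / f0[valid]
    return out, valid


def paired_onesided_t(after: np.ndarray, before: np.ndarray) -> tuple[float, float]:
    """One-sided paired t-test that `after` exceeds `before`.

    Returns (t statistic, p value).  No multiple-testing correction is applied.
    """
    res = stats.ttest_rel(np.asarray(after), np.asarray(before), alternative="greater")
    return float(res.statistic), float(res.pvalue)
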