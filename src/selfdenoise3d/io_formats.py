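"""TIFF input/output for time-lapse stacks and per-plane volumetric series.

The repository-wide axis convention is ``(x, y, t)``: within a TIFF page,
columns are x and rows are y; the page index is t, ascending.  Volumetric
sessions are stored as one multi-page TIFF per imaging plane, z order given
by lexicographic filename order.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VideoStack",
    "VolumeSeries",
    "read_stack",
    "write_stack",
    "read_volume_series",
]


@dataclass
class VideoStack:
    """A single-channel fluorescence time-lapse stack.

    Parameters
    ----------
    data
        3D intensity array indexed ``(x, y, t)``, arbitrary units.
    dtype_in
        dtype of the source file (or of the array it was built from).
    frame_interval
        Seconds per frame.
    pixel_size
        Micrometres per pixel, if known.
    name
        Provenance string (file path, generator description, ...).
    """

    data: np.ndarray
    dtype_in: np.dtype = field(default_factory=lambda: np.dtype(np.float32))
    frame_interval: float = 1.0 / 30.0
    pixel_size: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VideoStack data must have exactly 3 axes (x, y, t); got shape "
                f"{self.data.shape}"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all extents must be >= 1; got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VideoStack intensities must be finite (no NaN/Inf)")
        self.dtype_in = np.dtype(self.dtype_in)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, name: str | None = None) -> "VideoStack":
        """Copy of this stack's metadata around a new array."""
        return VideoStack(
            data=data,
            dtype_in=self.dtype_in,
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
            name=self.name if name is None else name,
        )


@dataclass
class VolumeSeries:
    """Ordered per-z-plane time-lapse stacks of one volumetric session."""

    planes: list[VideoStack]
    z_spacing: float | None = None

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("VolumeSeries needs at least one plane")
        shapes = {p.shape for p in self.planes}
        if len(shapes) > 1:
            raise ValueError(
                f"all planes must share identical (x, y, t) extents; got {shapes}"
            )

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    def as_array(self) -> np.ndarray:
        """Return the session as a 4D array indexed (x, y, z, t)."""
        return np.stack([p.data for p in self.planes], axis=2)


def read_stack(path: str | os.PathLike) -> VideoStack:
    """Read a single- or multi-page TIFF into a :class:`VideoStack`.

    Page order maps to t ascending; the result is (x, y, t).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such TIFF stack: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) == 0:
                raise ValueError(f"TIFF has zero pages: {path}")
            arr = tif.asarray()
    except tifffile.TiffFileError as exc:
        raise ValueError(f"not a readable TIFF payload: {path}") from exc
    if arr.ndim == 2:  # single page -> t extent 1
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(
            f"expected a single-channel (t, y, x) TIFF, got shape {arr.shape}: {path}"
        )
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite intensities in {path}")
    return VideoStack(data=data, dtype_in=arr.dtype, name=path)


def write_stack(
    stack: VideoStack,
    path: str | os.PathLike,
    dtype: np.dtype | str | None = None,
    clip: bool = False,
) -> str:
    """Write a stack as a multi-page TIFF, one page per frame.

    Integer output is quantised round-half-even.  Values outside the output
    dtype range raise unless ``clip`` is set.  BigTIFF is auto-selected for
    payloads over 4 GB.
    """
    path = os.fspath(path)
    out_dtype = np.dtype(dtype) if dtype is not None else np.dtype(np.float32)
    data = stack.data
    if np.issubdtype(out_dtype, np.integer):
        info = np.iinfo(out_dtype)
        quantised = np.rint(data)  # round-half-even
        if clip:
            quantised = np.clip(quantised, info.min, info.max)
        elif quantised.min() < info.min or quantised.max() > info.max:
            raise OverflowError(
                f"values in [{data.min():g}, {data.max():g}] overflow {out_dtype} "
                f"range [{info.min}, {info.max}]; pass clip=True to saturate"
            )
        out = quantised.astype(out_dtype)
    else:
        out = data.astype(out_dtype)
    pages = np.ascontiguousarray(out.transpose(2, 1, 0))
    bigtiff = pages.nbytes > 2**32 - 2**25
    tifffile.imwrite(path, pages, bigtiff=bigtiff, photometric="minisblack")
    return path


def read_volume_series(
    directory: str | os.PathLike, pattern: str = "*.tif*"
) -> VolumeSeries:
    """Read one TIFF per z-plane; lexicographic filename order defines z."""
    directory = os.fspath(directory)
    paths = sorted(_glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise FileNotFoundError(
            f"no files matching {pattern!r} under {directory}"
        )
    planes = [read_stack(p) for p in paths]
    shapes = [p.shape for p in planes]
    if len(set(shapes)) > 1:
        detail = ", ".join(f"{os.path.basename(f)}:{s}" for f, s in zip(paths, shapes))
        raise ValueError(f"plane shape mismatch across series: {detail}")
    return VolumeSeries(planes=planes)
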