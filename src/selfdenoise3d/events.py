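"""Quantification of fluorescence release events from annotated centers.

Each event is modelled as an ellipsoid: 1D intensity profiles are extracted
along x, y and z at the peak time, fitted with Gaussians to suppress
background fluctuation, deconvolved against the (Gaussian) system PSF with
the Richardson-Lucy algorithm to remove the anisotropic resolution limit,
and summarised as per-axis FWHM diameters plus per-plane ellipticities
(a - b)/a with a >= b the plane's two diameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import VolumeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SystemPSF",
    "ReleaseEvent",
    "GaussianFit",
    "FitError",
    "extract_profiles",
    "fit_gaussian",
    "rl_deconvolve",
    "fwhm",
    "event_geometry",
    "bin_events",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


class FitError(RuntimeError):
    """Raised when a profile cannot be fitted; the event is flagged upstream."""


@dataclass
class SystemPSF:
    """Gaussian model of the imaging PSF (FWHMs in micrometres)."""

    lateral_fwhm_um: float = 0.6
    axial_fwhm_um: float = 3.5

    def __post_init__(self) -> None:
        if not (self.axial_fwhm_um >= self.lateral_fwhm_um > 0):
            raise ValueError("need axial FWHM >= lateral FWHM > 0")

    def sigma_um(self, axis: str) -> float:
        f = self.axial_fwhm_um if axis == "z" else self.lateral_fwhm_um
        return f / FWHM_PER_SIGMA


@dataclass
class ReleaseEvent:
    center_um: tuple[float, float, float]
    peak_time_s: float
    diameters_um: dict[str, float]            # FWHM along x, y, z
    ellipticities: dict[str, float]           # planes xy, yz, xz
    flags: list[str] = field(default_factory=list)


@dataclass
class GaussianFit:
    amplitude: float
    center: float
    sigma: float
    baseline: float


def extract_profiles(
    volume: VolumeSeries | np.ndarray,
    center: tuple[int, int, int, int],
    half_width: int,
    half_width_z: int | None = None,
) -> dict[str, np.ndarray]:
    """1D intensity profiles along x, y and z through an event at its peak time.

    ``volume`` is a per-plane series or a 4D (x, y, z, t) array; ``center``
    is (x, y, z, t) in pixels/planes/frames.  Events whose window leaves the
    volume are excluded (raises ``ValueError``), matching the rule that
    edge events are skipped.
    """
    data = volume.as_array() if isinstance(volume, VolumeSeries) else np.asarray(volume)
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, t) volume")
    cx, cy, cz, ct = (int(c) for c in center)
    hz = half_width if half_width_z is None else half_width_z
    nx, ny, nz, nt = data.shape
    if not (
        half_width <= cx < nx - half_width
        and half_width <= cy < ny - half_width
        and hz <= cz < nz - hz
        and 0 <= ct < nt
    ):
        raise ValueError(
            f"event at {(cx, cy, cz, ct)} is within {half_width} px (z: {hz}) "
            f"of the volume edge; excluded"
        )
    return {
        "x": data[cx - half_width : cx + half_width + 1, cy, cz, ct].astype(float),
        "y": data[cx, cy - half_width : cy + half_width + 1, cz, ct].astype(float),
        "z": data[cx, cy, cz - hz : cz + hz + 1, ct].astype(float),
    }


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float, b: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + b


def fit_gaussian(profile: np.ndarray, coords: np.ndarray | None = None) -> GaussianFit:
    """Least-squares Gaussian fit A exp(-(x-mu)^2 / 2 sigma^2) + b."""
    profile = np.asarray(profile, dtype=float)
    if profile.size < 5:
        raise FitError("need at least 5 samples for a Gaussian fit")
    x = np.arange(profile.size, dtype=float) if coords is None else np.asarray(coords, dtype=float)
    rng_dyn = profile.max() - profile.min()
    if rng_dyn <= 0:
        raise FitError("profile has no dynamic range")
    p0 = (rng_dyn, float(x[np.argmax(profile)]), (x[-1] - x[0]) / 6.0, float(profile.min()))
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            profile,
            p0=p0,
            bounds=(
                (0.0, x[0], 1e-6, -np.inf),
                (np.inf, x[-1], (x[-1] - x[0]) * 2.0, np.inf),
            ),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    return GaussianFit(amplitude=float(popt[0]), center=float(popt[1]),
                       sigma=float(popt[2]), baseline=float(popt[3]))


def rl_deconvolve(curve: np.ndarray, psf: np.ndarray, iterations: int = 50) -> np.ndarray:
    """Standard multiplicative Richardson-Lucy deconvolution of a 1D curve.

    Circular boundary handling (FFT convolution), so total mass is conserved;
    the PSF must be nonnegative with unit sum.
    """
    curve = np.asarray(curve, dtype=float)
    psf = np.asarray(psf, dtype=float)
    if np.any(curve < 0) or np.any(psf < 0):
        raise ValueError("curve and PSF must be nonnegative")
    s = psf.sum()
    if s <= 0:
        raise ValueError("PSF must have positive mass")
    if abs(s - 1.0) > 1e-8:
        psf = psf / s
    n = curve.size
    k = np.zeros(n)
    m = psf.size
    if m > n:
        raise ValueError("PSF longer than the curve")
    # center the kernel at index 0 for circular convolution
    half = m // 2
    k[: m - half] = psf[half:]
    k[n - half :] = psf[:half]
    K = np.fft.rfft(k)
    Kc = np.conj(K)
    eps = 1e-12
    u = np.full(n, max(curve.mean(), eps))
    for _ in range(iterations):
        conv = np.fft.irfft(np.fft.rfft(u) * K, n)
        ratio = curve / np.maximum(conv, eps)
        u = u * np.fft.irfft(np.fft.rfft(ratio) * Kc, n)
        u = np.maximum(u, 0.0)
    return u


def fwhm(curve: np.ndarray, coords: np.ndarray | None = None,
         baseline: float | None = None) -> float:
    """Full width at half maximum with linear interpolation between samples.

    The half level is baseline + (peak - baseline)/2; default baseline is the
    curve minimum.  Raises ``FitError`` when no half-crossing exists on a side.
    """
    curve = np.asarray(curve, dtype=float)
    x = np.arange(curve.size, dtype=float) if coords is None else np.asarray(coords, dtype=float)
    b = float(curve.min()) if baseline is None else baseline
    peak_idx = int(np.argmax(curve))
    half = b + (curve[peak_idx] - b) / 2.0
    if curve[peak_idx] <= b:
        raise FitError("curve has no peak above baseline")

    def cross(indices: np.ndarray) -> float:
        for i in indices:
            if curve[i] <= half:
                # linear interpolation between i and the neighbour toward the peak
                j = i + 1 if i < peak_idx else i - 1
                frac = (half - curve[i]) / (curve[j] - curve[i])
                return x[i] + frac * (x[j] - x[i])
        raise FitError("no half-maximum crossing found")

    left = cross(np.arange(peak_idx, -1, -1))
    right = cross(np.arange(peak_idx, curve.size))
    return float(abs(right - left))


_PLANES = {"xy": ("x", "y"), "yz": ("y", "z"), "xz": ("x", "z")}


def event_geometry(
    profiles: dict[str, np.ndarray],
    psf: SystemPSF,
    pixel_size_um: float,
    z_spacing_um: float,
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    peak_time_s: float = 0.0,
    rl_iterations: int = 50,
    grid_step_px: float = 0.1,
) -> ReleaseEvent:
    """Diameters and ellipticities of one event from its three axis profiles.

    Per axis: Gaussian fit -> dense resampling of the fitted curve (baseline
    removed) -> Richardson-Lucy deconvolution against the PSF -> FWHM,
    converted to micrometres.  Any failed axis flags the event.
    """
    diameters: dict[str, float] = {}
    flags: list[str] = []
    for axis in ("x", "y", "z"):
        step_um = z_spacing_um if axis == "z" else pixel_size_um
        try:
            fit = fit_gaussian(profiles[axis])
            sigma_px = fit.sigma
            psf_sigma_px = psf.sigma_um(axis) / step_um
            # dense symmetric grid holding both the observed curve and the PSF
            support = max(6.0 * sigma_px, 6.0 * psf_sigma_px, 4.0)
            grid = np.arange(-support, support + grid_step_px, grid_step_px)
            observed = np.exp(-0.5 * (grid / sigma_px) ** 2)
            kernel = np.exp(-0.5 * (grid / psf_sigma_px) ** 2)
            kernel /= kernel.sum()
            deconv = rl_deconvolve(observed, kernel, iterations=rl_iterations)
            diameters[axis] = fwhm(deconv, coords=grid, baseline=0.0) * step_um
        except FitError as exc:
            flags.append(f"{axis}: {exc}")
            diameters[axis] = math.nan
    ellipticities: dict[str, float] = {}
    for plane, (a1, a2) in _PLANES.items():
        d1, d2 = diameters[a1], diameters[a2]
        if math.isnan(d1) or math.isnan(d2):
            ellipticities[plane] = math.nan
        else:
            a, b = max(d1, d2), min(d1, d2)
            ellipticities[plane] = (a - b) / a
    if flags:
        logger.warning("event at %s flagged: %s", center_um, "; ".join(flags))
    return ReleaseEvent(
        center_um=center_um,
        peak_time_s=peak_time_s,
        diameters_um=diameters,
        ellipticities=ellipticities,
        flags=flags,
    )


def bin_events(
    peak_times_s: np.ndarray,
    bin_width_s: float,
    session_length_s: float,
) -> np.ndarray:
    """Histogram event peak times into half-open bins [k*w, (k+1)*w).

    An event exactly on a boundary goes to the later bin; counts sum to the
    number of events.
    """
    times = np.asarray(peak_times_s, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= session_length_s):
        raise ValueError("event times must lie within [0, session_length)")
    n_bins = int(math.ceil(session_length_s / bin_width_s))
    idx = np.floor(times / bin_width_s).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return counts
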