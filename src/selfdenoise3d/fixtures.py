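"""Deterministic synthetic fixtures binding the pipeline together for testing.

Everything is generated at run time from (parameters, seed) — nothing is
shipped as binary data — and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .events import FWHM_PER_SIGMA, SystemPSF
from .io_formats import VideoStack
from .metrics import snr_db
from .simulate import (
    NoiseModel,
    SceneParams,
    add_noise,
    calibrate_photons,
    make_scene,
    render_clean,
)

__all__ = [
    "make_denoising_fixture",
    "make_event_fixture",
    "EventTruth",
]


def make_denoising_fixture(
    target_snr_db: float,
    size: tuple[int, int, int] = (128, 128, 600),
    seed: int = 7,
    scene_overrides: dict | None = None,
) -> tuple[VideoStack, VideoStack, NoiseModel, dict]:
    """Paired (clean, noisy) calcium movies at a calibrated SNR level.

    Returns (clean, noisy, noise_model, manifest); the manifest records the
    realised SNR, which is within ±0.25 dB of the request.  The clean movie
    depends only on (size, seed, scene parameters), not on the SNR level.
    """
    nx, ny, nt = size
    if nx > 128 or ny > 128 or nt > 600:
        raise ValueError("fixture size capped at 128 x 128 x 600")
    overrides = dict(scene_overrides or {})
    # keep the default cell density when the field of view shrinks
    overrides.setdefault("n_cells", max(1, round(30 * nx * ny / (128 * 128))))
    params = SceneParams(fov=(nx, ny), n_frames=nt, **overrides)
    scene = make_scene(params, seed=seed)
    clean = render_clean(scene)
    model = calibrate_photons(clean, target_snr_db, seed=seed + 1)
    noisy = add_noise(clean, model, seed=seed + 1)
    realised = snr_db(noisy.data, clean.data)
    if abs(realised - target_snr_db) > 0.25:
        raise ValueError(
            f"calibration failed: realised {realised:.2f} dB for target "
            f"{target_snr_db:.2f} dB"
        )
    manifest = {
        "target_snr_db": float(target_snr_db),
        "realised_snr_db": float(realised),
        "photon_scale": model.photon_scale,
        "gauss_sigma": model.gauss_sigma,
        "size": list(size),
        "seed": seed,
    }
    return clean, noisy, model, manifest


@dataclass
class EventTruth:
    center: tuple[int, int, int, int]       # (x, y, z, t) in pixels/frames
    fwhm_px: tuple[float, float, float]     # true FWHMs before PSF blur
    amplitude: float


def make_event_fixture(
    events: list[EventTruth],
    psf: SystemPSF,
    shape: tuple[int, int, int, int] = (48, 48, 24, 8),
    pixel_size_um: float = 1.0,
    z_spacing_um: float = 1.0,
    noise_sigma: float = 0.0,
    baseline: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """4D (x, y, z, t) volume of ellipsoidal events blurred by the system PSF.

    Forward model: Gaussian ellipsoid (per-axis sigma = FWHM / 2.3548) ->
    anisotropic Gaussian PSF blur -> optional additive Gaussian noise on a
    constant baseline.  Each event also has a temporal Gaussian envelope
    peaking at its annotated frame.
    """
    nx, ny, nz, nt = shape
    rng = np.random.default_rng(seed)
    vol = np.full(shape, baseline, dtype=float)
    psf_sig = (
        psf.sigma_um("x") / pixel_size_um,
        psf.sigma_um("y") / pixel_size_um,
        psf.sigma_um("z") / z_spacing_um,
    )
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    for ev in events:
        cx, cy, cz, ct = ev.center
        sig = tuple(f / FWHM_PER_SIGMA for f in ev.fwhm_px)
        blob = ev.amplitude * np.exp(
            -0.5 * (
                ((x - cx) / sig[0]) ** 2
                + ((y - cy) / sig[1]) ** 2
                + ((z - cz) / sig[2]) ** 2
            )
        )
        blurred = gaussian_filter(blob, sigma=psf_sig, mode="constant")
        envelope = np.exp(-0.5 * ((np.arange(nt) - ct) / 1.5) ** 2)
        vol += blurred[:, :, :, None] * envelope[None, None, None, :]
    if noise_sigma > 0:
        vol += rng.normal(0.0, noise_sigma, size=shape)
        vol = np.clip(vol, 0.0, None)
    return vol
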