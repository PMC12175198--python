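"""Phantom and scene generators for end-to-end testing without real data.

The phantoms emulate the joint absorption/phase structure of an H&E-stained
tissue section as seen by a coherent microscope: smooth stroma with
correlated absorption and optical-path-delay fluctuations, punctuated by
nucleus-like disks that are both darker and optically denser.  Resolution
targets (two-point, Siemens star, bar groups) and a two-plane scene with an
out-of-focus opaque marker complete the suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import (CaptureStack, ComplexObject, NoiseSpec, OpticalConfig,
                     apply_noise, led_wavevectors, make_pupil, shift_pixels,
                     _angular_spectrum)

__all__ = [
    "PhantomSpec",
    "TwoPlaneScene",
    "make_phantom",
    "two_point_positions",
    "marker_occluder",
    "simulate_two_plane_stack",
]

PHANTOM_KINDS = ("tissue", "two_point", "star", "bars", "uniform")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic complex object.

    ``feature_scale`` (μm) sets the blob/stroke size for the tissue kind
    and the point separation for the two-point kind.  ``mu_range`` and
    ``phi_range`` bound absorption and phase; the defaults keep
    |o| ∈ [0.22, 1] so the phase stays far from wrapping.

    ``band_limit`` (1/μm) applies a raised-cosine spectral taper to the
    tissue kind's absorption and phase fields so their content lies inside
    the widest synthetic aperture of the default 13×13 / 52 mm / NA 0.3
    geometry (≈ 1.62 1/μm at 523 nm) while still exercising the dark-field
    captures; resolution-target kinds are left sharp.
    """

    kind: str = "tissue"
    size: int = 128
    pixel_size: float = 0.1625
    mu_range: tuple[float, float] = (0.0, 1.5)
    phi_range: tuple[float, float] = (0.0, 1.5)
    feature_scale: float = 2.0
    band_limit: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.mu_range[0] < 0:
            raise ValueError("absorption must be nonnegative")
        if self.kind != "uniform" and self.feature_scale < self.pixel_size:
            raise ValueError("feature_scale below the grid pixel size")


@dataclass
class TwoPlaneScene:
    """Tissue at z = 0 plus an occluding marker plane at z = separation (μm).

    ``occluder_mask`` records where the marker absorbs significantly
    (area fraction in ``mask_fraction``).
    """

    tissue: ComplexObject
    occluder: ComplexObject
    separation: float
    occluder_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.separation == 0:
            raise ValueError("plane separation must be nonzero")
        if self.tissue.phase.shape != self.occluder.phase.shape:
            raise ValueError("tissue and occluder grids must match")

    @property
    def mask_fraction(self) -> float:
        return float(self.occluder_mask.mean())


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

def _smooth_noise(rng, size, sigma_px):
    f = gaussian_filter(rng.standard_normal((size, size)), sigma_px, mode="wrap")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros_like(f)


def _bandlimit(field: np.ndarray, pixel_size: float, k_hi: float,
               rolloff: float = 0.25) -> np.ndarray:
    """Raised-cosine spectral low-pass: unity below (1−rolloff)·k_hi,
    zero above k_hi."""
    n = field.shape[0]
    f = np.fft.fftfreq(n, d=pixel_size)
    kx, ky = np.meshgrid(f, f, indexing="xy")
    kr = np.hypot(kx, ky)
    k_lo = (1 - rolloff) * k_hi
    taper = np.clip((k_hi - kr) / (k_hi - k_lo), 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(np.pi * taper)
    return np.real(np.fft.ifft2(np.fft.fft2(field) * taper))


def two_point_positions(size: int, sep_px: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pixel coordinates (row, col) of the two points, centered on the grid."""
    c = size // 2
    x0 = c - sep_px // 2
    return (c, x0), (c, x0 + sep_px)


def make_phantom(spec: PhantomSpec) -> ComplexObject:
    """Deterministic synthetic complex object of the requested kind."""
    rng = np.random.default_rng(spec.seed)
    n, dx = spec.size, spec.pixel_size
    mu_lo, mu_hi = spec.mu_range
    phi_lo, phi_hi = spec.phi_range
    scale_px = spec.feature_scale / dx
    # final band-limiting smooth: keeps phantom content inside the widest
    # synthetic aperture the default geometry can measure
    blim_px = max(0.35 / dx, 1.0)

    if spec.kind == "uniform":
        zeros = np.zeros((n, n))
        return ComplexObject(phase=zeros.copy(), absorption=zeros.copy(),
                             pixel_size=dx)

    if spec.kind == "tissue":
        stroma = _smooth_noise(rng, n, scale_px)
        fine = _smooth_noise(rng, n, max(scale_px / 6, 1.0))
        # nucleus-like disks: dark and optically dense, correlated in mu/phi
        nuclei = np.zeros((n, n))
        yy, xx = np.mgrid[0:n, 0:n]
        n_nuclei = max(3, int((n * dx / (4 * spec.feature_scale)) ** 2))
        for _ in range(n_nuclei):
            cy, cx = rng.integers(0, n, 2)
            r = scale_px * rng.uniform(0.5, 1.0)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            nuclei = np.maximum(nuclei, (d2 < (r / 1.4) ** 2).astype(float))
        mu_field = 0.35 * stroma + 0.45 * nuclei + 0.20 * fine
        phi_field = 0.30 * stroma + 0.40 * nuclei + 0.30 * fine
        mu = mu_lo + (mu_hi - mu_lo) * _bandlimit(mu_field, dx, spec.band_limit)
        phi = phi_lo + (phi_hi - phi_lo) * _bandlimit(phi_field, dx, spec.band_limit)
        return ComplexObject(phase=phi, absorption=np.clip(mu, 0, None),
                             pixel_size=dx)

    if spec.kind == "two_point":
        sep_px = int(round(spec.feature_scale / dx))
        mu = np.full((n, n), max(mu_hi, 1e-3))
        (r0, c0), (r1, c1) = two_point_positions(n, sep_px)
        mu[r0, c0] = 0.0
        mu[r1, c1] = 0.0
        return ComplexObject(phase=np.zeros((n, n)), absorption=mu,
                             pixel_size=dx)

    if spec.kind == "star":
        yy, xx = np.mgrid[0:n, 0:n] - n // 2
        theta = np.arctan2(yy, xx)
        rr = np.hypot(yy, xx) * dx
        n_spokes = max(4, int(np.pi * n * dx / (2 * spec.feature_scale)) // 2 * 2)
        spokes = (np.cos(n_spokes * theta) > 0) & (rr > 2 * dx) & (rr < n * dx / 2.2)
        mu = mu_hi * gaussian_filter(spokes.astype(float), blim_px / 2)
        phi = (phi_hi - phi_lo) * 0.5 * gaussian_filter(spokes.astype(float), blim_px / 2)
        return ComplexObject(phase=phi, absorption=mu, pixel_size=dx)

    # bars: vertical bar groups with period = feature_scale
    xx = np.arange(n) * dx
    period = spec.feature_scale
    bars = (np.mod(xx, period) < period / 2).astype(float)
    mu = mu_hi * gaussian_filter(np.tile(bars, (n, 1)), blim_px / 2, mode="wrap")
    return ComplexObject(phase=np.zeros((n, n)), absorption=mu, pixel_size=dx)


def marker_occluder(size: int, pixel_size: float, *, stroke_mu: float = 3.0,
                    n_strokes: int = 2, stroke_width: float | None = None,
                    seed: int = 0) -> tuple[ComplexObject, np.ndarray]:
    """Opaque marker-pen strokes (μ = stroke_mu ≈ 95% absorption, φ ≈ 0).

    Returns the occluder object and the boolean occluded-region mask.
    """
    rng = np.random.default_rng(seed)
    n = size
    width_px = (stroke_width / pixel_size) if stroke_width else n / 7
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    mask = np.zeros((n, n), dtype=bool)
    for s in range(n_strokes):
        ang = rng.uniform(0, np.pi)
        offset = rng.uniform(-n / 4, n / 4)
        d = (xx - n / 2) * np.cos(ang) + (yy - n / 2) * np.sin(ang) - offset
        mask |= np.abs(d) < width_px / 2
    mu = stroke_mu * gaussian_filter(mask.astype(float), 1.0)
    occ = ComplexObject(phase=np.zeros((n, n)), absorption=mu,
                        pixel_size=pixel_size)
    return occ, mu > stroke_mu / 2


# --------------------------------------------------------------------------
# two-plane capture simulation
# --------------------------------------------------------------------------

def simulate_two_plane_stack(scene: TwoPlaneScene, config: OpticalConfig,
                             focal_z: float = 0.0,
                             gammas: np.ndarray | float = 1.0,
                             noise: NoiseSpec | None = None,
                             seed: int = 0) -> CaptureStack:
    """Capture stack of tissue at z = 0 occluded by a marker plane.

    For every LED the tilted field leaving the tissue is propagated by the
    plane separation with the angular-spectrum kernel on the HR grid,
    multiplied by the occluder transmission, and imaged through the pupil
    with the residual defocus ``focal_z − separation`` (the system focuses
    at ``focal_z``, tissue plane = 0).  With a transparent occluder this
    reduces exactly to the single-plane simulator at z = focal_z.
    """
    if scene.tissue.phase.shape != scene.occluder.phase.shape:
        raise ValueError("tissue and occluder grids must match")
    cfg = config
    illum = led_wavevectors(cfg)
    n_led = len(illum)
    g = np.broadcast_to(np.asarray(gammas, dtype=float), (n_led,)).copy()
    if np.any(g < 0):
        raise ValueError("gamma factors must be nonnegative")

    n, big, u = cfg.lr_side, cfg.hr_side, cfg.hr_upsample
    if scene.tissue.phase.shape[0] != big:
        raise ValueError("scene grid does not match config HR grid")
    tissue_spec = np.fft.fftshift(np.fft.fft2(scene.tissue.values, norm="ortho"))
    occ_field = scene.occluder.values
    kx_hr, ky_hr = cfg.hr_freq_grid()
    h_sep = _angular_spectrum(kx_hr, ky_hr, cfg.wavelength, scene.separation)
    pupil = make_pupil(cfg, [0.0])
    kx, ky = cfg.lr_freq_grid()
    h_img = _angular_spectrum(kx, ky, cfg.wavelength, focal_z - scene.separation)
    shifts = shift_pixels(cfg, illum.wavevectors)
    c = big // 2
    lo = c - n // 2
    frames = np.empty((n_led, n, n))
    for m in range(n_led):
        sx, sy = shifts[m]
        shifted = np.roll(tissue_spec, (-int(sy), -int(sx)), axis=(0, 1))
        field_at_occ = np.fft.ifft2(np.fft.ifftshift(shifted * h_sep),
                                    norm="ortho")
        exit_spec = np.fft.fftshift(np.fft.fft2(field_at_occ * occ_field,
                                                norm="ortho"))
        window = exit_spec[lo:lo + n, lo:lo + n]
        lr_field = np.fft.ifft2(np.fft.ifftshift(window * pupil.values * h_img),
                                norm="ortho") / u
        frames[m] = g[m] * np.abs(lr_field) ** 2
    noise = noise or NoiseSpec()
    frames = apply_noise(frames, noise, np.random.default_rng(seed))
    meta = {"focal_z": float(focal_z), "separation": float(scene.separation),
            "seed": int(seed), "two_plane": True}
    return CaptureStack(images=frames, gammas=g, config=cfg,
                        illumination=illum, meta=meta)
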