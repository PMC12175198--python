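"""Physical forward model of Fourier ptychographic image formation.

An FPM acquisition illuminates a thin sample with a sequence of tilted
plane waves from an LED array.  Each tilt shifts the object spectrum by
``k_m = (sin θx / λ, sin θy / λ)``; the objective passes the NA-limited
pupil window, an angular-spectrum kernel ``H(k, z)`` models defocus, and
the camera records the low-resolution intensity

    I_i = γ_i · | F⁻¹[ o(k − k_m) · P(k) · H(k, z) ] |²

with a per-capture brightness factor ``γ_i``.  This module implements the
sample representation, the illumination geometry, the pupil, the defocus
kernel and the capture equation, plus a stack simulator driving the model
over every LED.

Conventions
-----------
* All spectra are stored DC-centered (``fftshift`` layout) and use
  orthonormal FFTs, so spatial and spectral energies agree (Parseval).
* The low- and high-resolution grids share the same frequency step
  ``dk = 1/(n · Δx_LR)``; an LED's spectral shift is realized as a
  nearest-pixel translation of the n×n crop window inside the HR
  spectrum.
* Lengths are in μm except LED pitch and height, which are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .zernike import zernike_basis

__all__ = [
    "OpticalConfig",
    "ComplexObject",
    "ObjectSpectrum",
    "IlluminationSet",
    "Pupil",
    "DefocusKernel",
    "NoiseSpec",
    "CaptureStack",
    "reference_config",
    "led_wavevectors",
    "make_pupil",
    "defocus_kernel",
    "forward_capture",
    "simulate_stack",
]


# --------------------------------------------------------------------------
# configuration and domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of one FPM acquisition channel.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in μm.
    objective_na : float
        Numerical aperture of the objective, in (0, 1).
    magnification : float
        Objective magnification (> 0).
    camera_pixel : float
        Camera pixel pitch at the sensor plane, μm.
    led_grid : (int, int)
        LED array dimensions (rows, cols); odd×odd so a central LED exists.
    led_pitch : float
        LED spacing, mm.
    led_height : float
        Sample-to-array distance, mm.
    hr_upsample : int
        Ratio of high-resolution to low-resolution grid sampling (≥ 2).
    lr_shape : (int, int)
        Pixels per low-resolution capture (square, even).
    """

    wavelength: float
    objective_na: float
    magnification: float
    camera_pixel: float
    led_grid: tuple[int, int] = (13, 13)
    led_pitch: float = 4.0
    led_height: float = 52.0
    hr_upsample: int = 4
    lr_shape: tuple[int, int] = (32, 32)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.objective_na < 1:
            raise ValueError("objective_na must be in (0, 1)")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.camera_pixel <= 0:
            raise ValueError("camera_pixel must be positive")
        if self.led_height <= 0:
            raise ValueError("led_height must be positive")
        if self.hr_upsample < 2:
            raise ValueError("hr_upsample must be >= 2")
        ny, nx = self.lr_shape
        if ny != nx or ny % 2:
            raise ValueError("lr_shape must be square with an even side")

    # -- derived sampling ---------------------------------------------------
    @property
    def lr_pixel(self) -> float:
        """Object-plane sampling of a capture, μm (camera pixel / magnification)."""
        return self.camera_pixel / self.magnification

    @property
    def hr_pixel(self) -> float:
        return self.lr_pixel / self.hr_upsample

    @property
    def lr_side(self) -> int:
        return self.lr_shape[0]

    @property
    def hr_side(self) -> int:
        return self.lr_side * self.hr_upsample

    @property
    def dk(self) -> float:
        """Frequency step shared by the LR and HR grids, 1/μm."""
        return 1.0 / (self.lr_side * self.lr_pixel)

    @property
    def cutoff(self) -> float:
        """Coherent pupil cutoff NA/λ, 1/μm."""
        return self.objective_na / self.wavelength

    def n_leds(self) -> int:
        return self.led_grid[0] * self.led_grid[1]

    def lr_freq_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """DC-centered spatial-frequency coordinates (kx, ky) of the LR grid."""
        f = np.fft.fftshift(np.fft.fftfreq(self.lr_side, d=self.lr_pixel))
        return np.meshgrid(f, f, indexing="xy")

    def hr_freq_grid(self) -> tuple[np.ndarray, np.ndarray]:
        f = np.fft.fftshift(np.fft.fftfreq(self.hr_side, d=self.hr_pixel))
        return np.meshgrid(f, f, indexing="xy")


def reference_config(wavelength: float = 0.523, lr_shape: tuple[int, int] = (32, 32),
                 hr_upsample: int = 4) -> OpticalConfig:
    """The 10×/0.3-NA, 6.5 μm-pixel, 13×13-LED, 52 mm geometry.

    LED pitch defaults to 4 mm, a common commercial array spacing that
    yields ~65% pupil overlap between neighbouring LEDs at this height.
    """
    return OpticalConfig(
        wavelength=wavelength,
        objective_na=0.3,
        magnification=10.0,
        camera_pixel=6.5,
        led_grid=(13, 13),
        led_pitch=4.0,
        led_height=52.0,
        hr_upsample=hr_upsample,
        lr_shape=lr_shape,
    )


@dataclass
class ComplexObject:
    """Thin-sample complex transmission o(r) = exp(iφ(r) − μ(r)).

    ``phase`` (radians) and ``absorption`` (μ ≥ 0) live on the square
    high-resolution grid with spacing ``pixel_size`` (μm).
    """

    phase: np.ndarray
    absorption: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.absorption.shape:
            raise ValueError("phase and absorption grids must match")
        s = self.phase.shape
        if len(s) != 2 or s[0] != s[1] or s[0] % 2:
            raise ValueError("object grid must be square with an even side")

    @property
    def values(self) -> np.ndarray:
        """The complex field exp(iφ − μ)."""
        return np.exp(1j * self.phase - self.absorption)

    def spectrum(self) -> "ObjectSpectrum":
        n = self.phase.shape[0]
        vals = np.fft.fftshift(np.fft.fft2(self.values, norm="ortho"))
        return ObjectSpectrum(values=vals, k_sampling=1.0 / (n * self.pixel_size))


@dataclass
class ObjectSpectrum:
    """DC-centered orthonormal 2-D spectrum of a complex object."""

    values: np.ndarray
    k_sampling: float

    def to_field(self) -> np.ndarray:
        return np.fft.ifft2(np.fft.ifftshift(self.values), norm="ortho")


@dataclass
class IlluminationSet:
    """Per-LED spectral shifts in a deterministic center-outward spiral order.

    ``wavevectors[m] = (kx, ky)`` in 1/μm; ``led_indices[m]`` is the LED's
    (row, col) on the array grid; index ``central_index`` (always 0) is the
    on-axis LED with exactly zero shift.
    """

    wavevectors: np.ndarray      # (N, 2)
    led_indices: np.ndarray      # (N, 2) int
    central_index: int = 0

    def __len__(self) -> int:
        return len(self.wavevectors)


@dataclass
class Pupil:
    """Complex coherent transfer function on the LR frequency grid.

    ``values = support · exp(i Σ c_j Z_j)`` with Noll-indexed Zernike modes
    evaluated on the disk normalized to the NA/λ cutoff.
    """

    support: np.ndarray
    zernike_coeffs: np.ndarray
    values: np.ndarray


@dataclass
class DefocusKernel:
    """Angular-spectrum defocus factor H(k, z) on the LR frequency grid.

    ``H = exp(i·(2π/λ)·z·sqrt(1 − (λkx)² − (λky)²))`` on propagating
    frequencies; evanescent frequencies decay as
    ``exp(−(2π/λ)|z|·sqrt((λk)² − 1))`` so that H(k, 0) ≡ 1 and
    H(k, −z) = conj(H(k, z)) hold on the whole grid.
    """

    z: float
    values: np.ndarray


@dataclass(frozen=True)
class NoiseSpec:
    """Optional capture noise: Poisson shot noise at a photon budget per
    pixel at unit intensity, plus additive Gaussian read noise (counts)."""

    photons: float | None = None
    read_sigma: float = 0.0

    @property
    def enabled(self) -> bool:
        return self.photons is not None or self.read_sigma > 0


@dataclass
class CaptureStack:
    """The N low-resolution intensity frames with their acquisition context."""

    images: np.ndarray           # (N, n, n) nonnegative
    gammas: np.ndarray           # (N,) positive
    config: OpticalConfig
    illumination: IlluminationSet
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.gammas):
            raise ValueError("images and gammas must have equal length")
        if np.any(self.images < 0):
            raise ValueError("capture intensities must be nonnegative")

    @property
    def central_frame(self) -> np.ndarray:
        return self.images[self.illumination.central_index]


# --------------------------------------------------------------------------
# illumination geometry
# --------------------------------------------------------------------------

def led_wavevectors(config: OpticalConfig, *, central_led: tuple[int, int] | None = None
                    ) -> IlluminationSet:
    """Spectral shifts k_m for every LED, spiral-ordered from the center.

    For an LED at lateral offset (dx, dy) from the optical axis at height h,
    ``sin θx = dx / sqrt(dx² + dy² + h²)`` and ``k_m = (sin θx / λ,
    sin θy / λ)``.  LEDs are ordered by square ring (Chebyshev distance from
    the center) and, within a ring, by azimuth counterclockwise from the +x
    axis, so index 0 is always the on-axis LED.
    """
    rows, cols = config.led_grid
    if central_led is None:
        if rows % 2 == 0 or cols % 2 == 0:
            raise ValueError(
                f"LED grid {rows}x{cols} has no central LED; pass central_led "
                "explicitly to resolve the ambiguity")
        central_led = (rows // 2, cols // 2)
    cr, cc = central_led

    entries = []
    for r in range(rows):
        for c in range(cols):
            i, j = r - cr, c - cc          # grid offsets (row, col)
            ring = max(abs(i), abs(j))
            ang = np.arctan2(i, j) % (2 * np.pi)
            entries.append((ring, ang, j, i, r, c))
    entries.sort()

    h = config.led_height
    kvecs = np.empty((len(entries), 2))
    idx = np.empty((len(entries), 2), dtype=int)
    for m, (_, _, j, i, r, c) in enumerate(entries):
        dx, dy = j * config.led_pitch, i * config.led_pitch   # mm
        norm = np.sqrt(dx * dx + dy * dy + h * h)
        kvecs[m] = (dx / norm / config.wavelength, dy / norm / config.wavelength)
        idx[m] = (r, c)
    kvecs[0] = (0.0, 0.0)   # exact by construction; enforce against rounding
    return IlluminationSet(wavevectors=kvecs, led_indices=idx, central_index=0)


# --------------------------------------------------------------------------
# pupil and defocus
# --------------------------------------------------------------------------

def make_pupil(config: OpticalConfig, zernike_coeffs: np.ndarray | list[float]
               ) -> Pupil:
    """NA-limited pupil with a Zernike-parameterized phase.

    Raises if the NA/λ cutoff exceeds the LR grid's Nyquist frequency
    (the capture would be undersampled).
    """
    coeffs = np.atleast_1d(np.asarray(zernike_coeffs, dtype=float))
    kx, ky = config.lr_freq_grid()
    nyquist = 1.0 / (2.0 * config.lr_pixel)
    if config.cutoff > nyquist:
        raise ValueError(
            f"pupil cutoff {config.cutoff:.4g}/um exceeds the LR Nyquist "
            f"frequency {nyquist:.4g}/um: capture undersampled")
    kr = np.hypot(kx, ky)
    support = kr <= config.cutoff
    rho = kr / config.cutoff
    theta = np.arctan2(ky, kx)
    basis = zernike_basis(len(coeffs), rho, theta)
    phase = np.tensordot(coeffs, basis, axes=1)
    values = np.where(support, np.exp(1j * phase), 0.0)
    return Pupil(support=support, zernike_coeffs=coeffs, values=values)


def _angular_spectrum(kx: np.ndarray, ky: np.ndarray, wavelength: float,
                      z: float) -> np.ndarray:
    radicand = 1.0 - (wavelength * kx) ** 2 - (wavelength * ky) ** 2
    prop = radicand >= 0
    h = np.empty(radicand.shape, dtype=complex)
    h[prop] = np.exp(1j * 2 * np.pi / wavelength * z * np.sqrt(radicand[prop]))
    h[~prop] = np.exp(-2 * np.pi / wavelength * abs(z) * np.sqrt(-radicand[~prop]))
    return h


def defocus_kernel(config: OpticalConfig, z: float) -> DefocusKernel:
    """Defocus kernel H(k, z) on the LR frequency grid (z in μm, signed)."""
    kx, ky = config.lr_freq_grid()
    return DefocusKernel(z=float(z),
                         values=_angular_spectrum(kx, ky, config.wavelength, z))


# --------------------------------------------------------------------------
# capture equation
# --------------------------------------------------------------------------

def shift_pixels(config: OpticalConfig, k_m: np.ndarray) -> np.ndarray:
    """Nearest-pixel spectral shift of a wavevector (or array of them)."""
    return np.rint(np.asarray(k_m) / config.dk).astype(int)


def _crop_window(spectrum: np.ndarray, n: int, shift: np.ndarray,
                 led_label: str = "") -> np.ndarray:
    big = spectrum.shape[0]
    c = big // 2
    sx, sy = int(shift[0]), int(shift[1])
    r0, c0 = c + sy - n // 2, c + sx - n // 2
    if r0 < 0 or c0 < 0 or r0 + n > big or c0 + n > big:
        raise ValueError(
            f"spectral window for LED {led_label or 'shift ' + str((sx, sy))} "
            f"extends beyond the HR spectrum bounds ({big}x{big})")
    return spectrum[r0:r0 + n, c0:c0 + n]


def forward_capture(spectrum: ObjectSpectrum, k_m: np.ndarray, pupil: Pupil,
                    kernel: DefocusKernel | None, gamma: float = 1.0,
                    config: OpticalConfig | None = None) -> np.ndarray:
    """One LR intensity frame: γ·|F⁻¹[o(k−k_m)·P·H]|².

    The n×n window of the HR spectrum centered (to the nearest pixel) at
    ``k_m`` is multiplied by pupil and defocus kernel and inverse
    transformed; intensity is scaled so that a unit-transmission object
    under on-axis illumination yields a frame of value γ.
    """
    n = pupil.values.shape[0]
    big = spectrum.values.shape[0]
    u = big // n
    if config is not None:
        dk = config.dk
    else:
        dk = spectrum.k_sampling
    shift = np.rint(np.asarray(k_m, dtype=float) / dk).astype(int)
    window = _crop_window(spectrum.values, n, shift)
    filt = pupil.values if kernel is None else pupil.values * kernel.values
    field = np.fft.ifft2(np.fft.ifftshift(window * filt), norm="ortho") / u
    return float(gamma) * np.abs(field) ** 2


def apply_noise(images: np.ndarray, noise: NoiseSpec,
                rng: np.random.Generator) -> np.ndarray:
    if not noise.enabled:
        return images
    out = images.astype(float)
    if noise.photons is not None:
        out = rng.poisson(np.clip(out, 0, None) * noise.photons) / noise.photons
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def simulate_stack(obj: ComplexObject, config: OpticalConfig, z: float = 0.0,
                   gammas: np.ndarray | float = 1.0,
                   noise: NoiseSpec | None = None, seed: int = 0) -> CaptureStack:
    """Drive the capture equation over every LED of the array.

    Deterministic given ``seed``; with ``noise=None`` each frame equals
    :func:`forward_capture` exactly.
    """
    illum = led_wavevectors(config)
    n_led = len(illum)
    g = np.broadcast_to(np.asarray(gammas, dtype=float), (n_led,)).copy()
    if np.any(g < 0):
        raise ValueError("gamma factors must be nonnegative")
    spectrum = obj.spectrum()
    pupil = make_pupil(config, [0.0])
    kernel = defocus_kernel(config, z)
    n = config.lr_side
    frames = np.empty((n_led, n, n))
    for m in range(n_led):
        try:
            frames[m] = forward_capture(spectrum, illum.wavevectors[m], pupil,
                                        kernel, g[m], config=config)
        except ValueError as exc:
            raise ValueError(f"LED index {m}: {exc}") from exc
    noise = noise or NoiseSpec()
    frames = apply_noise(frames, noise, np.random.default_rng(seed))
    meta = {"z": float(z), "seed": int(seed),
            "noise": {"photons": noise.photons, "read_sigma": noise.read_sigma}}
    return CaptureStack(images=frames, gammas=g, config=config,
                        illumination=illum, meta=meta)
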