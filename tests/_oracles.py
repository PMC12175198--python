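"""Independent brute-force oracles: direct double-sum discrete transforms.

These deliberately avoid numpy's FFT (and the package's shift/crop
bookkeeping) so they can certify the FFT-based forward model.  Quadratic
cost — keep grids at 16×16 or smaller.
"""

import numpy as np


def dft2_centered(field: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DFT with the zero frequency at index n//2."""
    n = field.shape[0]
    k = np.arange(n) - n // 2
    x = np.arange(n)
    w = np.exp(-2j * np.pi * np.outer(k, x) / n) / np.sqrt(n)
    return w @ field @ w.T


def idft2_centered(spec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dft2_centered` by direct summation."""
    n = spec.shape[0]
    k = np.arange(n) - n // 2
    x = np.arange(n)
    w = np.exp(2j * np.pi * np.outer(x, k) / n) / np.sqrt(n)
    return w @ spec @ w.T


def forward_capture_oracle(obj_field: np.ndarray, k_m, pupil_values,
                           kernel_values, gamma: float, lr_side: int,
                           lr_pixel: float) -> np.ndarray:
    """Capture equation evaluated with direct sums only.

    Crops the LR window of the object's centered spectrum at the
    nearest-pixel shift of ``k_m``, applies pupil and defocus factors, and
    inverse transforms by direct summation.
    """
    big = obj_field.shape[0]
    u = big // lr_side
    dk = 1.0 / (lr_side * lr_pixel)
    spec = dft2_centered(obj_field)
    sx, sy = (int(round(k_m[0] / dk)), int(round(k_m[1] / dk)))
    c = big // 2
    r0, c0 = c + sy - lr_side // 2, c + sx - lr_side // 2
    window = spec[r0:r0 + lr_side, c0:c0 + lr_side]
    field = idft2_centered(window * pupil_values * kernel_values) / u
    return gamma * np.abs(field) ** 2


def two_plane_capture_oracle(tissue_field, occ_field, k_m, pupil_values,
                             h_sep_hr, h_img_lr, gamma, lr_side, lr_pixel):
    """Two-plane capture: tilt, propagate, occlude, image — direct sums."""
    big = tissue_field.shape[0]
    u = big // lr_side
    dk = 1.0 / (lr_side * lr_pixel)
    sx, sy = (int(round(k_m[0] / dk)), int(round(k_m[1] / dk)))
    spec = dft2_centered(tissue_field)
    shifted = np.roll(spec, (-sy, -sx), axis=(0, 1))
    field_at_occ = idft2_centered(shifted * h_sep_hr)
    exit_spec = dft2_centered(field_at_occ * occ_field)
    c = big // 2
    lo = c - lr_side // 2
    window = exit_spec[lo:lo + lr_side, lo:lo + lr_side]
    field = idft2_centered(window * pupil_values * h_img_lr) / u
    return gamma * np.abs(field) ** 2
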