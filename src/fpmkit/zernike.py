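"""Noll-indexed Zernike polynomials on the unit disk.

Used to parameterize the pupil aberration phase.  Indexing follows Noll
(j = 1 is piston, j = 2/3 tip/tilt, j = 4 defocus, ...), with the usual
Noll normalization so that each mode has unit RMS over the disk (piston
``Z_1`` is identically 1).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["noll_to_nm", "zernike", "zernike_basis"]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll index ``j`` (1-based) to radial/azimuthal orders (n, m)."""
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate Noll mode ``Z_j`` at polar coordinates; zero outside the disk."""
    n, m = noll_to_nm(j)
    r = _radial(n, m, rho)
    if m == 0:
        z = math.sqrt(n + 1) * r
    elif m > 0:
        z = math.sqrt(2 * (n + 1)) * r * np.cos(m * theta)
    else:
        z = math.sqrt(2 * (n + 1)) * r * np.sin(-m * theta)
    return np.where(rho <= 1.0, z, 0.0)


def zernike_basis(j_max: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Stack of modes ``Z_1 .. Z_{j_max}``, shape ``(j_max, *rho.shape)``."""
    return np.stack([zernike(j, rho, theta) for j in range(1, j_max + 1)])
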