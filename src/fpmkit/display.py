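"""RGB assembly from per-wavelength reconstructions and phase display scaling.

Each wavelength channel is reconstructed independently; the three HR
intensity maps are then stacked along the channel dimension as
(R, G, B) ← (623, 523, 470) nm and normalized per channel by a robust
percentile so the result lands in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RgbImage", "assemble_rgb", "phase_to_display"]

RGB_WAVELENGTHS = (0.623, 0.523, 0.470)   # μm, channel order R, G, B


@dataclass
class RgbImage:
    channels: np.ndarray          # (h, w, 3) in [0, 1], order R, G, B
    normalization: dict           # per-channel divisor actually applied
    wavelengths: tuple = RGB_WAVELENGTHS


def assemble_rgb(recon_r: np.ndarray, recon_g: np.ndarray, recon_b: np.ndarray,
                 wavelengths: tuple[float, float, float] | None = None,
                 percentile: float = 99.0) -> RgbImage:
    """Stack three intensity maps into an RGB image.

    If ``wavelengths`` is given (μm, parallel to the inputs, e.g. capture
    order 523/470/623), the maps are reordered to R = 623, G = 523,
    B = 470 nm first.  Each channel is divided by its ``percentile``-th
    intensity percentile and clipped to [0, 1]; the divisors are recorded
    for reversibility.
    """
    maps = [np.asarray(m, dtype=float) for m in (recon_r, recon_g, recon_b)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValueError("the three channel maps must share a shape")
    if wavelengths is not None:
        order = np.argsort(wavelengths)[::-1]   # descending → R, G, B
        maps = [maps[i] for i in order]
    scales = {}
    out = np.empty(maps[0].shape + (3,))
    for i, (name, m) in enumerate(zip("RGB", maps)):
        s = float(np.percentile(m, percentile))
        s = s if s > 0 else 1.0
        scales[name] = s
        out[..., i] = np.clip(m / s, 0.0, 1.0)
    return RgbImage(channels=out, normalization=scales)


def phase_to_display(phase: np.ndarray) -> tuple[np.ndarray, dict]:
    """Linearly rescale a radian phase map to [0, 1] for rendering.

    No unwrapping is performed; the recorded (min, max) metadata makes the
    scaling reversible.  A constant map displays as zeros.
    """
    phase = np.asarray(phase, dtype=float)
    vmin, vmax = float(phase.min()), float(phase.max())
    meta = {"min": vmin, "max": vmax, "units": "radians"}
    if vmax == vmin:
        return np.zeros_like(phase), meta
    return (phase - vmin) / (vmax - vmin), meta
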