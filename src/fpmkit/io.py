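"""On-disk formats: multi-page TIFF capture stacks with YAML sidecars,
float TIFF maps, PNG renders and YAML run reports.

A stack lives as ``<stem>.tif`` (one LR frame per page, float32 or uint16)
plus ``<stem>.yaml`` holding every optics field, the LED ordering name,
the simulated defocus, the γ vector, seed and noise spec.  Lengths are μm
except LED pitch and height (mm), stated in the sidecar's ``units`` field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .optics import (CaptureStack, ComplexObject, NoiseSpec, OpticalConfig,
                     led_wavevectors)

__all__ = [
    "write_stack", "read_stack",
    "write_object", "read_object",
    "write_map", "read_map",
    "write_report", "write_png",
    "config_to_dict", "config_from_dict",
]

UNITS_NOTE = "lengths in um except led_pitch and led_height in mm"
LED_ORDERING = "spiral"


def config_to_dict(config: OpticalConfig) -> dict:
    return {
        "wavelength": config.wavelength,
        "objective_na": config.objective_na,
        "magnification": config.magnification,
        "camera_pixel": config.camera_pixel,
        "led_grid": list(config.led_grid),
        "led_pitch": config.led_pitch,
        "led_height": config.led_height,
        "hr_upsample": config.hr_upsample,
        "lr_shape": list(config.lr_shape),
    }


def config_from_dict(d: dict) -> OpticalConfig:
    known = {"wavelength", "objective_na", "magnification", "camera_pixel",
             "led_grid", "led_pitch", "led_height", "hr_upsample", "lr_shape"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown optics key: {sorted(unknown)[0]!r}")
    d = dict(d)
    d["led_grid"] = tuple(d.get("led_grid", (13, 13)))
    d["lr_shape"] = tuple(d.get("lr_shape", (32, 32)))
    return OpticalConfig(**d)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: CaptureStack, path: str | Path,
                dtype: str = "float32") -> Path:
    """Write a capture stack as multi-page TIFF + YAML sidecar."""
    path = Path(path).with_suffix(".tif")
    if dtype == "float32":
        data = stack.images.astype(np.float32)
        scale = 1.0
    elif dtype == "uint16":
        peak = float(stack.images.max()) or 1.0
        scale = peak / 65535.0
        data = np.round(stack.images / scale).astype(np.uint16)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    tifffile.imwrite(path, data)
    meta = dict(stack.meta)
    noise = meta.pop("noise", {"photons": None, "read_sigma": 0.0})
    side = {
        "units": UNITS_NOTE,
        "led_ordering": LED_ORDERING,
        "optics": config_to_dict(stack.config),
        "z": float(meta.pop("z", 0.0)),
        "gammas": [float(g) for g in stack.gammas],
        "seed": int(meta.pop("seed", 0)),
        "noise": noise,
        "intensity_scale": scale,
        "extra": meta,
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(side, fh, sort_keys=False)
    return path


def read_stack(path: str | Path) -> CaptureStack:
    """Read a stack written by :func:`write_stack`; validates page count."""
    path = Path(path).with_suffix(".tif")
    side_path = _sidecar(path)
    if not side_path.exists():
        raise FileNotFoundError(f"missing sidecar config {side_path}")
    with open(side_path) as fh:
        side = yaml.safe_load(fh)
    if side.get("led_ordering", LED_ORDERING) != LED_ORDERING:
        raise ValueError(f"unsupported LED ordering "
                         f"{side.get('led_ordering')!r} in {side_path}")
    config = config_from_dict(side["optics"])
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    n_led = config.n_leds()
    if len(data) != n_led:
        raise ValueError(f"{path}: expected {n_led} pages for the "
                         f"{config.led_grid[0]}x{config.led_grid[1]} LED "
                         f"grid, found {len(data)}")
    scale = float(side.get("intensity_scale", 1.0))
    images = data.astype(np.float64)
    if data.dtype != np.float32 and data.dtype != np.float64:
        images = images * scale
    noise = side.get("noise") or {}
    meta = {"z": float(side.get("z", 0.0)),
            "seed": int(side.get("seed", 0)),
            "noise": {"photons": noise.get("photons"),
                      "read_sigma": noise.get("read_sigma", 0.0)},
            "intensity_scale": scale}
    meta.update(side.get("extra") or {})
    return CaptureStack(images=images,
                        gammas=np.asarray(side["gammas"], dtype=float),
                        config=config,
                        illumination=led_wavevectors(config),
                        meta=meta)


# --------------------------------------------------------------------------
# maps and objects
# --------------------------------------------------------------------------

def write_map(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_object(obj: ComplexObject, stem: str | Path) -> tuple[Path, Path]:
    """Phase/absorption float-TIFF pair plus a small YAML descriptor."""
    stem = Path(stem)
    p_phase = write_map(obj.phase, stem.parent / (stem.name + "_phase.tif"))
    p_mu = write_map(obj.absorption, stem.parent / (stem.name + "_absorption.tif"))
    with open(stem.parent / (stem.name + ".yaml"), "w") as fh:
        yaml.safe_dump({"pixel_size_um": obj.pixel_size,
                        "fields": ["phase", "absorption"]}, fh)
    return p_phase, p_mu


def read_object(stem: str | Path) -> ComplexObject:
    stem = Path(stem)
    with open(stem.parent / (stem.name + ".yaml")) as fh:
        d = yaml.safe_load(fh)
    return ComplexObject(
        phase=read_map(stem.parent / (stem.name + "_phase.tif")),
        absorption=read_map(stem.parent / (stem.name + "_absorption.tif")),
        pixel_size=float(d["pixel_size_um"]))


def write_png(image: np.ndarray, path: str | Path) -> Path:
    import imageio.v3 as iio
    path = Path(path).with_suffix(".png")
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))
    return path


def write_report(path: str | Path, payload: dict) -> Path:
    """YAML run report; numpy scalars/arrays are converted to plain types."""
    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return [clean(x) for x in v.tolist()]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v
    path = Path(path).with_suffix(".yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(clean(payload), fh, sort_keys=False)
    return path
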