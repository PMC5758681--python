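"""File containers for images and sinograms, plus display windowing.

The native container is a ``.npy`` array with a JSON metadata sidecar
(``<stem>.json``) carrying shape, pixel spacing, and the unit tag, so files
are self-describing and the round trip is lossless.  A 16-bit PNG export
(HU + 1024 offset, clipped to [0, 65535]) is provided for visualization in
ordinary viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .image import AttenuationImage
from .projector import ScanGeometry, Sinogram

#: Display defaults for contrast-enhanced vascular CT: window level 300 HU,
#: window width 1000 HU.
DEFAULT_WINDOW_LEVEL_HU = 300.0
DEFAULT_WINDOW_WIDTH_HU = 1000.0

PNG16_HU_OFFSET = 1024.0


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(img: AttenuationImage, path: str | Path) -> Path:
    """Write an image to ``<path>.npy`` + JSON sidecar; returns the array path."""
    path = Path(path).with_suffix(".npy")
    np.save(path, img.values)
    meta = {
        "kind": "image",
        "shape": list(img.shape),
        "pixel_spacing_mm": img.pixel_spacing_mm,
        "unit": img.unit,
        "mu_water": img.mu_water,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> AttenuationImage:
    path = Path(path).with_suffix(".npy")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    if "unit" not in meta:
        raise ValueError(f"{sidecar} has no unit tag")
    if "pixel_spacing_mm" not in meta:
        raise ValueError(f"{sidecar} has no pixel spacing")
    values = np.load(path)
    return AttenuationImage(
        values=values,
        pixel_spacing_mm=float(meta["pixel_spacing_mm"]),
        unit=meta["unit"],
        mu_water=float(meta.get("mu_water", 0.192)),
    )


def write_sinogram(sino: Sinogram, path: str | Path) -> Path:
    path = Path(path).with_suffix(".npy")
    np.save(path, sino.values)
    geom = sino.geometry
    meta = {
        "kind": "sinogram",
        "shape": list(sino.shape),
        "n_views": geom.n_views,
        "image_size_px": geom.image_size_px,
        "detector_spacing_mm": geom.detector_spacing_mm,
        "parallel_beam": geom.parallel_beam,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path).with_suffix(".npy")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    geom = ScanGeometry(
        n_views=int(meta["n_views"]),
        image_size_px=int(meta["image_size_px"]),
        detector_spacing_mm=float(meta["detector_spacing_mm"]),
    )
    return Sinogram(values=np.load(path), geometry=geom)


def render_window(
    img: AttenuationImage,
    level_hu: float = DEFAULT_WINDOW_LEVEL_HU,
    width_hu: float = DEFAULT_WINDOW_WIDTH_HU,
) -> np.ndarray:
    """Map [level - width/2, level + width/2] affinely onto 0..255, clipped.

    Rounding is round-half-to-even (np.rint), so a pixel exactly at the
    window level maps to 128.
    """
    if width_hu <= 0:
        raise ValueError("window width must be positive")
    hu = img.to_hu().values
    lo = level_hu - width_hu / 2.0
    scaled = (hu - lo) / width_hu * 255.0
    return np.rint(np.clip(scaled, 0.0, 255.0)).astype(np.uint8)


def export_png16(img: AttenuationImage, path: str | Path) -> Path:
    """16-bit PNG export: stored value = clip(HU + 1024, 0, 65535)."""
    path = Path(path).with_suffix(".png")
    hu = img.to_hu().values
    stored = np.clip(hu + PNG16_HU_OFFSET, 0, 65535).astype(np.uint16)
    PILImage.fromarray(stored).save(path)
    return path
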