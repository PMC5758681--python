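"""Objective image-quality metrics: circular ROI statistics, noise, CNR.

Noise is the standard deviation of HU inside a circular region of interest;
contrast-to-noise ratio is

    CNR = (mean HU vessel - mean HU muscle) / SD(HU) in air

a dimensionless index.  ROIs are defined by center and physical area and are
copied unchanged between paired reconstructions so the comparison is
pixel-for-pixel fair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import AttenuationImage
from .semar import MetalMask

ROI_LABELS = ("vessel", "muscle", "air")

#: Default circular ROI areas: 10 mm^2 for celiac/SMA-sized vessels,
#: 6 mm^2 for renal-sized ones.
DEFAULT_ROI_AREA_MM2 = {"large_vessel": 10.0, "small_vessel": 6.0}


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI: center in pixels (row, col), area in mm^2."""

    center_px: tuple[float, float]
    area_mm2: float
    label: str = "vessel"

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("ROI area must be positive")
        if self.label not in ROI_LABELS:
            raise ValueError(f"ROI label must be one of {ROI_LABELS}")

    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))


@dataclass(frozen=True)
class ROIStats:
    """Mean, population SD, and pixel count over an ROI."""

    mean_hu: float
    sd_hu: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 5:
            raise ValueError("ROI must contain at least 5 pixels")
        if self.sd_hu < 0:
            raise ValueError("SD must be nonnegative")


@dataclass(frozen=True)
class CNRInputs:
    vessel: ROIStats
    muscle: ROIStats
    air: ROIStats


def roi_mask(img: AttenuationImage, roi: ROISpec) -> np.ndarray:
    """Boolean pixel-membership mask: pixel centers inside the circle."""
    radius_px = roi.radius_mm() / img.pixel_spacing_mm
    r0, c0 = roi.center_px
    if (
        r0 - radius_px < -0.5
        or c0 - radius_px < -0.5
        or r0 + radius_px > img.shape[0] - 0.5
        or c0 + radius_px > img.shape[1] - 0.5
    ):
        raise ValueError("ROI circle extends outside the image")
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2


def roi_stats(
    img: AttenuationImage, roi: ROISpec, exclusion_mask: MetalMask | None = None
) -> ROIStats:
    """Mean and population SD of HU over the ROI.

    If an exclusion mask is given (e.g. segmented stent metal), the ROI must
    not overlap it — implants and calcifications must never contaminate a
    noise measurement.
    """
    if img.unit != "HU":
        raise ValueError("roi_stats expects an HU image")
    mask = roi_mask(img, roi)
    n = int(mask.sum())
    if n < 5:
        raise ValueError(f"ROI contains only {n} pixels (< 5)")
    if exclusion_mask is not None and np.any(mask & exclusion_mask.values):
        raise ValueError("ROI overlaps the exclusion (metal) mask")
    pixels = img.values[mask]
    return ROIStats(
        mean_hu=float(pixels.mean()),
        sd_hu=float(pixels.std(ddof=0)),
        n_pixels=n,
    )


def copy_roi(roi: ROISpec, from_img: AttenuationImage, to_img: AttenuationImage) -> ROISpec:
    """Validate that an ROI transfers unchanged to a paired image.

    The returned spec is identical; the call only asserts the two images
    share shape and pixel spacing, so 'exactly the same location' is
    well defined.
    """
    if from_img.shape != to_img.shape:
        raise ValueError("paired images differ in shape")
    if from_img.pixel_spacing_mm != to_img.pixel_spacing_mm:
        raise ValueError("paired images differ in pixel spacing")
    return roi


def cnr(inputs: CNRInputs) -> float:
    """(vessel mean - muscle mean) / air SD, dimensionless."""
    if inputs.air.sd_hu <= 0:
        raise ValueError("air SD must be positive to define CNR")
    return (inputs.vessel.mean_hu - inputs.muscle.mean_hu) / inputs.air.sd_hu
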