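"""Three-pass single-energy metal artifact reduction (SEMAR).

The pipeline operates on raw data (the sinogram) in three reconstruction
passes:

1. **First pass** — standard FBP of the corrupted sinogram; metal is
   segmented in this image by an HU threshold.
2. **Second pass** — the metal's sinogram trace (found by forward projecting
   the binary metal mask) is removed by per-view 1-D linear interpolation
   from neighboring non-metal detector bins, and the in-painted sinogram is
   reconstructed.
3. **Third pass** — the second-pass image is classified into air / water /
   bone to form a prior image; the original sinogram is blended with the
   prior's forward projection inside the trace (normalized in-painting), and
   the blended sinogram is reconstructed.  Finally the metal pixels from the
   first-pass image are reinserted so the implant itself is not erased.

Outside the metal trace the blended sinogram is bit-identical to the
original: measured data are never altered where no metal shadows them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image import AttenuationImage, hu_to_mu
from .projector import ScanGeometry, Sinogram, fbp, radon_forward

logger = logging.getLogger(__name__)

AIR_HU = -1000.0
WATER_HU = 0.0


@dataclass(frozen=True)
class MetalMask:
    """Binary metal segmentation in the image domain."""

    values: np.ndarray
    threshold_hu: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def empty(self) -> bool:
        return not bool(self.values.any())


@dataclass(frozen=True)
class TraceMask:
    """Binary metal trace in the sinogram domain (views x bins)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("trace must be 2-D")

    @property
    def empty(self) -> bool:
        return not bool(self.values.any())


@dataclass(frozen=True)
class SemarParams:
    """Free parameters of the three-pass pipeline.

    The vendor publishes none of these; the defaults are declared choices.
    ``blend_weight`` interpolates between plain linear in-painting (0) and
    prior-normalized in-painting (1).
    """

    metal_threshold_hu: float = 2500.0
    air_threshold_hu: float = -400.0
    bone_threshold_hu: float = 400.0
    blend_weight: float = 1.0
    filter_name: str = "shepp-logan"
    # Trace threshold on the projected binary mask, in cm of metal path.
    # 0.02 cm = 20% of one 1-mm strut: rays that merely clip a strut corner
    # stay out of the trace, so small-vessel lumens are not fully shadowed.
    trace_epsilon: float = 0.02
    prior_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.air_threshold_hu < self.bone_threshold_hu < self.metal_threshold_hu):
            raise ValueError("thresholds must satisfy air < bone < metal")
        if not (0.0 <= self.blend_weight <= 1.0):
            raise ValueError("blend weight must lie in [0, 1]")


@dataclass(frozen=True)
class SemarResult:
    """All pipeline intermediates, for inspection and testing."""

    first_pass: AttenuationImage  # HU
    second_pass: AttenuationImage | None
    final: AttenuationImage  # HU
    metal_mask: MetalMask
    trace_mask: TraceMask | None
    interpolated_sinogram: Sinogram | None
    blended_sinogram: Sinogram | None


def segment_metal(img: AttenuationImage, threshold_hu: float = 2500.0) -> MetalMask:
    """Threshold an HU image; metal = pixels at or above the threshold."""
    if img.unit != "HU":
        raise ValueError("segment_metal expects an HU image")
    return MetalMask(values=img.values >= threshold_hu, threshold_hu=threshold_hu)


def project_metal_trace(
    mask: MetalMask, geom: ScanGeometry, pixel_spacing_mm: float | None = None,
    epsilon: float = 0.02,
) -> TraceMask:
    """Sinogram bins whose rays intersect the metal mask.

    The binary mask is forward projected; a bin is in the trace iff its
    projection exceeds ``epsilon``.
    """
    spacing = pixel_spacing_mm if pixel_spacing_mm is not None else geom.detector_spacing_mm
    if mask.empty:
        return TraceMask(values=np.zeros((geom.n_views, geom.n_detector_bins), dtype=bool))
    indicator = AttenuationImage(
        values=mask.values.astype(float), pixel_spacing_mm=spacing, unit="mu"
    )
    proj = radon_forward(indicator, geom).values
    return TraceMask(values=proj > epsilon)


def _interpolate_rows(values: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Per-row linear in-painting of trace bins; non-trace bins untouched.

    Interior runs are bridged linearly between the nearest non-trace bin on
    each side; runs touching a detector edge take the single available
    neighbor's value (np.interp's clamped extrapolation).
    """
    out = values.copy()
    cols = np.arange(values.shape[1])
    for i in range(values.shape[0]):
        t = trace[i]
        if not t.any():
            continue
        good = ~t
        if not good.any():
            raise ValueError(
                f"view {i} is entirely inside the metal trace; "
                "metal spans the full field of view"
            )
        good_idx = cols[good]
        t_idx = cols[t]
        row = values[i]
        # bracketing non-trace bins; fill = y0 + (x - x0) * (y1 - y0) / (x1 - x0)
        pos = np.searchsorted(good_idx, t_idx)
        left = good_idx[np.clip(pos - 1, 0, good_idx.size - 1)]
        right = good_idx[np.clip(pos, 0, good_idx.size - 1)]
        y0, y1 = row[left], row[right]
        with np.errstate(invalid="ignore", divide="ignore"):
            filled = y0 + (t_idx - left) * (y1 - y0) / (right - left)
        filled = np.where(pos == 0, row[good_idx[0]], filled)
        filled = np.where(pos == good_idx.size, row[good_idx[-1]], filled)
        out[i, t] = filled
    return out


def interpolate_trace(sino: Sinogram, trace: TraceMask) -> Sinogram:
    """Remove the metal trace by per-view linear interpolation."""
    if trace.values.shape != sino.shape:
        raise ValueError("trace shape does not match sinogram")
    return Sinogram(
        values=_interpolate_rows(sino.values, trace.values), geometry=sino.geometry
    )


def classify_tissues(second_pass: AttenuationImage, params: SemarParams) -> AttenuationImage:
    """Classify the second-pass image into air / water / bone (prior image).

    Pixels below the air threshold become exactly air (-1000 HU); pixels
    above the bone threshold retain their HU (flattening bone would project
    it incorrectly); everything in between becomes water (0 HU).
    """
    if second_pass.unit != "HU":
        raise ValueError("classify_tissues expects an HU image")
    hu = second_pass.values
    prior = np.where(
        hu < params.air_threshold_hu,
        AIR_HU,
        np.where(hu > params.bone_threshold_hu, hu, WATER_HU),
    )
    return AttenuationImage(
        values=prior, pixel_spacing_mm=second_pass.pixel_spacing_mm, unit="HU"
    )


def blend_with_prior(
    original: Sinogram,
    prior_img: AttenuationImage,
    trace: TraceMask,
    geom: ScanGeometry,
    params: SemarParams,
) -> Sinogram:
    """Blend normalized and plain in-painting inside the metal trace.

    Outside the trace the original sinogram is returned unchanged.  Inside,
    the value is ``beta * p_norm + (1 - beta) * p_lin`` where ``p_lin`` is
    plain linear in-painting and ``p_norm`` divides the original by the
    prior image's forward projection, in-paints the ratio linearly, and
    multiplies the prior projection back — so anatomy encoded in the prior
    shapes the fill instead of being flattened.
    """
    if trace.values.shape != original.shape:
        raise ValueError("trace shape does not match sinogram")
    beta = params.blend_weight
    p_lin = _interpolate_rows(original.values, trace.values)
    if beta == 0.0:
        return Sinogram(values=p_lin, geometry=original.geometry)

    prior_proj = radon_forward(prior_img.to_mu(), geom).values
    prior_proj = np.maximum(prior_proj, params.prior_floor)
    if np.any(prior_proj[trace.values] <= 0):
        raise ValueError(
            "prior forward projection is nonpositive inside the metal trace "
            "even after flooring; prior image degenerate"
        )
    ratio = original.values / prior_proj
    ratio_filled = _interpolate_rows(ratio, trace.values)
    p_norm = ratio_filled * prior_proj

    out = original.values.copy()
    t = trace.values
    out[t] = beta * p_norm[t] + (1.0 - beta) * p_lin[t]
    return Sinogram(values=out, geometry=original.geometry)


def reinsert_metal(
    third_pass: AttenuationImage, first_pass: AttenuationImage, mask: MetalMask
) -> AttenuationImage:
    """Substitute first-pass values on the metal mask (image domain)."""
    if third_pass.shape != first_pass.shape or third_pass.shape != mask.values.shape:
        raise ValueError("image/mask shapes do not agree")
    final = np.where(mask.values, first_pass.values, third_pass.values)
    return AttenuationImage(
        values=final, pixel_spacing_mm=third_pass.pixel_spacing_mm, unit=third_pass.unit
    )


def run_semar(corrupted: Sinogram, params: SemarParams | None = None) -> SemarResult:
    """Execute the full three-pass pipeline on a corrupted sinogram.

    Metal-free input short-circuits: the final image is the first-pass
    (standard) reconstruction, bit-identical.
    """
    if params is None:
        params = SemarParams()
    geom = corrupted.geometry

    first_mu = fbp(corrupted, params.filter_name)
    first_hu = first_mu.to_hu()
    mask = segment_metal(first_hu, params.metal_threshold_hu)

    if mask.empty:
        logger.info("no metal above %.0f HU; returning standard reconstruction",
                    params.metal_threshold_hu)
        return SemarResult(
            first_pass=first_hu,
            second_pass=None,
            final=first_hu,
            metal_mask=mask,
            trace_mask=None,
            interpolated_sinogram=None,
            blended_sinogram=None,
        )

    trace = project_metal_trace(
        mask, geom, pixel_spacing_mm=first_hu.pixel_spacing_mm,
        epsilon=params.trace_epsilon,
    )
    interp = interpolate_trace(corrupted, trace)
    second_hu = fbp(interp, params.filter_name).to_hu()
    prior = classify_tissues(second_hu, params)
    blended = blend_with_prior(corrupted, prior, trace, geom, params)
    third_hu = fbp(blended, params.filter_name).to_hu()
    final = reinsert_metal(third_hu, first_hu, mask)

    return SemarResult(
        first_pass=first_hu,
        second_pass=second_hu,
        final=final,
        metal_mask=mask,
        trace_mask=trace,
        interpolated_sinogram=interp,
        blended_sinogram=blended,
    )
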