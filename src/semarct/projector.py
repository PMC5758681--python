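"""Parallel-beam forward projection, FBP, and polychromatic acquisition.

The projection backend is scikit-image's ``radon``/``iradon`` pair
(``circle=False`` so the detector row always covers the image diagonal),
wrapped so sinogram entries are true line integrals of linear attenuation,
``∫ mu dl`` with ``mu`` in 1/cm and path length in cm.

``polychromatic_acquire`` adds the two physical mechanisms that create metal
streaks in a real scan: beam hardening (a polychromatic spectrum whose
low-energy photons are preferentially absorbed by dense material, biasing the
log-normalized measurement low along metal-crossing rays) and photon counting
noise (Poisson statistics on the transmitted intensity, exploding after the
log transform when rays behind metal are starved of photons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .image import MU_WATER, AttenuationImage, hu_to_mu

VALID_FILTERS = ("ramp", "shepp-logan", "hann")


def _diagonal_bins(image_size_px: int) -> int:
    # skimage radon(circle=False) pads the image to its diagonal
    return int(np.ceil(np.sqrt(2) * image_size_px))


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel-beam scan geometry.

    View angles are uniformly spaced on the half-open interval [0, 180)
    degrees.  The detector bin count is fixed by the image size (the padded
    diagonal), so that every ray through the image support is measured.
    """

    n_views: int
    image_size_px: int
    detector_spacing_mm: float = 1.0
    parallel_beam: bool = True

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.image_size_px < 1:
            raise ValueError("image_size_px must be >= 1")
        if self.detector_spacing_mm <= 0:
            raise ValueError("detector spacing must be positive")
        if not self.parallel_beam:
            raise ValueError("only parallel-beam geometry is supported")

    @property
    def n_detector_bins(self) -> int:
        return _diagonal_bins(self.image_size_px)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.n_views, endpoint=False)


@dataclass(frozen=True)
class Sinogram:
    """Line integrals (dimensionless, = ∫mu dl) on a scan geometry.

    Axis 0 indexes view angle, axis 1 the detector bin; bin 0 sits at the
    most negative lateral offset.
    """

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.geometry.n_views, self.geometry.n_detector_bins):
            raise ValueError(
                f"sinogram shape {values.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_detector_bins})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Spectrum:
    """Discrete polychromatic X-ray spectrum.

    ``weights`` are the normalized photon fractions per energy bin and
    ``mu_scale`` maps each material name to per-bin multiplicative factors on
    that material's reference attenuation.  A single-bin spectrum with unit
    scale factors reproduces the monochromatic path exactly.
    """

    energies_kev: tuple[float, ...]
    weights: tuple[float, ...]
    mu_scale: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.energies_kev) < 1:
            raise ValueError("spectrum needs at least one energy bin")
        if len(self.weights) != len(self.energies_kev):
            raise ValueError("weights and energies must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        for mat, sc in self.mu_scale.items():
            if len(sc) != len(self.energies_kev):
                raise ValueError(f"mu_scale[{mat!r}] length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.energies_kev)

    def scale_for(self, material: str) -> np.ndarray:
        if material not in self.mu_scale:
            raise KeyError(f"no attenuation scaling for material {material!r}")
        return np.asarray(self.mu_scale[material], dtype=float)

    @classmethod
    def monochromatic(cls, materials: tuple[str, ...] = ()) -> "Spectrum":
        """Degenerate single-bin spectrum: no beam hardening."""
        return cls(
            energies_kev=(70.0,),
            weights=(1.0,),
            mu_scale={m: (1.0,) for m in materials},
        )

    @classmethod
    def default_polychromatic(cls) -> "Spectrum":
        """Three-bin 120 kVp stand-in.

        Scale factors follow the qualitative energy dependence of the
        materials: water-like tissues vary mildly with energy, bone more
        (photoelectric contribution of calcium), metal strongly.  Values are
        declared plumbing, not measured cross sections.
        """
        return cls(
            energies_kev=(50.0, 70.0, 100.0),
            weights=(0.3, 0.5, 0.2),
            mu_scale={
                "air": (1.0, 1.0, 1.0),
                "soft_tissue": (1.22, 1.0, 0.86),
                "muscle": (1.22, 1.0, 0.86),
                "contrast_vessel": (1.6, 1.0, 0.72),
                "bone": (1.9, 1.0, 0.65),
                "metal": (2.6, 1.0, 0.48),
            },
        )


def radon_forward(img: AttenuationImage, geom: ScanGeometry) -> Sinogram:
    """Forward project a linear-attenuation image onto ``geom``.

    Each sinogram entry is the line integral ``∫ mu dl`` (mu in 1/cm, path in
    cm) along the corresponding parallel ray; the operation is linear in the
    image.
    """
    if img.unit != "mu":
        raise ValueError("radon_forward expects a linear-attenuation (mu) image")
    n_rows, n_cols = img.shape
    if n_rows != n_cols:
        raise ValueError("image must be square")
    if n_rows != geom.image_size_px:
        raise ValueError(
            f"image size {n_rows} does not match geometry image_size_px "
            f"{geom.image_size_px}"
        )
    # skimage returns (detector, view); transpose to (view, detector) and
    # scale pixel-unit sums to cm path lengths.
    pix_cm = img.pixel_spacing_mm / 10.0
    sino = radon(img.values, theta=geom.angles_deg, circle=False).T * pix_cm
    return Sinogram(values=sino, geometry=geom)


def fbp(sino: Sinogram, filter_name: str = "shepp-logan") -> AttenuationImage:
    """Filtered back-projection estimate of the attenuation image.

    Returns a mu-unit image on the geometry's native grid
    (``image_size_px`` square, pixel pitch = detector spacing).
    """
    if filter_name not in VALID_FILTERS:
        raise ValueError(
            f"unknown filter {filter_name!r}; choose one of {VALID_FILTERS}"
        )
    geom = sino.geometry
    pix_cm = geom.detector_spacing_mm / 10.0
    recon = iradon(
        sino.values.T / pix_cm,
        theta=geom.angles_deg,
        filter_name=filter_name,
        circle=False,
        output_size=geom.image_size_px,
    )
    return AttenuationImage(
        values=recon, pixel_spacing_mm=geom.detector_spacing_mm, unit="mu"
    )


def polychromatic_acquire(
    material_map,
    spectrum: Spectrum,
    geom: ScanGeometry,
    photons_per_ray: float = 1e5,
    seed: int | None = None,
    hu_table: dict[str, float] | None = None,
    mu_water: float = MU_WATER,
    starvation_floor_counts: float = 0.5,
) -> Sinogram:
    """Simulate a polychromatic, photon-counting parallel-beam scan.

    Per ray the transmitted intensity is

        I = sum_bins  w_b * I0 * exp(-sum_materials L_m * mu_m(b))

    with ``L_m`` the ray's path length through material ``m`` (cm) and
    ``mu_m(b)`` that material's attenuation in energy bin ``b``.  Poisson
    counting noise is applied when ``photons_per_ray`` is finite; rays with
    zero detected counts are clamped to ``starvation_floor_counts`` before
    the log (photon starvation).  The returned sinogram holds the
    log-normalized line integrals ``-ln(I/I0)``.

    Deterministic for a fixed ``seed``.
    """
    from .phantom import DEFAULT_HU_TABLE  # local import avoids a cycle

    if photons_per_ray <= 0:
        raise ValueError("photons_per_ray must be positive")
    if hu_table is None:
        hu_table = DEFAULT_HU_TABLE
    materials = material_map.present_materials()
    for mat in materials:
        if mat not in hu_table:
            raise KeyError(f"material {mat!r} missing from HU table")
        spectrum.scale_for(mat)  # raises if missing

    spacing = material_map.pixel_spacing_mm
    # Path-length sinogram per material (cm), via projection of its indicator.
    pathlengths = {}
    for mat in materials:
        indicator = AttenuationImage(
            values=material_map.mask(mat).astype(float),
            pixel_spacing_mm=spacing,
            unit="mu",
        )
        pathlengths[mat] = radon_forward(indicator, geom).values

    weights = np.asarray(spectrum.weights, dtype=float)
    intensity = np.zeros_like(next(iter(pathlengths.values())))
    for b in range(spectrum.n_bins):
        line_integral_b = np.zeros_like(intensity)
        for mat in materials:
            mu_ref = hu_to_mu(hu_table[mat], mu_water)
            line_integral_b += pathlengths[mat] * mu_ref * spectrum.scale_for(mat)[b]
        intensity += weights[b] * np.exp(-np.clip(line_integral_b, 0.0, None))

    if math.isfinite(photons_per_ray):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(photons_per_ray * intensity).astype(float)
        counts = np.maximum(counts, starvation_floor_counts)
        sino = -np.log(counts / photons_per_ray)
    else:
        sino = -np.log(np.clip(intensity, 1e-300, None))
    return Sinogram(values=sino, geometry=geom)
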