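"""Synthetic stented-abdomen phantoms and synthetic reader ratings.

A phantom is a 2-D axial material label map: a soft-tissue body ellipse in
air, two paraspinal muscle ellipses, a vertebral bone disc, contrast-filled
vessels (the aorta and small visceral arteries), and metal stent struts
arranged on a stented vessel's circumference.  Discrete high-density struts
are what throw the dark/bright streaks that the artifact-reduction pipeline
must remove, mirroring the radiopaque markers and stent material of
fenestrated/branched aortic stent grafts.

Everything is deterministic for a fixed spec + seed, so downstream stages
are testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import AttenuationImage

MATERIALS = ("air", "soft_tissue", "muscle", "bone", "contrast_vessel", "metal")
_LABEL = {name: i for i, name in enumerate(MATERIALS)}

#: Default HU per material.  Configurable defaults, not claims about true
#: materials; metal is set well above any tissue so a threshold separates it.
DEFAULT_HU_TABLE: dict[str, float] = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "muscle": 60.0,
    "bone": 700.0,
    "contrast_vessel": 300.0,
    "metal": 8000.0,
}


@dataclass(frozen=True)
class MaterialMap:
    """Square 2-D grid of material identifiers."""

    labels: np.ndarray  # int array of indices into MATERIALS
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 2 or labels.shape[0] != labels.shape[1]:
            raise ValueError("label grid must be 2-D and square")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if labels.min() < 0 or labels.max() >= len(MATERIALS):
            raise ValueError("unknown material label")
        if np.all(labels == _LABEL["air"]):
            raise ValueError("map must contain at least one non-air label")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, material: str) -> np.ndarray:
        return self.labels == _LABEL[material]

    def present_materials(self) -> tuple[str, ...]:
        present = np.unique(self.labels)
        return tuple(MATERIALS[i] for i in present)

    def count(self, material: str) -> int:
        return int(self.mask(material).sum())


@dataclass(frozen=True)
class VesselSpec:
    """Circular contrast-filled vessel cross-section."""

    center_px: tuple[float, float]  # (row, col)
    diameter_mm: float
    contrast_hu: float = 300.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("vessel diameter must be positive")


@dataclass(frozen=True)
class StentSpec:
    """Metal struts on the circumference of a vessel."""

    vessel_index: int
    n_struts: int = 8
    strut_thickness_px: int = 1
    phase_deg: float = 0.0
    full_ring: bool = False

    def __post_init__(self) -> None:
        if self.n_struts < 1:
            raise ValueError("a stent needs at least one strut")
        if self.strut_thickness_px < 1:
            raise ValueError("strut thickness must be >= 1 px")


@dataclass(frozen=True)
class Ellipse:
    """(row, col) center and semi-axes, all in pixels."""

    center_px: tuple[float, float]
    semi_axes_px: tuple[float, float]  # (row semi-axis, col semi-axis)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic axial slice.

    Defaults place an abdomen-sized body ellipse on a 256 px, 1 mm grid with
    paraspinal muscles and a vertebral body; vessels/stents are supplied by
    the caller (see :func:`default_spec` and :func:`random_spec`).
    """

    image_size_px: int = 256
    pixel_spacing_mm: float = 1.0
    body: Ellipse | None = None
    muscles: tuple[Ellipse, ...] | None = None
    bone: Ellipse | None = None
    vessels: tuple[VesselSpec, ...] = ()
    stents: tuple[StentSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 16:
            raise ValueError("image_size_px too small")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        n = self.image_size_px
        c = (n - 1) / 2.0
        if self.body is None:
            object.__setattr__(
                self, "body", Ellipse((c, c), (0.37 * n, 0.45 * n))
            )
        if self.muscles is None:
            object.__setattr__(
                self,
                "muscles",
                (
                    Ellipse((c + 0.22 * n, c - 0.14 * n), (0.08 * n, 0.055 * n)),
                    Ellipse((c + 0.22 * n, c + 0.14 * n), (0.08 * n, 0.055 * n)),
                ),
            )
        if self.bone is None:
            object.__setattr__(
                self, "bone", Ellipse((c + 0.24 * n, c), (0.07 * n, 0.07 * n))
            )
        for stent in self.stents:
            if not (0 <= stent.vessel_index < len(self.vessels)):
                raise ValueError("stent refers to a nonexistent vessel")


def _ellipse_mask(shape: tuple[int, int], ell: Ellipse) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = ell.center_px
    ar, ac = ell.semi_axes_px
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def strut_centers(vessel: VesselSpec, stent: StentSpec, pixel_spacing_mm: float) -> list[tuple[float, float]]:
    """Strut center coordinates (row, col) on the vessel circumference."""
    radius_px = vessel.diameter_mm / 2.0 / pixel_spacing_mm
    out = []
    for k in range(stent.n_struts):
        ang = np.deg2rad(stent.phase_deg) + 2.0 * np.pi * k / stent.n_struts
        out.append(
            (
                vessel.center_px[0] + radius_px * np.sin(ang),
                vessel.center_px[1] + radius_px * np.cos(ang),
            )
        )
    return out


def make_phantom(spec: PhantomSpec) -> MaterialMap:
    """Render a :class:`PhantomSpec` into a material label map.

    Painting order is air < soft tissue < muscle < bone < vessel < metal, so
    later structures overwrite earlier ones.  Rejects vessels outside the
    body ellipse and stents whose struts would overlap bone.
    """
    n = spec.image_size_px
    shape = (n, n)
    labels = np.full(shape, _LABEL["air"], dtype=np.int8)

    body_mask = _ellipse_mask(shape, spec.body)
    labels[body_mask] = _LABEL["soft_tissue"]
    for m in spec.muscles:
        labels[_ellipse_mask(shape, m)] = _LABEL["muscle"]
    bone_mask = _ellipse_mask(shape, spec.bone)
    labels[bone_mask] = _LABEL["bone"]

    for vessel in spec.vessels:
        radius_px = vessel.diameter_mm / 2.0 / spec.pixel_spacing_mm
        vmask = _disk_mask(shape, vessel.center_px, radius_px)
        if not np.all(body_mask[vmask]):
            raise ValueError(
                f"vessel at {vessel.center_px} extends outside the body ellipse"
            )
        labels[vmask] = _LABEL["contrast_vessel"]

    metal_mask = np.zeros(shape, dtype=bool)
    for stent in spec.stents:
        vessel = spec.vessels[stent.vessel_index]
        radius_px = vessel.diameter_mm / 2.0 / spec.pixel_spacing_mm
        if stent.full_ring:
            ring = _disk_mask(shape, vessel.center_px, radius_px + 0.5) & ~_disk_mask(
                shape, vessel.center_px, radius_px - 0.5
            )
            metal_mask |= ring
        half = stent.strut_thickness_px / 2.0
        for center in strut_centers(vessel, stent, spec.pixel_spacing_mm):
            metal_mask |= _disk_mask(shape, center, half)
    if np.any(metal_mask & bone_mask):
        raise ValueError("metal struts overlap the bone region")
    labels[metal_mask] = _LABEL["metal"]

    return MaterialMap(labels=labels, pixel_spacing_mm=spec.pixel_spacing_mm)


def materials_to_hu(
    material_map: MaterialMap, hu_table: dict[str, float] | None = None
) -> AttenuationImage:
    """Pixelwise material -> HU lookup."""
    if hu_table is None:
        hu_table = DEFAULT_HU_TABLE
    for mat in material_map.present_materials():
        if mat not in hu_table:
            raise KeyError(f"material {mat!r} missing from HU table")
    lut = np.array([hu_table.get(m, np.nan) for m in MATERIALS], dtype=float)
    return AttenuationImage(
        values=lut[material_map.labels],
        pixel_spacing_mm=material_map.pixel_spacing_mm,
        unit="HU",
    )


def struts_for_diameter(diameter_mm: float) -> int:
    """Default strut count: one point-like strut per ~5 mm of circumference.

    At 1 mm pixels a strut cross-section is a single pixel; spacing them
    ~5 mm apart leaves enough unshadowed rays through the lumen for the
    in-painting passes to recover the contrast inside the stent, as thin
    real-world struts do.
    """
    return max(3, round(np.pi * diameter_mm / 5.0))


def default_spec(seed: int = 0) -> PhantomSpec:
    """One aorta (20 mm) plus three stented visceral arteries.

    Stent diameters default to the clinical ranges for celiac/SMA (8-12 mm)
    and renal (5-8 mm) branch stents.
    """
    n = 256
    c = (n - 1) / 2.0
    vessels = (
        VesselSpec((c - 0.02 * n, c), 20.0),              # aorta, unstented
        VesselSpec((c - 0.16 * n, c - 0.12 * n), 10.0),   # celiac
        VesselSpec((c - 0.13 * n, c + 0.14 * n), 8.0),    # SMA
        VesselSpec((c + 0.05 * n, c - 0.20 * n), 6.0),    # renal
    )
    stents = tuple(
        StentSpec(vessel_index=i, n_struts=struts_for_diameter(vessels[i].diameter_mm))
        for i in (1, 2, 3)
    )
    return PhantomSpec(image_size_px=n, vessels=vessels, stents=stents, seed=seed)


def random_spec(seed: int) -> PhantomSpec:
    """Randomized stented phantom: jittered vessel positions and diameters.

    Diameters are drawn from the clinical stent ranges (celiac/SMA 8-12 mm,
    renal 5-8 mm); positions jitter by a few pixels around the default
    layout.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    n = 256
    c = (n - 1) / 2.0

    def jitter(row: float, col: float, scale: float = 4.0) -> tuple[float, float]:
        return (row + rng.uniform(-scale, scale), col + rng.uniform(-scale, scale))

    vessels = (
        VesselSpec(jitter(c - 0.02 * n, c, 2.0), rng.uniform(18.0, 22.0)),
        VesselSpec(jitter(c - 0.16 * n, c - 0.12 * n), rng.uniform(8.0, 12.0)),
        VesselSpec(jitter(c - 0.13 * n, c + 0.14 * n), rng.uniform(8.0, 12.0)),
        VesselSpec(jitter(c + 0.05 * n, c - 0.20 * n), rng.uniform(5.0, 8.0)),
    )
    stents = tuple(
        StentSpec(
            vessel_index=i,
            n_struts=struts_for_diameter(vessels[i].diameter_mm),
            phase_deg=rng.uniform(0, 60),
        )
        for i in (1, 2, 3)
    )
    return PhantomSpec(image_size_px=n, vessels=vessels, stents=stents, seed=seed)


def read_spec_config(path) -> PhantomSpec:
    """Read a :class:`PhantomSpec` from a plain-text key-value config.

    INI-style schema: a ``[phantom]`` section with ``image_size_px``,
    ``pixel_spacing_mm``, ``seed``; one ``[vessel.<name>]`` section per
    vessel (``center_row``, ``center_col``, ``diameter_mm``,
    ``contrast_hu``); one ``[stent.<name>]`` section per stent
    (``vessel_index``, ``n_struts``, ``strut_thickness_px``, ``phase_deg``,
    ``full_ring``).  Vessel order follows file order.
    """
    import configparser

    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise FileNotFoundError(f"config file {path} not found or unreadable")
    ph = cp["phantom"] if cp.has_section("phantom") else {}
    vessels = []
    stents = []
    for section in cp.sections():
        if section.startswith("vessel."):
            s = cp[section]
            vessels.append(
                VesselSpec(
                    center_px=(s.getfloat("center_row"), s.getfloat("center_col")),
                    diameter_mm=s.getfloat("diameter_mm"),
                    contrast_hu=s.getfloat("contrast_hu", 300.0),
                )
            )
        elif section.startswith("stent."):
            s = cp[section]
            stents.append(
                StentSpec(
                    vessel_index=s.getint("vessel_index"),
                    n_struts=s.getint("n_struts", 8),
                    strut_thickness_px=s.getint("strut_thickness_px", 2),
                    phase_deg=s.getfloat("phase_deg", 0.0),
                    full_ring=s.getboolean("full_ring", False),
                )
            )
    return PhantomSpec(
        image_size_px=int(ph.get("image_size_px", 256)),
        pixel_spacing_mm=float(ph.get("pixel_spacing_mm", 1.0)),
        vessels=tuple(vessels),
        stents=tuple(stents),
        seed=int(ph.get("seed", 0)),
    )


@dataclass(frozen=True)
class RatingTable:
    """Two readers' ordinal scores on the 1-5 artifact/visualization scales."""

    reader1: np.ndarray
    reader2: np.ndarray

    def __post_init__(self) -> None:
        r1 = np.asarray(self.reader1, dtype=int)
        r2 = np.asarray(self.reader2, dtype=int)
        object.__setattr__(self, "reader1", r1)
        object.__setattr__(self, "reader2", r2)
        if r1.shape != r2.shape or r1.ndim != 1:
            raise ValueError("readers must give equal-length 1-D score vectors")
        for r in (r1, r2):
            if r.size and (r.min() < 1 or r.max() > 5):
                raise ValueError("scores must lie in {1,...,5}")


def simulate_ratings(
    true_scores, reader_noise_sd: float, seed: int
) -> RatingTable:
    """Two readers = true score + independent rounded Gaussian noise, clipped.

    A statistical fixture for exercising agreement statistics, not a model
    of human readers.
    """
    true = np.asarray(true_scores, dtype=float)
    if true.size and (true.min() < 1 or true.max() > 5):
        raise ValueError("true scores must lie in [1, 5]")
    if reader_noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(2):
        noisy = true + rng.normal(0.0, reader_noise_sd, size=true.shape)
        scores.append(np.clip(np.rint(noisy), 1, 5).astype(int))
    return RatingTable(reader1=scores[0], reader2=scores[1])
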