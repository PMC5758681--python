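"""Shared fixtures: small phantoms and a cached stented-phantom SEMAR run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import semarct as sc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_spec(seed: int = 0, stented: bool = True) -> sc.PhantomSpec:
    """128 px phantom with one aorta and two stentable visceral vessels."""
    n = 128
    c = (n - 1) / 2.0
    vessels = (
        sc.VesselSpec((c - 0.02 * n, c), 16.0),
        sc.VesselSpec((c - 0.16 * n, c - 0.12 * n), 10.0),
        sc.VesselSpec((c + 0.05 * n, c - 0.20 * n), 6.0),
    )
    stents = (
        (sc.StentSpec(vessel_index=1, n_struts=6), sc.StentSpec(vessel_index=2, n_struts=4))
        if stented
        else ()
    )
    return sc.PhantomSpec(image_size_px=n, vessels=vessels, stents=stents, seed=seed)


@pytest.fixture(scope="session")
def small_geom() -> sc.ScanGeometry:
    return sc.ScanGeometry(n_views=120, image_size_px=128, detector_spacing_mm=1.0)


@pytest.fixture(scope="session")
def stented_case(small_geom):
    """One corrupted acquisition of a small stented phantom + SEMAR result."""
    spec = small_spec(seed=3)
    material_map = sc.make_phantom(spec)
    sino = sc.polychromatic_acquire(
        material_map,
        sc.Spectrum.default_polychromatic(),
        small_geom,
        photons_per_ray=1e5,
        seed=11,
    )
    result = sc.run_semar(sino)
    return {
        "spec": spec,
        "map": material_map,
        "sino": sino,
        "result": result,
    }


@pytest.fixture(scope="session")
def metal_free_case(small_geom):
    """Noiseless monochromatic scan of a metal-free phantom."""
    spec = small_spec(seed=5, stented=False)
    material_map = sc.make_phantom(spec)
    spectrum = sc.Spectrum.monochromatic(materials=material_map.present_materials())
    sino = sc.polychromatic_acquire(
        material_map, spectrum, small_geom, photons_per_ray=float("inf")
    )
    return {"spec": spec, "map": material_map, "sino": sino}
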