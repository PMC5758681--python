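"""2-D attenuation images with explicit units.

CT images live in one of two unit systems: linear attenuation ``mu`` in 1/cm
(what the projector integrates along rays) and Hounsfield units ``HU``
(what radiologists read).  The two are related through the attenuation of
water at the effective beam energy:

    HU = 1000 * (mu - mu_water) / mu_water

``AttenuationImage`` carries its unit tag so the conversion is always
explicit and lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Linear attenuation of water at ~70 keV effective energy, 1/cm.
MU_WATER = 0.192


@dataclass(frozen=True)
class AttenuationImage:
    """Square 2-D image of attenuation values.

    Parameters
    ----------
    values
        2-D float array, either linear attenuation (1/cm) or HU.
    pixel_spacing_mm
        Isotropic pixel pitch in millimetres.
    unit
        ``"mu"`` or ``"HU"``.
    mu_water
        Water attenuation (1/cm) anchoring the HU scale.
    """

    values: np.ndarray
    pixel_spacing_mm: float = 1.0
    unit: str = "HU"
    mu_water: float = MU_WATER

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.unit not in ("mu", "HU"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if self.mu_water <= 0:
            raise ValueError("mu_water must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_hu(self) -> "AttenuationImage":
        if self.unit == "HU":
            return self
        hu = 1000.0 * (self.values - self.mu_water) / self.mu_water
        return replace(self, values=hu, unit="HU")

    def to_mu(self) -> "AttenuationImage":
        if self.unit == "mu":
            return self
        mu = self.mu_water * (1.0 + self.values / 1000.0)
        return replace(self, values=mu, unit="mu")


def hu_to_mu(hu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """HU -> linear attenuation (1/cm)."""
    return mu_water * (1.0 + np.asarray(hu, dtype=float) / 1000.0)


def mu_to_hu(mu: np.ndarray, mu_water: float = MU_WATER) -> np.ndarray:
    """Linear attenuation (1/cm) -> HU."""
    return 1000.0 * (np.asarray(mu, dtype=float) - mu_water) / mu_water
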