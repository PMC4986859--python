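"""Anatomical fractions consumed by the sandwich model.

The model needs the mesophyll core fraction alpha; the cross-section
measurements that produce it (layer thicknesses from stained sections)
also yield the variant alpha' that re-assigns the inner, non-wall part of
the epidermis to the core, the cuticle+outer-wall share of the epidermis
layer, and — from mass and thickness — the intercellular air fraction.
All thicknesses are in micrometres; the "epidermis layer" always means
epidermal tissue plus its cuticle membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "AnatomyProfile",
    "LeafMassSample",
    "mesophyll_fraction",
    "mesophyll_fraction_prime",
    "surface_fraction",
    "air_fraction",
    "WATER_DENSITY",
    "SOLID_TISSUE_DENSITY",
]

#: specific gravity of water, g/cm^3
WATER_DENSITY = 1.0
#: specific gravity of solid (cell-wall + protoplast dry matter) tissue, g/cm^3
SOLID_TISSUE_DENSITY = 1.5


@dataclass(frozen=True)
class AnatomyProfile:
    """Per-layer thicknesses of one lamina cross-section, micrometres.

    Outer walls are the outer periclinal cell walls of the respective
    epidermis and are contained in the epidermis thickness (cuticle is not).
    """

    upper_cuticle: float
    upper_epidermis: float
    upper_outer_wall: float
    palisade: float
    spongy: float
    lower_epidermis: float
    lower_outer_wall: float
    lower_cuticle: float

    def __post_init__(self) -> None:
        vals = (
            self.upper_cuticle,
            self.upper_epidermis,
            self.upper_outer_wall,
            self.palisade,
            self.spongy,
            self.lower_epidermis,
            self.lower_outer_wall,
            self.lower_cuticle,
        )
        if any(v < 0 for v in vals):
            raise ValueError("layer thicknesses must be >= 0")
        if self.upper_outer_wall > self.upper_epidermis:
            raise ValueError("upper outer wall exceeds upper epidermis thickness")
        if self.lower_outer_wall > self.lower_epidermis:
            raise ValueError("lower outer wall exceeds lower epidermis thickness")
        if self.total_thickness <= 0:
            raise ValueError("total thickness must be positive")

    @property
    def mesophyll_thickness(self) -> float:
        return self.palisade + self.spongy

    @property
    def total_thickness(self) -> float:
        """Whole lamina thickness: cuticles + epidermises + mesophyll, um."""
        return (
            self.upper_cuticle
            + self.upper_epidermis
            + self.palisade
            + self.spongy
            + self.lower_epidermis
            + self.lower_cuticle
        )


@dataclass(frozen=True)
class LeafMassSample:
    """Fresh/dry mass per area (g/m^2) and thickness (mm) of one leaf."""

    fresh_mass_per_area: float
    dry_mass_per_area: float
    thickness: float

    def __post_init__(self) -> None:
        if self.dry_mass_per_area <= 0:
            raise ValueError("dry mass must be positive")
        if self.fresh_mass_per_area < self.dry_mass_per_area:
            raise ValueError("fresh mass cannot be below dry mass")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


def mesophyll_fraction(profile: AnatomyProfile) -> float:
    """Core fraction alpha: (palisade + spongy) / total lamina thickness."""
    return profile.mesophyll_thickness / profile.total_thickness


def mesophyll_fraction_prime(profile: AnatomyProfile) -> float:
    """Variant alpha' counting the inner part of each epidermis as core.

    The stiff face is reduced to cuticle + outer periclinal wall; the inner
    epidermis (cells minus outer wall) joins the mesophyll.  Always
    >= alpha, and equal to it when the outer walls fill the epidermis.
    """
    inner = (
        profile.upper_epidermis
        - profile.upper_outer_wall
        + profile.lower_epidermis
        - profile.lower_outer_wall
    )
    return (profile.mesophyll_thickness + inner) / profile.total_thickness


def surface_fraction(profile: AnatomyProfile) -> float:
    """Cuticle + outer-wall share of the epidermis layers.

    (upper/lower cuticles + outer walls) / (cuticles + epidermises); in
    [0, 1].  This share tracks face stiffness across species.
    """
    epidermis_layer = (
        profile.upper_cuticle
        + profile.lower_cuticle
        + profile.upper_epidermis
        + profile.lower_epidermis
    )
    if epidermis_layer <= 0:
        raise ValueError("epidermis layer has zero thickness")
    stiff = (
        profile.upper_cuticle
        + profile.lower_cuticle
        + profile.upper_outer_wall
        + profile.lower_outer_wall
    )
    return stiff / epidermis_layer


def air_fraction(sample: LeafMassSample) -> float:
    """Intercellular airspace as a fraction of lamina volume.

    Water volume is (fresh - dry) / 1 and solid volume dry / 1.5 (g/cm^3
    specific gravities); the remainder of thickness x area is air.  With
    masses in g/m^2 and thickness in mm the lamina volume is
    1000 * thickness cm^3/m^2.  A negative result (inconsistent inputs,
    e.g. thickness underestimated) is returned with a warning.
    """
    water_vol = (sample.fresh_mass_per_area - sample.dry_mass_per_area) / WATER_DENSITY
    solid_vol = sample.dry_mass_per_area / SOLID_TISSUE_DENSITY
    total_vol = 1000.0 * sample.thickness
    frac = 1.0 - (water_vol + solid_vol) / total_vol
    if frac < 0:
        warnings.warn(
            f"negative air fraction {frac:.3f}: mass and thickness inputs "
            "are mutually inconsistent",
            UserWarning,
            stacklevel=2,
        )
    return frac
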