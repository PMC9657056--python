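"""Stacked cross-section idealization of the implanted femur.

The femur working length is modelled as a stack of axial stations, each
carrying a set of concentric regions: a cortical annulus, and either a
cancellous core (intact, and everywhere distal to the stem tip) or a
stem cylinder surrounded by a thin resin annulus (implanted, proximal to
the stem tip). Axial coordinate z runs from 0 at the lesser trochanter,
increasing distally, in mm.

The stem radius tapers linearly from its proximal value to its value at
the tip, emulating a press-fit stem that nearly fills the reamed canal
proximally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .materials import MaterialSpec, resolve_material

#: Region roles: cortical regions carry the bone-side metrics; interior
#: regions (core, resin, stem) only share the section strain field.
ROLE_CORTICAL = "cortical"
ROLE_INTERIOR = "interior"


@dataclass(frozen=True)
class Region:
    """One material region of a cross-section.

    ``r_outer_mm``/``r_inner_mm`` keep the generating radii so that the
    field sampler can place element centroids; ``r_inner_mm`` is 0 for a
    solid circle.
    """

    material: str
    area_mm2: float
    i_x_mm4: float
    i_y_mm4: float
    role: str
    r_outer_mm: float
    r_inner_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0 or self.i_x_mm4 <= 0 or self.i_y_mm4 <= 0:
            raise GeometryError(
                f"region {self.material}: area and second moments must be > 0"
            )


@dataclass(frozen=True)
class Station:
    z_mm: float
    regions: tuple[Region, ...]


@dataclass(frozen=True)
class CrossSectionModel:
    """Ordered stack of stations covering [0, working_length]."""

    stations: tuple[Station, ...]
    stem_tip_z_mm: float
    working_length_mm: float
    configuration: str  # "intact" or the stem material name

    def __post_init__(self) -> None:
        zs = [s.z_mm for s in self.stations]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise GeometryError("stations must be strictly increasing in z")
        for s in self.stations:
            n_cort = sum(r.role == ROLE_CORTICAL for r in s.regions)
            if n_cort != 1:
                raise GeometryError(
                    f"station z={s.z_mm}: exactly one cortical region required"
                )


@dataclass(frozen=True)
class GeometryConfig:
    """Parameterized femur/stem geometry (all lengths in mm)."""

    working_length_mm: float = 328.0
    n_stations: int = 20
    cortical_outer_mm: float = 13.5
    cortical_inner_mm: float = 8.0
    stem_radius_proximal_mm: float = 7.5
    stem_radius_tip_mm: float = 5.0
    stem_tip_z_mm: float = 150.0

    def __post_init__(self) -> None:
        if self.working_length_mm <= 0:
            raise GeometryError("working length must be > 0")
        if not 0 < self.cortical_inner_mm < self.cortical_outer_mm:
            raise GeometryError("need 0 < inner radius < outer radius")
        if self.n_stations < 2:
            raise GeometryError("need at least two stations")
        if not 0 < self.stem_tip_z_mm < self.working_length_mm:
            raise GeometryError("stem tip must lie inside the working length")


def annulus_area(r_outer: float, r_inner: float) -> float:
    return math.pi * (r_outer**2 - r_inner**2)


def annulus_inertia(r_outer: float, r_inner: float) -> float:
    """Second moment of an annulus about any centroidal axis."""
    return math.pi / 4.0 * (r_outer**4 - r_inner**4)


def _stem_radius_at(config: GeometryConfig, z: float) -> float:
    t = z / config.stem_tip_z_mm
    return (
        config.stem_radius_proximal_mm
        + t * (config.stem_radius_tip_mm - config.stem_radius_proximal_mm)
    )


def build_geometry(
    config: GeometryConfig, stem_material: str | None = None
) -> CrossSectionModel:
    """Build the station stack for one configuration.

    ``stem_material=None`` gives the intact femur (cortical annulus +
    cancellous core everywhere). With a stem material, every station
    proximal to the stem tip replaces the cancellous core by a stem
    cylinder plus a resin annulus out to the cortical inner radius; the
    stem tip z is always inserted as a station edge so intact and
    implanted stacks share identical bands.

    Raises
    ------
    GeometryError
        If the stem radius reaches the cortical inner radius anywhere.
    """
    zs = np.linspace(0.0, config.working_length_mm, config.n_stations)
    zs = np.unique(np.append(zs, config.stem_tip_z_mm))

    stations: list[Station] = []
    for z in zs:
        cortical = Region(
            "cortical",
            annulus_area(config.cortical_outer_mm, config.cortical_inner_mm),
            annulus_inertia(config.cortical_outer_mm, config.cortical_inner_mm),
            annulus_inertia(config.cortical_outer_mm, config.cortical_inner_mm),
            ROLE_CORTICAL,
            config.cortical_outer_mm,
            config.cortical_inner_mm,
        )
        regions = [cortical]
        if z < config.stem_tip_z_mm:
            # Proximal bands always split the core at the stem radius so
            # intact and implanted stacks share one element layout; for
            # the intact femur both sub-regions are cancellous.
            rs = _stem_radius_at(config, z)
            if rs >= config.cortical_inner_mm:
                raise GeometryError(
                    f"stem radius {rs:.2f} mm >= cortical inner radius "
                    f"{config.cortical_inner_mm:.2f} mm at z={z:.1f} mm"
                )
            inner_mat = stem_material if stem_material is not None else "cancellous"
            outer_mat = "resin" if stem_material is not None else "cancellous"
            regions.append(
                Region(
                    inner_mat,
                    annulus_area(rs, 0.0),
                    annulus_inertia(rs, 0.0),
                    annulus_inertia(rs, 0.0),
                    ROLE_INTERIOR,
                    rs,
                )
            )
            regions.append(
                Region(
                    outer_mat,
                    annulus_area(config.cortical_inner_mm, rs),
                    annulus_inertia(config.cortical_inner_mm, rs),
                    annulus_inertia(config.cortical_inner_mm, rs),
                    ROLE_INTERIOR,
                    config.cortical_inner_mm,
                    rs,
                )
            )
        else:
            regions.append(
                Region(
                    "cancellous",
                    annulus_area(config.cortical_inner_mm, 0.0),
                    annulus_inertia(config.cortical_inner_mm, 0.0),
                    annulus_inertia(config.cortical_inner_mm, 0.0),
                    ROLE_INTERIOR,
                    config.cortical_inner_mm,
                )
            )
        stations.append(Station(float(z), tuple(regions)))

    return CrossSectionModel(
        tuple(stations),
        config.stem_tip_z_mm,
        config.working_length_mm,
        stem_material or "intact",
    )


def section_stiffness(
    regions: tuple[Region, ...] | list[Region],
    materials: dict[str, MaterialSpec],
) -> tuple[float, float, float]:
    """Modulus-weighted section rigidities (ΣEA, ΣEI_x, ΣEI_y).

    Units: N, N·mm², N·mm² (E in MPa = N/mm²).
    """
    ea = eix = eiy = 0.0
    for region in regions:
        e = resolve_material(region.material, materials).youngs_modulus_mpa
        ea += e * region.area_mm2
        eix += e * region.i_x_mm4
        eiy += e * region.i_y_mm4
    if ea <= 0 or eix <= 0 or eiy <= 0:
        raise GeometryError("section rigidities must be strictly positive")
    return ea, eix, eiy
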