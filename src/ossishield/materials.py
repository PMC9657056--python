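"""Linear-elastic material definitions.

All moduli and strengths are in MPa, densities in g/mL (= g/cm^3). The
default library mirrors a composite (Sawbone-type) femur construct:
e-glass/epoxy cortical shell, polyurethane-foam cancellous core, epoxy
canal resin, and the two stem materials under comparison (Ti6Al4V and
PEEK).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class MaterialSpec:
    """Isotropic linear-elastic material.

    Parameters
    ----------
    name
        Identifier used by cross-section regions and element tables.
    youngs_modulus_mpa
        Young's modulus E (MPa).
    poisson_ratio
        Poisson's ratio, in [0, 0.5).
    density_g_per_ml
        Mass density (g/mL), used for mass-weighted resorption sums.
    yield_strength_mpa, endurance_limit_mpa
        Optional strength data; required only for factor-of-safety
        evaluation of a stem material.
    """

    name: str
    youngs_modulus_mpa: float
    poisson_ratio: float
    density_g_per_ml: float
    yield_strength_mpa: float | None = None
    endurance_limit_mpa: float | None = None

    def __post_init__(self) -> None:
        if self.youngs_modulus_mpa <= 0:
            raise ParameterError(f"{self.name}: Young's modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ParameterError(f"{self.name}: Poisson ratio must be in [0, 0.5)")
        if self.density_g_per_ml <= 0:
            raise ParameterError(f"{self.name}: density must be > 0")
        for attr in ("yield_strength_mpa", "endurance_limit_mpa"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ParameterError(f"{self.name}: {attr} must be > 0 when given")


#: Default material library. Bone and resin values follow manufacturer
#: data for a 4th-generation composite femur; stem densities are standard
#: handbook values (they enter only stem mass bookkeeping, never the
#: cortical resorption sums).
DEFAULT_MATERIALS: dict[str, MaterialSpec] = {
    "cortical": MaterialSpec("cortical", 16_700.0, 0.30, 1.64),
    "cancellous": MaterialSpec("cancellous", 155.0, 0.30, 0.27),
    "resin": MaterialSpec("resin", 2_500.0, 0.30, 1.69),
    "cement": MaterialSpec("cement", 3_000.0, 0.30, 1.10),
    "ti6al4v": MaterialSpec("ti6al4v", 110_000.0, 0.30, 4.43),
    "peek": MaterialSpec(
        "peek",
        1_690.0,
        0.35,
        1.30,
        yield_strength_mpa=85.5,
        endurance_limit_mpa=70.0,
    ),
}


def resolve_material(name: str, materials: dict[str, MaterialSpec]) -> MaterialSpec:
    try:
        return materials[name]
    except KeyError:
        raise ConfigurationError(f"unknown material {name!r}") from None
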