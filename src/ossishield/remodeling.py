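"""Strain-adaptive bone resorption with a dead zone.

Huiskes-type site remodeling: bone density changes only when the local
strain energy per unit mass S departs from its pre-implantation value by
more than the dead-zone half-width s. Only the resorption branch
S < (1 - s) * S_intact matters for stress shielding, so the equilibrium
resorbed state is a binary per-element indicator.

With linear elasticity the strain-energy ratio reduces to the squared
ratio of principal compressive strains,

    S_implanted / S_intact = (eps_implanted / eps_intact)^2,

and an element resorbs iff that ratio falls below (1 - s). The resorbed
mass fraction of a zone is the mass-weighted average of the indicator
over its cortical elements. The typical dead-zone width from long-term
clinical densitometry is s = 0.6, making the resorption threshold an
energy ratio of 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, ParameterError
from .femur import PairedFields

#: g = g/mL * mm^3 * 1e-3
_MM3_ML = 1e-3


@dataclass(frozen=True)
class RemodelingParams:
    dead_zone_s: float = 0.6
    strain_floor: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.dead_zone_s < 1.0:
            raise ParameterError("dead zone width s must be in (0, 1)")
        if self.strain_floor < 0:
            raise ParameterError("strain floor must be >= 0")


@dataclass(frozen=True)
class ResorptionReport:
    zone: int
    resorbed_mass_fraction: float
    resorbing_mass_g: float
    total_mass_g: float
    excluded_elements: int


def strain_energy_ratio(eps_implanted: float, eps_intact: float) -> float:
    """(eps_implanted / eps_intact)^2; sign of the strains is irrelevant."""
    if eps_intact == 0:
        raise ParameterError("intact strain is zero; energy ratio undefined")
    return (eps_implanted / eps_intact) ** 2


def resorption_indicator(energy_ratio: float, params: RemodelingParams) -> int:
    """1 if the element resorbs at equilibrium, else 0.

    Resorption iff S_implanted < (1 - s) * S_intact, i.e.
    energy_ratio / (1 - s) < 1.
    """
    if energy_ratio < 0:
        raise ParameterError("energy ratio must be >= 0")
    x = energy_ratio / (1.0 - params.dead_zone_s)
    return 1 if x < 1.0 else 0


def resorbed_mass_fraction(
    paired: PairedFields, zone: int, params: RemodelingParams | None = None
) -> ResorptionReport:
    """Mass-weighted resorbed fraction of one zone's cortical bone.

    Elements whose intact compressive strain magnitude is at or below the
    strain floor (effectively unloaded, e.g. near the neutral axis) are
    excluded from both sums and counted.
    """
    if params is None:
        params = RemodelingParams()
    intact, implanted = paired.cortical()
    mask = (intact["zone"] == zone).to_numpy()
    if not mask.any():
        raise AggregationError(f"zone {zone}: no cortical elements")

    eps_int = intact.loc[mask, "comp_strain"].to_numpy()
    eps_imp = implanted.loc[mask, "comp_strain"].to_numpy()
    rho = intact.loc[mask, "density_g_per_ml"].to_numpy()
    vol = intact.loc[mask, "volume_mm3"].to_numpy()

    valid = np.abs(eps_int) > params.strain_floor
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise AggregationError(
            f"zone {zone}: all {n_excluded} elements below the strain floor"
        )

    ratio = (eps_imp[valid] / eps_int[valid]) ** 2
    resorbing = ratio < (1.0 - params.dead_zone_s)
    mass = rho[valid] * vol[valid] * _MM3_ML
    total_mass = float(mass.sum())
    resorbing_mass = float(mass[resorbing].sum())
    return ResorptionReport(
        zone, resorbing_mass / total_mass, resorbing_mass, total_mass, n_excluded
    )


def resorption_reports(
    paired: PairedFields,
    params: RemodelingParams | None = None,
    zones: tuple[int, ...] = tuple(range(1, 8)),
) -> list[ResorptionReport]:
    return [resorbed_mass_fraction(paired, z, params) for z in zones]


def total_resorbed_fraction(
    reports: list[ResorptionReport], weight: str = "mass"
) -> float:
    """Total bone loss across zones, mass-weighted by default.

    ``weight='uniform'`` averages the per-zone fractions instead (volume
    weighting coincides with mass weighting when cortical density is
    uniform, as it is here).
    """
    if not reports:
        raise AggregationError("no resorption reports")
    if weight == "mass":
        total = sum(r.total_mass_g for r in reports)
        return float(sum(r.resorbing_mass_g for r in reports) / total)
    if weight == "uniform":
        return float(np.mean([r.resorbed_mass_fraction for r in reports]))
    raise ParameterError(f"unknown weight {weight!r}")


def bone_loss_reduction(mr_reference: float, mr_candidate: float) -> float:
    """Fractional bone-loss reduction of a candidate stem vs a reference.

    Undefined (raises) when the reference zone loses no bone, as happens
    distal to the stem tip (Gruen zone 4); callers report that zone as
    not applicable.
    """
    if mr_reference <= 0:
        raise ParameterError(
            "bone loss reduction undefined: reference fraction must be > 0"
        )
    return (mr_reference - mr_candidate) / mr_reference


def reduction_frame(
    reference: list[ResorptionReport], candidate: list[ResorptionReport]
) -> pd.DataFrame:
    """Per-zone bone-loss reduction table; zones with no reference loss
    are reported as NA."""
    rows = []
    for ref, cand in zip(reference, candidate):
        if ref.zone != cand.zone:
            raise AggregationError("reference/candidate zone order mismatch")
        reduction = (
            bone_loss_reduction(ref.resorbed_mass_fraction, cand.resorbed_mass_fraction)
            if ref.resorbed_mass_fraction > 0
            else np.nan
        )
        rows.append(
            {
                "zone": ref.zone,
                "mr_reference": ref.resorbed_mass_fraction,
                "mr_candidate": cand.resorbed_mass_fraction,
                "bone_loss_reduction": reduction,
            }
        )
    return pd.DataFrame(rows)
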