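"""Rectangular (45 deg) strain-rosette reduction.

Converts raw bridge counts to microstrain, reduces three-channel rosette
readings to principal surface strains, and recovers the surface von
Mises stress under the plane-stress assumption. Gauge A defines the 0
deg axis (parallel to the femoral shaft), B sits at +45 deg and C at +90
deg, counterclockwise positive. Microstrain is the canonical internal
unit; counts are accepted only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import AggregationError, InputError, ParameterError

#: Digital counts per microstrain of the acquisition chain.
DEFAULT_SENSITIVITY_COUNTS_PER_UE = 545.4


@dataclass(frozen=True)
class SurfaceState:
    """Principal surface strains (microstrain) and principal angle.

    ``principal_angle_deg`` is the angle of the major principal direction
    from the gauge-A axis, in (-90, 90].
    """

    e1_ue: float
    e2_ue: float
    principal_angle_deg: float

    def __post_init__(self) -> None:
        if self.e1_ue < self.e2_ue:
            raise InputError("principal strains must satisfy e1 >= e2")


@dataclass(frozen=True)
class RosetteRecord:
    """One rosette reading: site, load step and the three channels (ue)."""

    site: str
    load_step_n: float
    eA_ue: float
    eB_ue: float
    eC_ue: float
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise InputError("repeats must be >= 1")


def counts_to_microstrain(
    peak_counts: float,
    zero_counts: float,
    sensitivity: float = DEFAULT_SENSITIVITY_COUNTS_PER_UE,
) -> float:
    """(peak - zero) / sensitivity, sign preserved."""
    if sensitivity <= 0:
        raise ParameterError("sensitivity must be > 0 counts/microstrain")
    return (peak_counts - zero_counts) / sensitivity


def rosette_principal(eA_ue: float, eB_ue: float, eC_ue: float) -> SurfaceState:
    """Reduce 45-deg rosette channels to principal strains.

    e1,2 = (eA+eC)/2 +- (1/sqrt2) * sqrt((eA-eB)^2 + (eB-eC)^2), with the
    principal angle from tan(2 theta) = (2 eB - eA - eC)/(eA - eC). The
    atan2 quadrant resolution picks the angle of the *major* principal
    strain.
    """
    for v in (eA_ue, eB_ue, eC_ue):
        if not math.isfinite(v):
            raise InputError("rosette channels must be finite")
    centre = 0.5 * (eA_ue + eC_ue)
    radius = math.sqrt((eA_ue - eB_ue) ** 2 + (eB_ue - eC_ue) ** 2) / math.sqrt(2.0)
    theta = 0.5 * math.degrees(
        math.atan2(2.0 * eB_ue - eA_ue - eC_ue, eA_ue - eC_ue)
    )
    return SurfaceState(centre + radius, centre - radius, theta)


def rosette_channels(state: SurfaceState) -> tuple[float, float, float]:
    """Forward transform: principal state -> (eA, eB, eC) channels.

    Normal strain at angle phi from gauge A:
    eps(phi) = c + r*cos(2*(phi - theta)), c = (e1+e2)/2, r = (e1-e2)/2.
    """
    c = 0.5 * (state.e1_ue + state.e2_ue)
    r = 0.5 * (state.e1_ue - state.e2_ue)
    theta = math.radians(state.principal_angle_deg)

    def at(phi_deg: float) -> float:
        return c + r * math.cos(2.0 * (math.radians(phi_deg) - theta))

    return at(0.0), at(45.0), at(90.0)


def surface_vm_stress(
    state: SurfaceState, youngs_modulus_mpa: float, poisson_ratio: float
) -> float:
    """Surface von Mises stress (MPa) from principal strains, plane stress.

    sigma_1 = E (e1 + nu e2)/(1 - nu^2), sigma_2 = E (e2 + nu e1)/(1 - nu^2),
    vm = sqrt(s1^2 - s1 s2 + s2^2). Strains are in microstrain.
    """
    if youngs_modulus_mpa <= 0:
        raise ParameterError("Young's modulus must be > 0")
    if not 0.0 <= poisson_ratio < 0.5:
        raise ParameterError("Poisson ratio must be in [0, 0.5)")
    e1 = state.e1_ue * 1e-6
    e2 = state.e2_ue * 1e-6
    denom = 1.0 - poisson_ratio**2
    s1 = youngs_modulus_mpa * (e1 + poisson_ratio * e2) / denom
    s2 = youngs_modulus_mpa * (e2 + poisson_ratio * e1) / denom
    return math.sqrt(s1**2 - s1 * s2 + s2**2)


def stress_ratio(implanted_vm_mpa: float, intact_vm_mpa: float) -> float:
    """Implanted/intact von Mises stress at one surface point.

    A ratio above 1 means the point carries more stress than before
    implantation, i.e. no stress shielding there.
    """
    if intact_vm_mpa <= 0:
        raise ParameterError(
            "stress ratio undefined: intact von Mises stress must be > 0"
        )
    return implanted_vm_mpa / intact_vm_mpa


def average_repeats(records: list[RosetteRecord]) -> RosetteRecord:
    """Channel-wise arithmetic mean over repeated readings of one site/step."""
    if not records:
        raise AggregationError("no records to average")
    sites = {r.site for r in records}
    steps = {r.load_step_n for r in records}
    if len(sites) > 1 or len(steps) > 1:
        raise AggregationError(
            f"cannot average across sites {sites} / load steps {steps}"
        )
    n = len(records)
    return replace(
        records[0],
        eA_ue=float(np.mean([r.eA_ue for r in records])),
        eB_ue=float(np.mean([r.eB_ue for r in records])),
        eC_ue=float(np.mean([r.eC_ue for r in records])),
        repeats=n,
    )
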