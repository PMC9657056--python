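"""Static yield and Soderberg fatigue factors of safety for the implant.

The load cycle is proportional with stress ratio R = sigma_min/sigma_max
(R = 0.1 here: 230 N trough, 2300 N peak), so the per-element minimum
stress is obtained by scaling the maximum-load field rather than
re-solving — exact under linear elasticity. Mean and alternating stress
follow as sigma_m = (sigma_max + sigma_min)/2 and
sigma_a = (sigma_max - sigma_min)/2, and the Soderberg criterion gives

    FoS = 1 / (sigma_a/sigma_N + sigma_m/sigma_y),

a conservative fatigue line joining the endurance limit sigma_N on the
alternating axis to the yield strength sigma_y on the mean axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, ParameterError
from ._util import round_half_up

__all__ = [
    "FatigueParams",
    "yield_fos",
    "cyclic_stresses",
    "soderberg_fos",
    "safety_map",
    "unsafe_fraction",
    "min_fos",
    "round_half_up",
]


@dataclass(frozen=True)
class FatigueParams:
    """Cycle and strength parameters for fatigue-safety evaluation.

    Defaults are the PEEK stem values: R = 0.1, yield 85.5 MPa,
    endurance limit 70 MPa at the qualification cycle count.
    """

    stress_ratio_r: float = 0.1
    yield_strength_mpa: float = 85.5
    endurance_limit_mpa: float = 70.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stress_ratio_r <= 1.0:
            raise ParameterError("stress ratio R must be in [0, 1]")
        if self.yield_strength_mpa <= 0 or self.endurance_limit_mpa <= 0:
            raise ParameterError("strengths must be > 0")
        if self.endurance_limit_mpa > self.yield_strength_mpa:
            raise ParameterError("endurance limit cannot exceed yield strength")


def yield_fos(sigma_max_mpa: float, yield_strength_mpa: float) -> float:
    """Static factor of safety: yield strength over peak stress.

    A non-positive peak stress carries no yield risk and reports an
    infinite FoS (excluded from minima by callers).
    """
    if yield_strength_mpa <= 0:
        raise ParameterError("yield strength must be > 0")
    if sigma_max_mpa <= 0:
        return math.inf
    return yield_strength_mpa / sigma_max_mpa


def cyclic_stresses(
    sigma_max_mpa: float, params: FatigueParams
) -> tuple[float, float]:
    """(mean, alternating) stress of the proportional cycle at one point."""
    if sigma_max_mpa < 0:
        raise ParameterError("peak stress must be >= 0")
    sigma_min = params.stress_ratio_r * sigma_max_mpa
    return 0.5 * (sigma_max_mpa + sigma_min), 0.5 * (sigma_max_mpa - sigma_min)


def soderberg_fos(
    sigma_a_mpa: float, sigma_m_mpa: float, params: FatigueParams
) -> float:
    """Soderberg fatigue factor of safety; infinite for an unstressed point."""
    if sigma_a_mpa < 0 or sigma_m_mpa < 0:
        raise ParameterError("cycle stresses must be >= 0")
    denom = (
        sigma_a_mpa / params.endurance_limit_mpa
        + sigma_m_mpa / params.yield_strength_mpa
    )
    if denom == 0:
        return math.inf
    return 1.0 / denom


def safety_map(
    field: pd.DataFrame,
    params: FatigueParams | None = None,
    stem_material: str | None = None,
) -> pd.DataFrame:
    """Per-element FoS map over the implant's maximum-load stress field.

    ``field`` is an element-field table at the cycle's peak load;
    ``stem_material`` restricts to the implant's elements when the table
    also carries bone/resin rows. Output columns include the
    Soderberg-diagram coordinates (mean_stress_mpa, alt_stress_mpa).
    """
    if params is None:
        params = FatigueParams()
    sel = field
    if stem_material is not None:
        sel = sel[sel["material"] == stem_material]
    if sel.empty:
        raise AggregationError("no stem elements in the field")

    smax = sel["vm_stress_mpa"].to_numpy(dtype=float)
    smin = params.stress_ratio_r * smax
    sm = 0.5 * (smax + smin)
    sa = 0.5 * (smax - smin)
    with np.errstate(divide="ignore"):
        fy = np.where(smax > 0, params.yield_strength_mpa / smax, np.inf)
        denom = sa / params.endurance_limit_mpa + sm / params.yield_strength_mpa
        fs = np.where(denom > 0, 1.0 / np.where(denom > 0, denom, 1.0), np.inf)

    out = pd.DataFrame(
        {
            "element_id": sel["element_id"].to_numpy(),
            "vm_stress_max_mpa": smax,
            "vm_stress_min_mpa": smin,
            "mean_stress_mpa": sm,
            "alt_stress_mpa": sa,
            "fos_yield": fy,
            "fos_soderberg": fs,
        }
    )
    if "volume_mm3" in sel.columns:
        out["volume_mm3"] = sel["volume_mm3"].to_numpy()
    return out


def unsafe_fraction(safety: pd.DataFrame, weight: str = "count") -> float:
    """Fraction of the stem with Soderberg FoS below 1.

    ``weight='count'`` is the element fraction; ``weight='volume'``
    weights by element volume.
    """
    if safety.empty:
        raise AggregationError("empty safety map")
    unsafe = (safety["fos_soderberg"] < 1.0).to_numpy()
    if weight == "count":
        return float(unsafe.mean())
    if weight == "volume":
        if "volume_mm3" not in safety.columns:
            raise ParameterError("volume weighting needs a volume_mm3 column")
        v = safety["volume_mm3"].to_numpy()
        return float(v[unsafe].sum() / v.sum())
    raise ParameterError(f"unknown weight {weight!r}")


def min_fos(safety: pd.DataFrame, column: str = "fos_soderberg") -> tuple[int, float]:
    """(element_id, value) of the smallest finite FoS; ties to lowest id."""
    finite = safety[np.isfinite(safety[column])]
    if finite.empty:
        raise AggregationError("no finite FoS values")
    ordered = finite.sort_values([column, "element_id"], kind="mergesort")
    row = ordered.iloc[0]
    return int(row["element_id"]), float(row[column])
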