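"""Stress Shielding Increase (SSI) over Gruen zones.

SSI of a region is the fractional drop in volume-averaged cortical von
Mises stress after implantation,

    SSI = (<sigma_intact> - <sigma_implanted>) / <sigma_intact>,

with the volume averages taken as sum(sigma_e * V_e)/sum(V_e) over the
zone's cortical elements, using element-centroid values as the element
integral estimate. Positive SSI means the zone is shielded (underloaded
relative to the intact femur); negative SSI means a local stress rise.
The total SSI weights zone values by their cortical volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError
from .femur import PairedFields

GRUEN_ZONES = tuple(range(1, 8))


@dataclass(frozen=True)
class ZoneReport:
    zone: int
    mean_vm_intact_mpa: float
    mean_vm_implanted_mpa: float
    ssi: float
    volume_mm3: float
    volume_fraction: float


def volume_weighted_mean(
    table: pd.DataFrame, zone: int | None = None, cortical_only: bool = True
) -> float:
    """Volume-weighted mean von Mises stress (MPa) of a selection."""
    sel = table
    if cortical_only:
        sel = sel[sel["side"] != "interior"]
    if zone is not None:
        sel = sel[sel["zone"] == zone]
    if sel.empty:
        raise AggregationError(f"no elements in selection (zone={zone})")
    v = sel["volume_mm3"].to_numpy()
    s = sel["vm_stress_mpa"].to_numpy()
    return float(np.sum(s * v) / np.sum(v))


def zone_ssi(paired: PairedFields, zone: int) -> ZoneReport:
    """SSI of one Gruen zone from an aligned intact/implanted pair.

    ``volume_fraction`` is filled relative to all seven zones by
    :func:`zone_reports`; a report built directly here carries the
    fraction of this zone alone (1.0).
    """
    intact, implanted = paired.cortical()
    mean_intact = volume_weighted_mean(intact, zone, cortical_only=False)
    mean_implanted = volume_weighted_mean(implanted, zone, cortical_only=False)
    if mean_intact == 0:
        raise AggregationError(f"zone {zone}: intact mean stress is zero; SSI undefined")
    volume = float(intact.loc[intact["zone"] == zone, "volume_mm3"].sum())
    return ZoneReport(
        zone,
        mean_intact,
        mean_implanted,
        (mean_intact - mean_implanted) / mean_intact,
        volume,
        1.0,
    )


def zone_reports(
    paired: PairedFields, zones: tuple[int, ...] = GRUEN_ZONES
) -> list[ZoneReport]:
    """Per-zone SSI with volume fractions normalized over ``zones``."""
    reports = [zone_ssi(paired, z) for z in zones]
    total_volume = sum(r.volume_mm3 for r in reports)
    return [
        ZoneReport(
            r.zone,
            r.mean_vm_intact_mpa,
            r.mean_vm_implanted_mpa,
            r.ssi,
            r.volume_mm3,
            r.volume_mm3 / total_volume,
        )
        for r in reports
    ]


def total_ssi(reports: list[ZoneReport]) -> float:
    """Volume-fraction-weighted total SSI over disjoint zones."""
    if not reports:
        raise AggregationError("no zone reports")
    zones = [r.zone for r in reports]
    if len(set(zones)) != len(zones):
        raise AggregationError(f"duplicate zones in reports: {zones}")
    total_volume = sum(r.volume_mm3 for r in reports)
    return float(sum(r.ssi * r.volume_mm3 / total_volume for r in reports))


def reports_frame(reports: list[ZoneReport]) -> pd.DataFrame:
    """Tabular form of zone reports plus a TOTAL row."""
    frame = pd.DataFrame([r.__dict__ for r in reports])
    total = {
        "zone": "TOTAL",
        "mean_vm_intact_mpa": np.nan,
        "mean_vm_implanted_mpa": np.nan,
        "ssi": total_ssi(reports),
        "volume_mm3": frame["volume_mm3"].sum(),
        "volume_fraction": frame["volume_fraction"].sum(),
    }
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)
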