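"""Synthetic femur element fields from composite-beam theory.

Generates paired intact/implanted element-field tables that emulate the
statistical and mechanical structure of a volumetric FE post-processing
export: one row per element with Gruen-zone label, centroid, volume,
density, von Mises stress and signed principal compressive strain.

Model
-----
The femur construct is loaded by a hip-joint force of magnitude P applied
at the head centre, tilted 10 deg in adduction (coronal plane) and 9 deg
in flexion (sagittal plane) relative to the shaft axis, as in ISO
7206-4 single-leg-stance testing. At each axial band the internal axial
force and bending moments are resolved, and the composite-section axial
strain field is

    eps(z, x, y) = N/sum(EA) + M_x*y/sum(EI_x) + M_y*x/sum(EI_y)

(plane sections: one strain field shared by all materials at a point).
Per-material stress is sigma_i = E_i * eps; the uniaxial magnitude
|sigma_i| stands in for the von Mises stress, since shaft surface stress
is bending-dominated and every downstream metric is a ratio.

Axis convention: z distal (0 at the lesser trochanter), x lateral->medial
positive, y posterior->anterior positive. Adduction is applied before
flexion when tilting the load vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    GeometryError,
    ParameterError,
    SamplingError,
)
from .geometry import (
    ROLE_CORTICAL,
    CrossSectionModel,
    GeometryConfig,
    build_geometry,
    section_stiffness,
)
from .materials import MaterialSpec, resolve_material

#: Canonical column order of an element-field table.
FIELD_COLUMNS = [
    "element_id",
    "zone",
    "z_mm",
    "side",
    "material",
    "volume_mm3",
    "density_g_per_ml",
    "vm_stress_mpa",
    "comp_strain",
]

#: The ten default rosette sites: (name, side, z below lesser trochanter, mm).
DEFAULT_GAUGE_SITES: tuple[tuple[str, str, float], ...] = (
    ("L1", "lateral", 0.0),
    ("L2", "lateral", 31.75),
    ("L3", "lateral", 63.5),
    ("L4", "lateral", 95.25),
    ("M1", "medial", 0.0),
    ("MX1", "medial", 16.0),
    ("M2", "medial", 31.75),
    ("MX2", "medial", 47.75),
    ("M3", "medial", 63.5),
    ("M4", "medial", 95.25),
)


@dataclass(frozen=True)
class LoadCase:
    """Hip-joint resultant force applied at the head centre.

    ``head_offset_mm`` locates the load application point relative to the
    shaft axis at the lesser trochanter (x medial, y anterior, z distal;
    a negative z is proximal to the lesser trochanter).
    """

    magnitude_n: float
    adduction_deg: float = 10.0
    flexion_deg: float = 9.0
    head_offset_mm: tuple[float, float, float] = (42.0, 0.0, -54.0)

    def __post_init__(self) -> None:
        if self.magnitude_n < 0:
            raise ParameterError("load magnitude must be >= 0")
        for name in ("adduction_deg", "flexion_deg"):
            a = getattr(self, name)
            if not 0.0 <= a <= 30.0:
                raise ParameterError(f"{name} must be in [0, 30] degrees")

    def force_vector(self) -> np.ndarray:
        """Force vector (N): shaft-aligned compression tilted by the two
        angles, adduction first, then flexion."""
        a = math.radians(self.adduction_deg)
        f = math.radians(self.flexion_deg)
        direction = np.array(
            [math.sin(a), -math.cos(a) * math.sin(f), math.cos(a) * math.cos(f)]
        )
        return self.magnitude_n * direction


def nominal_porosity(pore_size_mm: float, strut_size_mm: float) -> float:
    """Open fraction of an orthogonal rectilinear lattice period.

    One period along each axis is a pore followed by a strut, so the
    nominal (design) porosity is pore/(pore + strut).
    """
    if pore_size_mm < 0:
        raise ParameterError("pore size must be >= 0")
    if strut_size_mm <= 0:
        raise ParameterError("strut size must be > 0")
    return pore_size_mm / (pore_size_mm + strut_size_mm)


def default_band_edges(stem_tip_z_mm: float) -> list[float]:
    """Thirds of the stem length: edges of the proximal/mid/distal bands."""
    return [0.0, stem_tip_z_mm / 3.0, 2.0 * stem_tip_z_mm / 3.0, stem_tip_z_mm]


def assign_gruen_zones(
    table: pd.DataFrame,
    stem_tip_z_mm: float,
    band_edges: list[float] | None = None,
    working_length_mm: float | None = None,
) -> pd.DataFrame:
    """Label every element with its Gruen zone (1-7).

    Lateral side: zones 1 (proximal band), 2 (mid), 3 (distal stem band);
    medial side mirrors as 7, 6, 5. Everything distal to the stem tip is
    zone 4 regardless of side. Interior elements take the lateral band
    number; the label is inert because all zone metrics select cortical
    elements only.
    """
    if band_edges is None:
        band_edges = default_band_edges(stem_tip_z_mm)
    edges = np.asarray(band_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ParameterError("band edges must be strictly increasing")

    z = table["z_mm"].to_numpy()
    upper = working_length_mm if working_length_mm is not None else np.inf
    if np.any(z < 0) or np.any(z > upper):
        raise GeometryError("element z outside [0, working length]")

    band = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, len(edges) - 2)
    lateral_zone = band + 1
    medial_zone = 7 - band
    side = table["side"].to_numpy()
    zone = np.where(side == "medial", medial_zone, lateral_zone)
    zone = np.where(z >= stem_tip_z_mm, 4, zone)

    out = table.copy()
    out["zone"] = zone.astype(int)
    return out


def beam_fields(
    model: CrossSectionModel,
    load: LoadCase,
    materials: dict[str, MaterialSpec],
    mesh_density: int = 8,
    noise_sd: float = 0.02,
    seed: int | np.random.SeedSequence = 0,
    band_edges: list[float] | None = None,
) -> pd.DataFrame:
    """Generate one element-field table from the beam model.

    Each band between consecutive stations is discretized into
    ``mesh_density`` medial cortical, ``mesh_density`` lateral cortical,
    and ``mesh_density`` elements per interior region. Element stress and
    strain share one multiplicative Gaussian noise factor
    (1 + noise_sd*N(0,1)) so the table stays self-consistent; with a
    fixed seed the output is byte-identical, and fields scale exactly
    linearly with load magnitude.
    """
    if mesh_density < 1:
        raise ParameterError("mesh_density must be >= 1")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    force = load.force_vector()
    head = np.asarray(load.head_offset_mm, dtype=float)

    rows: list[tuple] = []
    eid = 0
    stations = model.stations
    for st0, st1 in zip(stations, stations[1:]):
        h = st1.z_mm - st0.z_mm
        zc = 0.5 * (st0.z_mm + st1.z_mm)
        ea, eix, eiy = section_stiffness(st0.regions, materials)

        lever = head - np.array([0.0, 0.0, zc])
        m_x = lever[1] * force[2] - lever[2] * force[1]
        m_y = lever[2] * force[0] - lever[0] * force[2]
        eps_axial = -force[2] / ea

        def strain_at(x: float, y: float) -> float:
            return eps_axial + m_x * y / eix + m_y * x / eiy

        for region in st0.regions:
            mat = resolve_material(region.material, materials)
            r_mid = 0.5 * (region.r_outer_mm + region.r_inner_mm)
            if region.role == ROLE_CORTICAL:
                vol = region.area_mm2 * h / (2.0 * mesh_density)
                phis = np.linspace(-np.pi / 3, np.pi / 3, mesh_density)
                placements = [
                    (side_name, sign * r_mid * math.cos(phi), r_mid * math.sin(phi))
                    for side_name, sign in (("medial", 1.0), ("lateral", -1.0))
                    for phi in phis
                ]
            else:
                vol = region.area_mm2 * h / mesh_density
                phis = np.linspace(0.0, 2 * np.pi, mesh_density, endpoint=False)
                placements = [
                    ("interior", r_mid * math.cos(phi), r_mid * math.sin(phi))
                    for phi in phis
                ]
            for side_name, x, y in placements:
                eid += 1
                rows.append(
                    (eid, side_name, zc, x, y, region.material, vol,
                     mat.density_g_per_ml, mat.youngs_modulus_mpa,
                     strain_at(x, y))
                )

    if not rows:
        raise GeometryError("model produced no elements")

    frame = pd.DataFrame(
        rows,
        columns=[
            "element_id", "side", "z_mm", "x_mm", "y_mm", "material",
            "volume_mm3", "density_g_per_ml", "youngs_modulus_mpa",
            "strain_raw",
        ],
    )

    noise = 1.0 + noise_sd * rng.standard_normal(len(frame))
    eps_noisy = frame["strain_raw"].to_numpy() * noise
    sigma = frame["youngs_modulus_mpa"].to_numpy() * eps_noisy

    frame["vm_stress_mpa"] = np.abs(sigma)
    frame["comp_strain"] = eps_noisy

    frame = assign_gruen_zones(
        frame, model.stem_tip_z_mm, band_edges, model.working_length_mm
    )
    return frame[FIELD_COLUMNS + ["x_mm", "y_mm"]].copy()


@dataclass(frozen=True)
class PairedFields:
    """Element-aligned intact and implanted field tables.

    Alignment contract: identical element ids, z, side, zone and volume
    row-by-row; identical density for cortical elements (interior
    material legitimately changes from cancellous to stem/resin on
    implantation).
    """

    intact: pd.DataFrame
    implanted: pd.DataFrame
    stem_material: str

    def __post_init__(self) -> None:
        a, b = self.intact, self.implanted
        if len(a) != len(b):
            raise AggregationError("paired tables differ in length")
        for col in ("element_id", "zone", "side"):
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                raise AggregationError(f"paired tables differ in column {col!r}")
        for col in ("z_mm", "volume_mm3"):
            if not np.allclose(a[col], b[col], rtol=0, atol=1e-9):
                raise AggregationError(f"paired tables differ in column {col!r}")
        cort = (a["side"] != "interior").to_numpy()
        if not np.allclose(
            a.loc[cort, "density_g_per_ml"], b.loc[cort, "density_g_per_ml"]
        ):
            raise AggregationError("cortical densities differ between the pair")

    def cortical(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        mask = (self.intact["side"] != "interior").to_numpy()
        return self.intact[mask], self.implanted[mask]


def generate_paired(
    geometry: GeometryConfig,
    materials: dict[str, MaterialSpec],
    load: LoadCase,
    stem_material: str,
    mesh_density: int = 8,
    noise_sd: float = 0.02,
    seed: int = 0,
    band_edges: list[float] | None = None,
) -> PairedFields:
    """Generate an aligned intact/implanted pair for one stem material.

    The intact and implanted tables get independent noise streams derived
    from the one seed, so distal (zone 4) stresses agree only up to
    noise, as two separate FE exports would.
    """
    ss = np.random.SeedSequence(seed)
    seed_intact, seed_implanted = ss.spawn(2)
    intact_model = build_geometry(geometry, None)
    implanted_model = build_geometry(geometry, stem_material)
    intact = beam_fields(
        intact_model, load, materials, mesh_density, noise_sd, seed_intact, band_edges
    )
    implanted = beam_fields(
        implanted_model, load, materials, mesh_density, noise_sd, seed_implanted,
        band_edges,
    )
    return PairedFields(intact, implanted, stem_material)


def sample_gauge_sites(
    table: pd.DataFrame,
    sites: tuple[tuple[str, str, float], ...] | None = None,
    poisson_ratio: float = 0.30,
    tolerance_mm: float = 25.0,
) -> pd.DataFrame:
    """Render surface strain at rosette sites as 45-deg rosette channels.

    Gauge A is parallel to the shaft axis; at a free shaft surface the
    state is uniaxial stress along the axis, so the channels are
    eps_A = eps, eps_B = (1 - nu)/2 * eps, eps_C = -nu * eps (Mohr-circle
    forward transform with zero surface shear). Channels are returned in
    microstrain. The nearest cortical element of the requested side is
    used; no element within ``tolerance_mm`` of the requested z is a
    sampling error.
    """
    if sites is None:
        sites = DEFAULT_GAUGE_SITES
    out_rows = []
    for name, side, z0 in sites:
        if side not in ("medial", "lateral"):
            raise SamplingError(f"site {name}: side must be medial or lateral")
        sel = table[table["side"] == side]
        if sel.empty:
            raise SamplingError(f"site {name}: no {side} surface elements")
        dz = (sel["z_mm"] - z0).abs()
        if dz.min() > tolerance_mm:
            raise SamplingError(
                f"site {name}: nearest surface element is {dz.min():.1f} mm away"
            )
        nearest = sel.loc[dz == dz.min()]
        # tie-break: strongest bending signal (largest |x|), then element id
        nearest = nearest.reindex(
            nearest["x_mm"].abs().sort_values(ascending=False).index
        )
        row = nearest.iloc[0]
        eps_ue = row["comp_strain"] * 1e6
        out_rows.append(
            {
                "site": name,
                "side": side,
                "z_mm": row["z_mm"],
                "element_id": int(row["element_id"]),
                "eA_ue": eps_ue,
                "eB_ue": 0.5 * (1.0 - poisson_ratio) * eps_ue,
                "eC_ue": -poisson_ratio * eps_ue,
                "vm_stress_mpa": row["vm_stress_mpa"],
            }
        )
    return pd.DataFrame(out_rows)


def model_stiffness(
    model: CrossSectionModel,
    load: LoadCase,
    materials: dict[str, MaterialSpec],
) -> float:
    """Construct stiffness (kN/mm) along the load line by virtual work.

    Unit-load method over the station bands: the displacement of the load
    point along the load direction sums axial and bending compliances,
    delta = sum h*(N*n/EA + Mx*mx/EIx + My*my/EIy).
    """
    if load.magnitude_n <= 0:
        raise ParameterError("stiffness requires a positive load magnitude")
    force = load.force_vector()
    unit = force / load.magnitude_n
    head = np.asarray(load.head_offset_mm, dtype=float)

    delta = 0.0
    for st0, st1 in zip(model.stations, model.stations[1:]):
        h = st1.z_mm - st0.z_mm
        zc = 0.5 * (st0.z_mm + st1.z_mm)
        ea, eix, eiy = section_stiffness(st0.regions, materials)
        lever = head - np.array([0.0, 0.0, zc])

        def moments(f: np.ndarray) -> tuple[float, float, float]:
            mx = lever[1] * f[2] - lever[2] * f[1]
            my = lever[2] * f[0] - lever[0] * f[2]
            return -f[2], mx, my

        n_real, mx_real, my_real = moments(force)
        n_virt, mx_virt, my_virt = moments(unit)
        delta += h * (
            n_real * n_virt / ea
            + mx_real * mx_virt / eix
            + my_real * my_virt / eiy
        )
    delta = abs(delta)
    return load.magnitude_n / delta / 1000.0  # N/mm -> kN/mm


def simulate_load_displacement(
    stiffness_kn_per_mm: float,
    loads_n: np.ndarray | list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    toe_mm: float = 0.0,
) -> pd.DataFrame:
    """Synthesize a load-displacement record for a known stiffness.

    Optional toe-in offset emulates seating of the construct before the
    linear region; multiplicative noise on displacement emulates crosshead
    measurement scatter.
    """
    if stiffness_kn_per_mm <= 0:
        raise ParameterError("stiffness must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    loads = np.asarray(loads_n, dtype=float)
    disp = toe_mm + loads / (stiffness_kn_per_mm * 1000.0)
    disp = disp * (1.0 + noise_sd * rng.standard_normal(len(loads)))
    return pd.DataFrame({"load_n": loads, "displacement_mm": disp})


def write_fields(table: pd.DataFrame, path) -> None:
    """Write an element-field table as CSV with the canonical header."""
    cols = [c for c in FIELD_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_fields(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in FIELD_COLUMNS if c not in frame.columns and c != "material"]
    if missing:
        raise ParameterError(f"field CSV missing columns: {missing}")
    return frame
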