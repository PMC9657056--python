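"""End-to-end run: generate -> validate -> SSI -> resorption -> safety.

A :class:`RunConfig` fixes geometry, materials, loads and seeds; the
pipeline is deterministic for a fixed config and embeds the config hash
in its manifest. Stage outputs are CSV; the manifest is JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gauges, remodeling, safety, shielding, validation
from .errors import ConfigurationError
from .femur import (
    LoadCase,
    PairedFields,
    beam_fields,
    build_geometry,
    generate_paired,
    model_stiffness,
    sample_gauge_sites,
    simulate_load_displacement,
    write_fields,
)
from .geometry import GeometryConfig
from .materials import DEFAULT_MATERIALS, MaterialSpec, resolve_material
from .remodeling import RemodelingParams
from .safety import FatigueParams

log = logging.getLogger("ossishield")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one analysis run.

    Loads: ``analysis_load_n`` drives the SSI/resorption/safety stages
    (ISO 7206-4 level); the validation stage steps through
    ``validation_loads_n`` (single-leg-stance protocol).
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: dict[str, MaterialSpec] = field(
        default_factory=lambda: dict(DEFAULT_MATERIALS)
    )
    reference_stem: str = "ti6al4v"
    candidate_stem: str = "peek"
    analysis_load_n: float = 2300.0
    validation_loads_n: tuple[float, ...] = tuple(range(500, 1300, 100))
    adduction_deg: float = 10.0
    flexion_deg: float = 9.0
    head_offset_mm: tuple[float, float, float] = (42.0, 0.0, -54.0)
    mesh_density: int = 8
    noise_sd: float = 0.02
    seed: int = 0
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    fatigue: FatigueParams = field(default_factory=FatigueParams)
    band_edges_mm: tuple[float, ...] | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for stem in (self.reference_stem, self.candidate_stem):
            resolve_material(stem, self.materials)
        if self.analysis_load_n <= 0:
            raise ConfigurationError("analysis load must be > 0")
        if self.seed is None:
            raise ConfigurationError("seed must be explicit")

    def load_case(self, magnitude_n: float) -> LoadCase:
        return LoadCase(
            magnitude_n, self.adduction_deg, self.flexion_deg, self.head_offset_mm
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["materials"] = {k: asdict(v) for k, v in self.materials.items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; absent blocks keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "geometry" in raw:
        kwargs["geometry"] = GeometryConfig(**raw.pop("geometry"))
    if "materials" in raw:
        mats = dict(DEFAULT_MATERIALS)
        for name, spec in raw.pop("materials").items():
            mats[name] = MaterialSpec(name=name, **spec)
        kwargs["materials"] = mats
    if "remodeling" in raw:
        kwargs["remodeling"] = RemodelingParams(**raw.pop("remodeling"))
    if "fatigue" in raw:
        kwargs["fatigue"] = FatigueParams(**raw.pop("fatigue"))
    for key in (
        "reference_stem", "candidate_stem", "analysis_load_n", "adduction_deg",
        "flexion_deg", "mesh_density", "noise_sd", "seed", "out_dir",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "validation_loads_n" in raw:
        kwargs["validation_loads_n"] = tuple(raw.pop("validation_loads_n"))
    if "head_offset_mm" in raw:
        kwargs["head_offset_mm"] = tuple(raw.pop("head_offset_mm"))
    if "band_edges_mm" in raw:
        edges = raw.pop("band_edges_mm")
        kwargs["band_edges_mm"] = tuple(edges) if edges is not None else None
    if raw:
        raise ConfigurationError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def _derive_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31))


def generate_stage(config: RunConfig, stem: str, load_n: float) -> PairedFields:
    band_edges = list(config.band_edges_mm) if config.band_edges_mm else None
    return generate_paired(
        config.geometry,
        config.materials,
        config.load_case(load_n),
        stem,
        config.mesh_density,
        config.noise_sd,
        _derive_seed(config.seed, 1),
        band_edges,
    )


def validation_stage(config: RunConfig) -> dict:
    """Gauge reduction, stress ratios, Bland-Altman, stiffness fits.

    The 'experiment' is a noisy generator run sampled at the ten rosette
    sites and reduced through the rosette chain; the 'model' is the
    noise-free run at the same sites.
    """
    cortical = resolve_material("cortical", config.materials)
    load = config.load_case(max(config.validation_loads_n))
    band_edges = list(config.band_edges_mm) if config.band_edges_mm else None

    site_vm: dict[str, dict[str, float]] = {}
    measured, predicted = [], []
    for tag, stem in (
        ("intact", None),
        (config.reference_stem, config.reference_stem),
        (config.candidate_stem, config.candidate_stem),
    ):
        model = build_geometry(config.geometry, stem)
        noisy = beam_fields(
            model, load, config.materials, config.mesh_density, config.noise_sd,
            _derive_seed(config.seed, 2 if stem is None else 3 if stem == config.reference_stem else 4),
            band_edges,
        )
        clean = beam_fields(
            model, load, config.materials, config.mesh_density, 0.0, 0, band_edges
        )
        sites_noisy = sample_gauge_sites(noisy, poisson_ratio=cortical.poisson_ratio)
        sites_clean = sample_gauge_sites(clean, poisson_ratio=cortical.poisson_ratio)
        vm_by_site = {}
        for (_, row_n), (_, row_c) in zip(
            sites_noisy.iterrows(), sites_clean.iterrows()
        ):
            state = gauges.rosette_principal(
                row_n["eA_ue"], row_n["eB_ue"], row_n["eC_ue"]
            )
            vm = gauges.surface_vm_stress(
                state, cortical.youngs_modulus_mpa, cortical.poisson_ratio
            )
            vm_by_site[row_n["site"]] = vm
            measured.append(vm)
            predicted.append(row_c["vm_stress_mpa"])
        site_vm[tag] = vm_by_site

    agreement = validation.bland_altman(measured, predicted)

    ratios = {
        stem: {
            site: gauges.stress_ratio(site_vm[stem][site], site_vm["intact"][site])
            for site in site_vm["intact"]
        }
        for stem in (config.reference_stem, config.candidate_stem)
    }

    stiffness: dict[str, float] = {}
    fits: dict[str, validation.StiffnessFit] = {}
    for tag, stem in (
        ("intact", None),
        (config.reference_stem, config.reference_stem),
        (config.candidate_stem, config.candidate_stem),
    ):
        model = build_geometry(config.geometry, stem)
        k = model_stiffness(model, load, config.materials)
        record = simulate_load_displacement(
            k,
            list(config.validation_loads_n),
            noise_sd=config.noise_sd / 4.0,
            seed=_derive_seed(config.seed, 5),
        )
        fits[tag] = validation.fit_stiffness(record)
        stiffness[tag] = fits[tag].stiffness_kn_per_mm

    return {
        "bland_altman": agreement,
        "stress_ratios": ratios,
        "stiffness_kn_per_mm": stiffness,
        "stiffness_fits": fits,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write CSV outputs plus a JSON manifest.

    Returns the manifest dict. Deterministic for a fixed config.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }

    # --- generation + shielding + resorption per stem -------------------
    ssi_block: dict = {}
    resorption_block: dict = {}
    pairs: dict[str, PairedFields] = {}
    for stem in (config.reference_stem, config.candidate_stem):
        log.info("generate: stem=%s load=%.0f N", stem, config.analysis_load_n)
        paired = generate_stage(config, stem, config.analysis_load_n)
        pairs[stem] = paired
        write_fields(paired.implanted, out / f"fields_{stem}.csv")
        manifest["outputs"][f"fields_{stem}"] = str(out / f"fields_{stem}.csv")

        reports = shielding.zone_reports(paired)
        shielding.reports_frame(reports).to_csv(out / f"ssi_{stem}.csv", index=False)
        manifest["outputs"][f"ssi_{stem}"] = str(out / f"ssi_{stem}.csv")
        ssi_block[stem] = {
            "zones": {r.zone: r.ssi for r in reports},
            "total": shielding.total_ssi(reports),
        }

        rreports = remodeling.resorption_reports(paired, config.remodeling)
        excluded = sum(r.excluded_elements for r in rreports)
        log.info("resorption: stem=%s excluded_elements=%d", stem, excluded)
        resorption_block[stem] = {
            "zones": {r.zone: r.resorbed_mass_fraction for r in rreports},
            "total": remodeling.total_resorbed_fraction(rreports),
            "excluded_elements": excluded,
        }
    write_fields(pairs[config.reference_stem].intact, out / "fields_intact.csv")
    manifest["outputs"]["fields_intact"] = str(out / "fields_intact.csv")

    ref_total = ssi_block[config.reference_stem]["total"]
    cand_total = ssi_block[config.candidate_stem]["total"]
    ssi_block["ssi_reduction"] = (
        (ref_total - cand_total) / ref_total if ref_total != 0 else float("nan")
    )
    manifest["ssi"] = ssi_block

    ref_reports = remodeling.resorption_reports(
        pairs[config.reference_stem], config.remodeling
    )
    cand_reports = remodeling.resorption_reports(
        pairs[config.candidate_stem], config.remodeling
    )
    red_frame = remodeling.reduction_frame(ref_reports, cand_reports)
    red_frame.to_csv(out / "bone_loss_reduction.csv", index=False)
    manifest["outputs"]["bone_loss_reduction"] = str(out / "bone_loss_reduction.csv")
    mr_ref = remodeling.total_resorbed_fraction(ref_reports)
    mr_cand = remodeling.total_resorbed_fraction(cand_reports)
    resorption_block["bone_loss_reduction_total"] = (
        remodeling.bone_loss_reduction(mr_ref, mr_cand) if mr_ref > 0 else float("nan")
    )
    manifest["resorption"] = resorption_block

    # --- implant safety (candidate stem) --------------------------------
    log.info("safety: stem=%s", config.candidate_stem)
    smap = safety.safety_map(
        pairs[config.candidate_stem].implanted,
        config.fatigue,
        stem_material=config.candidate_stem,
    )
    smap.to_csv(out / f"safety_{config.candidate_stem}.csv", index=False)
    manifest["outputs"]["safety"] = str(out / f"safety_{config.candidate_stem}.csv")
    _, min_yield = safety.min_fos(smap, "fos_yield")
    _, min_sod = safety.min_fos(smap, "fos_soderberg")
    manifest["safety"] = {
        "stem": config.candidate_stem,
        "min_fos_yield": min_yield,
        "min_fos_soderberg": min_sod,
        "unsafe_fraction_count": safety.unsafe_fraction(smap, "count"),
        "unsafe_fraction_volume": safety.unsafe_fraction(smap, "volume"),
    }

    # --- validation -----------------------------------------------------
    log.info("validate: loads %s N", list(config.validation_loads_n))
    val = validation_stage(config)
    manifest["validation"] = {
        "bland_altman": val["bland_altman"].__dict__,
        "stress_ratios": val["stress_ratios"],
        "stiffness_kn_per_mm": val["stiffness_kn_per_mm"],
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest
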