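"""Composite-beam femur generator: geometry, fields, zones, gauges."""

import math

import numpy as np
import pandas as pd
import pytest

from ossishield import (
    GeometryConfig,
    LoadCase,
    MaterialSpec,
    build_geometry,
    generate_paired,
    nominal_porosity,
    sample_gauge_sites,
    section_stiffness,
)
from ossishield.errors import GeometryError, ParameterError, SamplingError
from ossishield.femur import (
    DEFAULT_GAUGE_SITES,
    assign_gruen_zones,
    beam_fields,
)
from ossishield.geometry import ROLE_CORTICAL, Region


class TestGeometry:
    def test_intact_stack_has_no_stem_and_covers_working_length(self, geometry):
        model = build_geometry(geometry, None)
        zs = [s.z_mm for s in model.stations]
        assert zs[0] == 0.0 and zs[-1] == geometry.working_length_mm
        mats = {r.material for s in model.stations for r in s.regions}
        assert mats == {"cortical", "cancellous"}

    def test_implanted_stack_has_stem_only_proximal_to_tip(self, geometry):
        model = build_geometry(geometry, "ti6al4v")
        for station in model.stations:
            mats = {r.material for r in station.regions}
            if station.z_mm < geometry.stem_tip_z_mm:
                assert "ti6al4v" in mats and "resin" in mats
            else:
                assert mats == {"cortical", "cancellous"}

    def test_cortical_annulus_area_matches_closed_form(self, geometry):
        model = build_geometry(geometry, None)
        cort = next(
            r for r in model.stations[0].regions if r.role == ROLE_CORTICAL
        )
        assert cort.area_mm2 == pytest.approx(
            math.pi * (13.5**2 - 8.0**2), rel=1e-12
        )

    def test_oversized_stem_is_geometry_infeasible(self, geometry):
        bad = GeometryConfig(
            stem_radius_proximal_mm=8.5, stem_radius_tip_mm=8.5
        )
        with pytest.raises(GeometryError):
            build_geometry(bad, "ti6al4v")


class TestSectionStiffness:
    def test_identity_region(self):
        unit = Region("m", 1.0, 1.0, 1.0, ROLE_CORTICAL, 1.0)
        mats = {"m": MaterialSpec("m", 1.0, 0.0, 1.0)}
        assert section_stiffness([unit], mats) == (1.0, 1.0, 1.0)

    def test_additivity(self):
        r = Region("m", 2.0, 3.0, 4.0, ROLE_CORTICAL, 1.0)
        mats = {"m": MaterialSpec("m", 10.0, 0.0, 1.0)}
        single = section_stiffness([r], mats)
        double = section_stiffness([r, r], mats)
        assert double == tuple(2 * v for v in single)

    def test_hand_summed_composite_rigidity(self):
        a_cort = math.pi * (13.5**2 - 8.0**2)
        a_core = math.pi * 8.0**2
        cort = Region("cortical", a_cort, 1.0, 1.0, ROLE_CORTICAL, 13.5, 8.0)
        core = Region("peek", a_core, 1.0, 1.0, "interior", 8.0)
        mats = {
            "cortical": MaterialSpec("cortical", 16700.0, 0.3, 1.64),
            "peek": MaterialSpec("peek", 1690.0, 0.35, 1.3),
        }
        ea, _, _ = section_stiffness([cort, core], mats)
        assert ea == pytest.approx(16700.0 * a_cort + 1690.0 * a_core, rel=1e-12)

    def test_unknown_material_is_configuration_error(self):
        from ossishield.errors import ConfigurationError

        r = Region("mystery", 1.0, 1.0, 1.0, ROLE_CORTICAL, 1.0)
        with pytest.raises(ConfigurationError):
            section_stiffness([r], {})


class TestBeamFields:
    def test_zero_load_zeroes_all_fields(self, geometry, materials):
        model = build_geometry(geometry, None)
        table = beam_fields(model, LoadCase(0.0), materials, seed=3)
        assert (table["vm_stress_mpa"] == 0).all()
        assert (table["comp_strain"] == 0).all()

    def test_fields_scale_exactly_with_load_at_fixed_seed(self, geometry, materials):
        model = build_geometry(geometry, "peek")
        t1 = beam_fields(model, LoadCase(1200.0), materials, seed=11)
        t2 = beam_fields(model, LoadCase(2400.0), materials, seed=11)
        np.testing.assert_allclose(
            t2["vm_stress_mpa"], 2.0 * t1["vm_stress_mpa"], rtol=1e-12
        )

    def test_pure_axial_bar_recovers_p_over_a(self, geometry):
        # uniform modulus everywhere -> homogeneous bar, sigma = P/A
        e = 1000.0
        mats = {
            name: MaterialSpec(name, e, 0.3, 1.0)
            for name in ("cortical", "cancellous", "resin")
        }
        model = build_geometry(geometry, None)
        load = LoadCase(5000.0, 0.0, 0.0, (0.0, 0.0, -10.0))
        table = beam_fields(model, load, mats, noise_sd=0.0, seed=0)
        area = math.pi * 13.5**2
        np.testing.assert_allclose(
            table["vm_stress_mpa"], 5000.0 / area, rtol=1e-12
        )

    def test_negative_noise_sd_rejected(self, geometry, materials):
        model = build_geometry(geometry, None)
        with pytest.raises(ParameterError):
            beam_fields(model, LoadCase(100.0), materials, noise_sd=-0.1)

    def test_same_seed_reproduces_byte_identical_csv(self, geometry, materials):
        model = build_geometry(geometry, "ti6al4v")
        load = LoadCase(2300.0)
        a = beam_fields(model, load, materials, seed=5).to_csv(index=False)
        b = beam_fields(model, load, materials, seed=5).to_csv(index=False)
        assert a == b

    def test_stiffer_stem_lowers_proximal_cortical_stress(self, geometry, materials):
        """Load sharing: the stiffer member attracts load, so cortical
        stress ranks Ti < PEEK <= intact at every proximal element."""
        load = LoadCase(2300.0)
        tables = {
            stem: beam_fields(
                build_geometry(geometry, stem), load, materials, noise_sd=0.0
            )
            for stem in (None, "ti6al4v", "peek")
        }
        def station_means(table):
            cort = table[
                (table["side"] != "interior")
                & (table["z_mm"] < geometry.stem_tip_z_mm)
            ]
            return cort.groupby("z_mm")["vm_stress_mpa"].mean()

        vm_intact = station_means(tables[None])
        vm_ti = station_means(tables["ti6al4v"])
        vm_peek = station_means(tables["peek"])
        assert (vm_ti < vm_peek).all()
        assert (vm_peek <= vm_intact * (1 + 1e-12)).all()

    def test_zone4_identical_between_pair_without_noise(self, geometry, materials):
        paired = generate_paired(
            geometry, materials, LoadCase(2300.0), "ti6al4v", noise_sd=0.0, seed=1
        )
        zone4 = paired.intact["zone"] == 4
        np.testing.assert_allclose(
            paired.intact.loc[zone4, "vm_stress_mpa"],
            paired.implanted.loc[zone4, "vm_stress_mpa"],
            rtol=1e-12,
        )


class TestGruenZones:
    @pytest.mark.parametrize(
        "side,z,expected",
        [
            ("lateral", 10.0, 1),
            ("lateral", 60.0, 2),
            ("lateral", 120.0, 3),
            ("medial", 10.0, 7),
            ("medial", 60.0, 6),
            ("medial", 120.0, 5),
            ("medial", 200.0, 4),
            ("lateral", 200.0, 4),
        ],
    )
    def test_band_and_side_mapping(self, side, z, expected):
        table = pd.DataFrame(
            {"z_mm": [z], "side": [side], "zone": [0]}
        )
        out = assign_gruen_zones(table, stem_tip_z_mm=150.0)
        assert out["zone"].iloc[0] == expected

    def test_element_outside_working_length_rejected(self):
        table = pd.DataFrame({"z_mm": [400.0], "side": ["medial"], "zone": [0]})
        with pytest.raises(GeometryError):
            assign_gruen_zones(table, 150.0, working_length_mm=328.0)


class TestGaugeSites:
    def test_default_sites_give_ten_named_records(self, geometry, materials):
        model = build_geometry(geometry, None)
        table = beam_fields(model, LoadCase(1200.0), materials, seed=2)
        sites = sample_gauge_sites(table)
        assert len(sites) == 10
        assert set(sites["site"]) == {name for name, _, _ in DEFAULT_GAUGE_SITES}

    def test_zero_field_gives_zero_channels(self, geometry, materials):
        model = build_geometry(geometry, None)
        table = beam_fields(model, LoadCase(0.0), materials, seed=2)
        sites = sample_gauge_sites(table)
        assert (sites[["eA_ue", "eB_ue", "eC_ue"]] == 0).all().all()

    def test_uniaxial_channels_with_zero_poisson(self, geometry, materials):
        model = build_geometry(geometry, None)
        table = beam_fields(model, LoadCase(1200.0), materials, noise_sd=0.0)
        sites = sample_gauge_sites(table, poisson_ratio=0.0)
        np.testing.assert_allclose(sites["eB_ue"], sites["eA_ue"] / 2.0, rtol=1e-12)
        assert (sites["eC_ue"] == 0).all()

    def test_site_beyond_tolerance_is_sampling_error(self, geometry, materials):
        model = build_geometry(geometry, None)
        table = beam_fields(model, LoadCase(1200.0), materials, seed=2)
        with pytest.raises(SamplingError):
            sample_gauge_sites(
                table, sites=(("X", "medial", 1000.0),), tolerance_mm=5.0
            )


class TestNominalPorosity:
    def test_equal_pore_and_strut_is_half_open(self):
        assert nominal_porosity(0.4, 0.4) == pytest.approx(0.5)

    def test_no_pores_is_fully_dense(self):
        assert nominal_porosity(0.0, 0.4) == 0.0

    def test_three_to_one_ratio(self):
        assert nominal_porosity(0.6, 0.2) == pytest.approx(0.75)

    def test_nonpositive_strut_rejected(self):
        with pytest.raises(ParameterError):
            nominal_porosity(0.4, 0.0)
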