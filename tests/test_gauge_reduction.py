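"""Rosette reduction, plane-stress recovery and repeat averaging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ossishield.errors import AggregationError, ParameterError
from ossishield.gauges import (
    RosetteRecord,
    SurfaceState,
    average_repeats,
    counts_to_microstrain,
    rosette_channels,
    rosette_principal,
    stress_ratio,
    surface_vm_stress,
)

finite_ue = st.floats(-5000.0, 5000.0, allow_nan=False)


class TestCountsConversion:
    def test_peak_equals_zero_gives_zero(self):
        assert counts_to_microstrain(1234, 1234) == 0.0

    def test_printed_sensitivity_arithmetic(self):
        assert counts_to_microstrain(5454.0 + 100.0, 100.0, 545.4) == pytest.approx(10.0)

    def test_sign_preserved(self):
        assert counts_to_microstrain(0.0, 5454.0, 545.4) == pytest.approx(-10.0)

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(ParameterError):
            counts_to_microstrain(1, 0, 0.0)


class TestRosettePrincipal:
    def test_zero_channels(self):
        state = rosette_principal(0.0, 0.0, 0.0)
        assert state.e1_ue == state.e2_ue == 0.0

    def test_equibiaxial_has_zero_mohr_radius(self):
        state = rosette_principal(250.0, 250.0, 250.0)
        assert state.e1_ue == pytest.approx(250.0)
        assert state.e2_ue == pytest.approx(250.0)

    def test_pure_shearless_axial_case(self):
        state = rosette_principal(100.0, 50.0, 0.0)
        assert state.e1_ue == pytest.approx(100.0)
        assert state.e2_ue == pytest.approx(0.0, abs=1e-12)
        assert state.principal_angle_deg == pytest.approx(0.0)

    def test_against_brute_force_mohr_rotation(self):
        """Oracle: extremize the normal strain over a dense angle grid."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            eA, eB, eC = rng.uniform(-1000, 1000, 3)
            state = rosette_principal(eA, eB, eC)
            c = 0.5 * (eA + eC)
            gamma = 2.0 * eB - eA - eC  # engineering shear in gauge frame
            thetas = np.linspace(0, np.pi, 20001)
            normal = (
                c
                + 0.5 * (eA - eC) * np.cos(2 * thetas)
                + 0.5 * gamma * np.sin(2 * thetas)
            )
            assert state.e1_ue == pytest.approx(normal.max(), abs=1e-3)
            assert state.e2_ue == pytest.approx(normal.min(), abs=1e-3)

    @settings(derandomize=True, max_examples=200)
    @given(e1=finite_ue, e2=finite_ue, theta=st.floats(-89.0, 89.0))
    def test_forward_backward_round_trip(self, e1, e2, theta):
        if e1 < e2:
            e1, e2 = e2, e1
        channels = rosette_channels(SurfaceState(e1, e2, theta))
        state = rosette_principal(*channels)
        assert state.e1_ue == pytest.approx(e1, abs=1e-9 * max(1, abs(e1)) + 1e-6)
        assert state.e2_ue == pytest.approx(e2, abs=1e-9 * max(1, abs(e2)) + 1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(eA=finite_ue, eB=finite_ue, eC=finite_ue)
    def test_first_strain_invariant(self, eA, eB, eC):
        state = rosette_principal(eA, eB, eC)
        assert state.e1_ue + state.e2_ue == pytest.approx(
            eA + eC, abs=1e-6 * max(1.0, abs(eA + eC))
        )

    @settings(derandomize=True, max_examples=100)
    @given(eA=finite_ue, eB=finite_ue, eC=finite_ue)
    def test_channel_exchange_reflects_angle(self, eA, eB, eC):
        fwd = rosette_principal(eA, eB, eC)
        rev = rosette_principal(eC, eB, eA)
        assert rev.e1_ue == pytest.approx(fwd.e1_ue, abs=1e-6)
        assert rev.e2_ue == pytest.approx(fwd.e2_ue, abs=1e-6)


class TestSurfaceVmStress:
    def test_zero_state(self):
        assert surface_vm_stress(SurfaceState(0, 0, 0), 16700.0, 0.3) == 0.0

    def test_uniaxial_stress_limit(self):
        # e2 = -nu*e1 is a uniaxial stress state: vm = E*e1 exactly
        nu, e1 = 0.3, 400.0
        vm = surface_vm_stress(SurfaceState(e1, -nu * e1, 0.0), 16700.0, nu)
        assert vm == pytest.approx(16700.0 * e1 * 1e-6, rel=1e-12)

    def test_hand_evaluated_plane_stress(self):
        vm = surface_vm_stress(SurfaceState(100.0, -30.0, 0.0), 16700.0, 0.3)
        assert vm == pytest.approx(1.670, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(e1=finite_ue, e2=finite_ue, k=st.floats(0.1, 10.0))
    def test_homogeneous_of_degree_one(self, e1, e2, k):
        if e1 < e2:
            e1, e2 = e2, e1
        base = surface_vm_stress(SurfaceState(e1, e2, 0.0), 16700.0, 0.3)
        scaled = surface_vm_stress(SurfaceState(k * e1, k * e2, 0.0), 16700.0, 0.3)
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-9)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ParameterError):
            surface_vm_stress(SurfaceState(1, 0, 0), 16700.0, 0.5)


class TestStressRatio:
    def test_equal_stresses(self):
        assert stress_ratio(2.5, 2.5) == 1.0

    def test_fully_shielded_point(self):
        assert stress_ratio(0.0, 2.5) == 0.0

    def test_ratio_above_one_means_no_shielding(self):
        assert stress_ratio(1.4, 1.0) == pytest.approx(1.4)

    def test_zero_intact_stress_is_undefined(self):
        with pytest.raises(ParameterError):
            stress_ratio(1.0, 0.0)


class TestAverageRepeats:
    def test_single_record_is_identity(self):
        rec = RosetteRecord("L1", 1200.0, 10.0, 5.0, 0.0)
        out = average_repeats([rec])
        assert out == rec

    def test_five_identical_records(self):
        rec = RosetteRecord("L1", 1200.0, 10.0, 5.0, 0.0)
        out = average_repeats([rec] * 5)
        assert out.eA_ue == rec.eA_ue and out.repeats == 5

    def test_channel_mean(self):
        records = [
            RosetteRecord("M1", 500.0, float(a), 0.0, 0.0) for a in (1, 2, 3, 4, 5)
        ]
        assert average_repeats(records).eA_ue == pytest.approx(3.0)

    def test_mixed_sites_rejected(self):
        with pytest.raises(AggregationError):
            average_repeats(
                [
                    RosetteRecord("M1", 500.0, 1.0, 0.0, 0.0),
                    RosetteRecord("L1", 500.0, 1.0, 0.0, 0.0),
                ]
            )
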