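"""Field-driven transport: displacements, dosimetry, drift–diffusion splitting."""

import numpy as np
import pytest

from gelget import (
    ConcentrationProfile,
    ConfigurationError,
    DosimetryInputs,
    GelGeometry,
    GelMedium,
    PlasmidSpec,
    PulseProtocol,
    PulseSegment,
    advect_diffuse_pulse,
    available_dna,
    coulomb_dosage,
    dosimetry_report,
    electrophoretic_displacement,
    electrophoretic_force,
    electrophoretic_mobility,
    electrophoretic_velocity,
    fd_diffusion_solve,
    joule_heating,
    pee_ratio,
    protocol_displacement,
    pulse_energy_factor,
    standard_grid,
    table1_protocols,
    table2_protocols,
)

# (t_p, mu 0.35% gel, L_E 0.35%, mu 3% gel, L_E 3%, U²tE at 160 V)
SCHEDULES = [
    (200e-6, 0.2e-8, 0.256, 0.03e-8, 0.0384, 40.96),
    (1e-3, 1.0e-8, 6.4, 0.03e-8, 0.192, 204.8),
    (5e-3, 2.4e-8, 76.8, 0.03e-8, 0.96, 1024.0),
    (10e-3, 2.8e-8, 179.2, 0.03e-8, 1.92, 2048.0),
]


class TestDisplacementAndEnergy:
    @pytest.mark.parametrize("t_p, mu35, le35, mu3, le3, u2te", SCHEDULES)
    def test_published_displacements_both_gels(self, t_p, mu35, le35, mu3, le3, u2te):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=t_p, N=8, U_V=160.0)
        assert electrophoretic_displacement(seg, mu35) == pytest.approx(le35, rel=1e-12)
        assert electrophoretic_displacement(seg, mu3) == pytest.approx(le3, rel=1e-12)

    @pytest.mark.parametrize("t_p, mu35, le35, mu3, le3, u2te", SCHEDULES)
    def test_published_energy_factors(self, t_p, mu35, le35, mu3, le3, u2te):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=t_p, N=8, U_V=160.0)
        assert pulse_energy_factor(seg) == pytest.approx(u2te, rel=1e-12)

    def test_energy_factor_requires_explicit_voltage(self):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=5e-3, N=8)
        with pytest.raises(ConfigurationError):
            pulse_energy_factor(seg)

    def test_displacement_linear_in_each_factor(self):
        base = PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=4)
        mu = 1e-8
        L = electrophoretic_displacement(base, mu)
        assert electrophoretic_displacement(base, 2 * mu) == pytest.approx(2 * L)
        double_E = PulseSegment(E_kV_cm=1.6, t_p_s=1e-3, N=4)
        assert electrophoretic_displacement(double_E, mu) == pytest.approx(2 * L)
        double_N = PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=8)
        assert electrophoretic_displacement(double_N, mu) == pytest.approx(2 * L)

    def test_protocol_displacement_additive_over_segments(self, medium):
        protos = table1_protocols()
        mu_of = lambda seg: electrophoretic_mobility(medium, pulse_duration_s=seg.t_p_s)
        hv, _ = protocol_displacement(protos["HV2"], mu_of)
        lv, _ = protocol_displacement(protos["LV2"], mu_of)
        combo, _ = protocol_displacement(protos["HV2+LV2"], mu_of)
        assert combo == pytest.approx(hv + lv, rel=1e-12)

    def test_obp_protocol_has_zero_net_depth_displacement(self, medium):
        protos = table1_protocols()
        mu_of = lambda seg: electrophoretic_mobility(medium, pulse_duration_s=seg.t_p_s)
        net, per_axis = protocol_displacement(protos["OBP"], mu_of)
        assert net == 0.0
        assert len(per_axis) == 1 and next(iter(per_axis.values())) > 0


class TestForceVelocityAndCounts:
    def test_force_on_default_plasmid(self, plasmid):
        # 310.2 e * 0.8 kV/cm
        assert electrophoretic_force(plasmid, 0.8) == pytest.approx(3.976e-12, rel=1e-3)
        assert electrophoretic_force(plasmid, 0.0) == 0.0

    def test_velocity_product_and_linearity(self):
        assert electrophoretic_velocity(2.4e-8, 0.8) == pytest.approx(1.92e-3, rel=1e-12)
        assert electrophoretic_velocity(4.8e-8, 0.8) == pytest.approx(3.84e-3, rel=1e-12)
        assert electrophoretic_velocity(2.4e-8, 0.0) == 0.0

    def test_available_dna_reference_count(self, plasmid):
        # hand unit chain: 90 µg/ml of 4.7 kbp (MW 3.055e6 g/mol) is
        # 1.7741e13 molecules/cm³; swept volume 76.8 µm x 100 µm² = 7.68e-9 cm³
        n = available_dna(
            c_ug_ml=90.0, mu_m2_vs=2.4e-8, E_kV_cm=0.8, t_E_s=0.04,
            S_cm2=100e-8, plasmid=plasmid,
        )
        assert n == pytest.approx(1.3625e5, rel=1e-3)

    def test_available_dna_zero_concentration_and_linearity(self, plasmid):
        args = dict(mu_m2_vs=2.4e-8, E_kV_cm=0.8, t_E_s=0.04, S_cm2=1e-6, plasmid=plasmid)
        assert available_dna(0.0, **args) == 0.0
        one = available_dna(10.0, **args)
        assert available_dna(20.0, **args) == pytest.approx(2 * one)


class TestPeeRatio:
    def test_dense_gel_dominance_thresholds(self):
        # dense-gel parameters: drift beats diffusion by >1e4 over a cell
        # diameter and >1e6 over a millimetre
        assert pee_ratio(0.03e-8, 0.8, 10.0, 0.01e-8) == pytest.approx(2.4e4, rel=1e-12)
        assert pee_ratio(0.03e-8, 0.8, 1000.0, 0.01e-8) == pytest.approx(2.4e6, rel=1e-12)

    def test_zero_distance_and_linearity(self):
        assert pee_ratio(1e-8, 0.8, 0.0, 3e-8) == 0.0
        assert pee_ratio(1e-8, 0.8, 20.0, 3e-8) == pytest.approx(
            2 * pee_ratio(1e-8, 0.8, 10.0, 3e-8)
        )

    def test_dimensionless_under_unit_rescaling(self):
        # the same physical quantities expressed via rescaled inputs must give
        # the same ratio: halve the field, double the mobility, etc.
        ref = pee_ratio(2.4e-8, 0.8, 10.0, 3e-8)
        assert pee_ratio(4.8e-8, 0.4, 10.0, 3e-8) == pytest.approx(ref, rel=1e-12)
        assert pee_ratio(2.4e-8, 0.8, 20.0, 6e-8) == pytest.approx(ref, rel=1e-12)

    def test_zero_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            pee_ratio(1e-8, 0.8, 10.0, 0.0)


class TestThermalAndCoulombDosimetry:
    def test_joule_heat_reference(self):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=5e-3, N=8)
        inputs = DosimetryInputs(current_a=1.0, resistance_ohm=100.0, sample_mass_kg=0.2e-3)
        q, dT = joule_heating(inputs, seg)
        assert q == pytest.approx(4.0, rel=1e-12)
        assert dT == pytest.approx(4.0 / (0.2e-3 * 4186.0), rel=1e-12)

    def test_joule_heat_linear_in_pulse_length(self):
        inputs = DosimetryInputs(current_a=1.0, resistance_ohm=50.0, sample_mass_kg=1e-3)
        q1, _ = joule_heating(inputs, PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=1))
        q2, _ = joule_heating(inputs, PulseSegment(E_kV_cm=0.8, t_p_s=2e-3, N=1))
        assert q2 == pytest.approx(2 * q1)

    def test_missing_thermal_inputs_rejected(self):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=5e-3, N=8)
        with pytest.raises(ValueError):
            joule_heating(DosimetryInputs(current_a=1.0), seg)

    def test_coulomb_dosage(self):
        seg = PulseSegment(E_kV_cm=0.8, t_p_s=5e-3, N=8)
        assert coulomb_dosage(DosimetryInputs(current_a=0.5), seg) == pytest.approx(0.02)
        assert coulomb_dosage(DosimetryInputs(current_a=1.0), seg) == pytest.approx(0.04)


class TestAdvectDiffusePulse:
    @pytest.mark.parametrize("t_p, mu35, le35, mu3, le3, u2te", SCHEDULES)
    def test_pure_drift_shifts_centroid_by_L_E(self, gaussian_profile, t_p, mu35,
                                               le35, mu3, le3, u2te):
        proto = PulseProtocol(
            (PulseSegment(E_kV_cm=0.8, t_p_s=t_p, N=8),), name="train"
        )
        res = advect_diffuse_pulse(gaussian_profile, proto, mu35, 0.0)
        z = gaussian_profile.z_um
        before = np.sum(gaussian_profile.c_ug_ml * z) / np.sum(gaussian_profile.c_ug_ml)
        after = np.sum(res.profile.c_ug_ml * z) / np.sum(res.profile.c_ug_ml)
        assert abs((after - before) - le35) < 2.0  # within one grid cell

    def test_zero_field_reduces_to_pure_diffusion(self, gaussian_profile, geometry):
        proto = PulseProtocol(
            (PulseSegment(E_kV_cm=0.0, t_p_s=5e-3, N=8),), name="nofield"
        )
        res = advect_diffuse_pulse(gaussian_profile, proto, 2.4e-8, 3e-8, geometry)
        ref = fd_diffusion_solve(
            gaussian_profile, 3e-8, proto.total_duration_s, geometry, "noflux"
        )
        # the two paths partition the Crank-Nicolson steps differently
        # (per-pulse intervals vs uniform dt), so agreement is to the
        # scheme's O(dt^2) consistency, not bitwise
        np.testing.assert_allclose(res.profile.c_ug_ml, ref.c_ug_ml, rtol=1e-5, atol=1e-6)
        assert res.exited_mass_ug == 0.0

    def test_mass_plus_exited_mass_conserved(self, geometry):
        # a long, strong train pushes a near-bottom bump out of the gel
        z = standard_grid(geometry)
        c = 30.0 * np.exp(-0.5 * ((z - 800.0) / 30.0) ** 2)
        prof = ConcentrationProfile(z, c)
        proto = PulseProtocol(
            (PulseSegment(E_kV_cm=0.8, t_p_s=10e-3, N=8),), name="strong"
        )
        res = advect_diffuse_pulse(prof, proto, 2.8e-8, 0.0, geometry)
        dz = prof.dz_um
        to_ug = dz * 1e-4 * geometry.surface_area_cm2
        m0 = np.sum(prof.c_ug_ml) * to_ug
        m1 = np.sum(res.profile.c_ug_ml) * to_ug
        assert res.exited_mass_ug > 0
        assert abs((m1 + res.exited_mass_ug) - m0) / m0 < 1e-6

    def test_obp_segment_does_not_drift(self, gaussian_profile):
        proto = PulseProtocol(
            (PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=8, polarity="OBP"),), name="OBP"
        )
        res = advect_diffuse_pulse(gaussian_profile, proto, 1e-8, 0.0)
        np.testing.assert_array_equal(res.profile.c_ug_ml, gaussian_profile.c_ug_ml)
        assert list(res.per_axis_displacement.values()) == [
            pytest.approx(1e-8 * 0.8e5 * 8 * 1e-3 * 1e6 / 2)
        ]


class TestProtocolFactoriesAndReport:
    def test_table1_protocol_parameters(self):
        protos = table1_protocols()
        hv2 = protos["HV2"].segments[0]
        assert (hv2.N, hv2.t_p_s, hv2.E_kV_cm) == (8, 200e-6, 0.8)
        lv2 = protos["LV2"].segments[0]
        assert (lv2.N, lv2.t_p_s, lv2.E_kV_cm) == (1, 100e-3, 0.150)
        assert protos["HV2+LV2"].inter_segment_lag_s == 0.02

    def test_dosimetry_report_reproduces_published_columns(self, medium):
        table = dosimetry_report(table2_protocols(), medium)
        np.testing.assert_allclose(
            table["L_E_um"].to_numpy(), [0.256, 6.4, 76.8, 179.2], rtol=1e-12
        )
        np.testing.assert_allclose(
            table["U2tE_V2s"].to_numpy(), [40.96, 204.8, 1024.0, 2048.0], rtol=1e-12
        )

    def test_invalid_segments_rejected(self):
        with pytest.raises(ValueError):
            PulseSegment(E_kV_cm=0.8, t_p_s=0.0, N=8)
        with pytest.raises(ValueError):
            PulseSegment(E_kV_cm=0.8, t_p_s=1e-3, N=0)
        with pytest.raises(ValueError):
            PulseProtocol(())
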