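"""Bead-shell hydrodynamics against analytic and double-sum oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest

from g4shape.hydrocalc import (HydroParams, WATER_20C_ETA_POISE,
                               asymmetry_ratio, bead_cluster_rigid_body,
                               calibrate_aer, ensemble_average,
                               equivalent_sphere_rho0, frictional_ratio,
                               kirkwood_dt, max_sphere_s,
                               rotational_relaxation, s20w_standardize,
                               sedimentation_coefficient, shell_model)

KB = 1.380649e-16


class TestStokesOracles:
    def test_single_bead_friction_exact(self, water_params):
        rb = bead_cluster_rigid_body(np.zeros((1, 3)), 5.0,
                                     water_params.eta, water_params.T)
        f_expected = 6 * math.pi * water_params.eta * 5.0e-8
        assert rb["f_trans"] == pytest.approx(f_expected, rel=1e-9)

    def test_sphere_translation_within_1pct(self, water_params, sphere_atoms):
        R = 19.4
        res = shell_model(sphere_atoms(R, water_params.aer), water_params,
                          sigma_list=(3.0, 2.4, 1.9), mass_da=21632.8)
        Dt_stokes = KB * water_params.T / (6 * math.pi * water_params.eta
                                           * R * 1e-8)
        assert res.Dt == pytest.approx(Dt_stokes, rel=0.01)

    def test_sphere_rotation_within_2pct(self, water_params, sphere_atoms):
        R = 19.4
        res = shell_model(sphere_atoms(R, water_params.aer), water_params,
                          sigma_list=(3.0, 2.4, 1.9), mass_da=21632.8)
        Dr_stokes = KB * water_params.T / (8 * math.pi * water_params.eta
                                           * (R * 1e-8) ** 3)
        assert np.mean(res.Dr) == pytest.approx(Dr_stokes, rel=0.02)

    def test_sphere_rho_matches_debye_volume(self, water_params, sphere_atoms):
        # rho = 3 eta V_hydrated / RT for the sphere the shell encloses
        R = 19.4
        res = shell_model(sphere_atoms(R, water_params.aer), water_params,
                          sigma_list=(3.0, 2.4, 1.9), mass_da=21632.8)
        V = (4.0 / 3.0) * math.pi * (R * 1e-8) ** 3
        rho_expected = 3 * water_params.eta * V / (KB * water_params.T) * 1e9
        assert res.rho_rot_ns == pytest.approx(rho_expected, rel=0.02)


class TestKirkwoodCrossCheck:
    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_double_sum_vs_supermatrix(self, n, water_params):
        rng = np.random.default_rng(n)
        # non-overlapping random cluster of unit beads
        pos = []
        while len(pos) < n:
            cand = rng.uniform(-6, 6, size=3)
            if all(np.linalg.norm(cand - p) > 2.2 for p in pos):
                pos.append(cand)
        pos = np.array(pos)
        rb = bead_cluster_rigid_body(pos, 1.0, water_params.eta,
                                     water_params.T)
        dk = kirkwood_dt(pos, 1.0, water_params.eta, water_params.T)
        assert dk == pytest.approx(rb["Dt"], rel=0.05)


class TestScalarRelations:
    def test_svedberg_proportionality(self, water_params):
        s1 = sedimentation_coefficient(3.0e-8, 21632.8, water_params)
        s2 = sedimentation_coefficient(6.0e-8, 21632.8, water_params)
        assert s1 == pytest.approx(2 * s2)

    def test_neutral_buoyancy_rejected(self):
        params = HydroParams(vbar=1.1)
        with pytest.raises(ValueError):
            sedimentation_coefficient(3.0e-8, 21632.8, params)

    def test_max_sphere_s_closed_form(self, water_params):
        # hydrated sphere of the 68-mer: R = 19.4 A, s ~ 4.4 S
        assert max_sphere_s(21632.8, water_params) == pytest.approx(4.42,
                                                                    abs=0.05)

    def test_standardization_identity_and_scaling(self, water_params):
        assert s20w_standardize(4.05, WATER_20C_ETA_POISE, 0.99823,
                                water_params) == pytest.approx(4.05)
        assert s20w_standardize(2.0, 2 * WATER_20C_ETA_POISE, 0.99823,
                                water_params) == pytest.approx(4.0)

    def test_standardization_round_trip(self, water_params):
        s = s20w_standardize(3.7, 0.0193, 1.08, water_params)
        back = s * (WATER_20C_ETA_POISE / 0.0193) * (
            (1 - 0.55 * 1.08) / (1 - 0.55 * 0.99823))
        assert back == pytest.approx(3.7, abs=1e-12)

    def test_frictional_ratio_conventions(self, water_params):
        # observed s with anhydrous reference sphere: f/f0 ~ 1.27
        anh = frictional_ratio(4.05, 21632.8, water_params, "anhydrous")
        hyd = frictional_ratio(4.05, 21632.8, water_params, "hydrated")
        assert anh == pytest.approx(1.27, abs=0.02)
        assert hyd == pytest.approx(1.09, abs=0.02)
        assert anh > hyd

    def test_frictional_ratio_decreases_with_s(self, water_params):
        vals = [frictional_ratio(s, 21632.8, water_params)
                for s in (3.0, 3.5, 4.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_sphere_self_consistency(self, water_params):
        s_sphere = max_sphere_s(21632.8, water_params)
        assert frictional_ratio(s_sphere, 21632.8, water_params,
                                "hydrated") == pytest.approx(1.0, abs=1e-9)


class TestEquivalentSphere:
    def test_htert_rho0(self, water_params):
        # 3 eta M vbar / RT for the 68-mer at water/20 C: 14.6 ns
        assert equivalent_sphere_rho0(21632.8, water_params) == pytest.approx(
            14.6, rel=0.01)

    def test_linear_scaling_in_mass(self, water_params):
        r68 = equivalent_sphere_rho0(21632.8, water_params)
        r22 = equivalent_sphere_rho0(6991.6, water_params)
        assert r22 == pytest.approx(r68 * 6991.6 / 21632.8, rel=1e-9)
        assert equivalent_sphere_rho0(0.0, water_params) == 0.0

    def test_asymmetry_ratio(self, water_params):
        assert asymmetry_ratio(30.9, 14.6) == pytest.approx(2.1, abs=0.02)
        assert asymmetry_ratio(14.6, 14.6) == 1.0


class TestRotationalRelaxation:
    def test_isotropic_closed_form(self):
        D = 1.0e7
        assert rotational_relaxation((D, D, D)) == pytest.approx(
            1e9 / (2 * D))

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            rotational_relaxation((1e7, -1e5, 2e7))


class TestViscosityScaling:
    def test_transport_scales_with_eta(self, water_params, sphere_atoms):
        atoms = sphere_atoms(14.0, water_params.aer)
        thick = replace(water_params, eta=2 * water_params.eta)
        a = shell_model(atoms, water_params, sigma_list=(2.5, 2.0, 1.6),
                        mass_da=10000.0)
        b = shell_model(atoms, thick, sigma_list=(2.5, 2.0, 1.6),
                        mass_da=10000.0)
        assert b.s == pytest.approx(a.s / 2, rel=1e-6)
        assert b.rho_rot_ns == pytest.approx(2 * a.rho_rot_ns, rel=1e-6)


class TestEnsembleSummary:
    def test_single_snapshot_zero_range(self, water_params, sphere_atoms):
        res = shell_model(sphere_atoms(14.0, water_params.aer), water_params,
                          sigma_list=(2.5, 2.0, 1.6), mass_da=10000.0)
        summ = ensemble_average([res])
        assert summ["s20w"]["range"] == 0.0
        assert summ["s20w"]["mean"] == res.s20w

    def test_permutation_invariance(self, water_params, sphere_atoms):
        res = [shell_model(sphere_atoms(R, water_params.aer), water_params,
                           sigma_list=(2.5, 2.0, 1.6), mass_da=10000.0)
               for R in (13.0, 14.0, 15.0)]
        a = ensemble_average(res)
        b = ensemble_average(res[::-1])
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])


def test_calibrate_aer_recovers_target(water_params, sphere_atoms):
    # tune AER so the sphere model reproduces a known target s20w
    atoms = sphere_atoms(16.0, 2.8)
    target = shell_model(atoms, replace(water_params, aer=3.1),
                         sigma_list=(2.5, 2.0, 1.6), mass_da=15000.0).s20w
    aer = calibrate_aer(atoms, 15000.0, target, water_params,
                        bounds=(2.2, 3.8), sigma_list=(2.5, 2.0, 1.6))
    assert aer == pytest.approx(3.1, abs=0.05)
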