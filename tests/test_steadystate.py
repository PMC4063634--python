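"""Analytic steady-state distributions and their internal consistency."""

import numpy as np
import pytest
from dataclasses import replace

import runtumble as rt
from runtumble.params import PHParams, ThermoParams
from runtumble.environments import Environment1D
from runtumble import steadystate as ss
from scipy.integrate import trapezoid

RP = rt.ReceptorParams()
MP = rt.MotorParams()


class TestSensitivity:
    def test_factors_and_scaling(self):
        s = ss.sensitivity_chi(RP, MP)
        assert s.chi == pytest.approx(s.receptor_gain * s.motor_gain * s.damping)
        # doubling N doubles chi; doubling H doubles the motor gain exactly
        # at the half-max operating point (bias 1/2 there is H-independent)
        s2 = ss.sensitivity_chi(replace(RP, N=2 * RP.N), MP)
        assert s2.chi == pytest.approx(2 * s.chi, rel=1e-12)
        sH = ss.sensitivity_chi(RP, replace(MP, H=2 * MP.H))
        assert sH.motor_gain == pytest.approx(2 * s.motor_gain, rel=1e-12)

    def test_rotational_diffusion_damps_chi(self):
        chis = [ss.sensitivity_chi(RP, replace(MP, D_r=d)).chi
                for d in (0.0, 0.062, 1.0, 100.0)]
        assert np.all(np.diff(chis) < 0)
        assert chis[-1] < 0.05 * chis[0]

    def test_receptor_gain_vanishes_at_high_activity(self):
        g = [ss.sensitivity_chi(replace(RP, a0_ref=a), MP).receptor_gain
             for a in (0.5, 0.9, 0.99)]
        assert g[0] > g[1] > g[2]


class TestGeneralSolver:
    def test_uniform_environment_gives_flat_density(self):
        env = Environment1D(ligand={"kind": "linear", "value_at_min": 10.0,
                                    "value_at_max": 10.0})
        d = ss.steady_state_density(env, RP, MP)
        assert np.ptp(d.density) / d.density.mean() < 1e-12

    def test_matches_chemotaxis_closed_form(self):
        # the general solver specialized to a linear attractant gradient with
        # constant speed must reproduce the closed-form tilt with chi from
        # the sensitivity formula -- this pins the derivation constants
        env = rt.chemo_fixture()
        chi = ss.sensitivity_chi(RP, MP).chi
        general = ss.steady_state_density(env, RP, MP)
        closed = ss.chemotaxis_closed_form(env, chi, RP)
        rel = np.max(np.abs(general.density - closed.density)) / closed.density.max()
        assert rel < 1e-8

    def test_normalization_and_positivity(self):
        for env in (rt.chemo_fixture(), rt.ph_fixture(), rt.thermo_fixture(),
                    rt.combined_fixture(attr_gradient=5.0)):
            d = ss.steady_state_density(env, RP, MP)
            assert np.all(d.density >= 0)
            assert trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-8)

    def test_inverse_speed_profile_without_receptor_gain(self):
        env = rt.speed_channel_fixture()
        d = ss.steady_state_density(env, rt.receptorless(RP), MP, mode="thermo")
        v = np.asarray(env.speed_at(d.grid))
        expected = (1.0 / v) / trapezoid(1.0 / v, d.grid)
        assert np.max(np.abs(d.density - expected)) / expected.max() < 1e-10

    def test_grid_convergence(self):
        from scipy.interpolate import CubicSpline

        base = rt.chemo_fixture(n_grid=512)
        fine = rt.chemo_fixture(n_grid=1024)
        d1 = ss.steady_state_density(base, RP, MP)
        d2 = ss.steady_state_density(fine, RP, MP)
        on_base = CubicSpline(d2.grid, d2.density)(d1.grid)
        # renormalize the interpolant on the coarse grid before comparing
        on_base /= trapezoid(on_base, d1.grid)
        assert np.max(np.abs(on_base - d1.density)) < 1e-6


class TestActivityAndTumblingDifferences:
    def test_uniform_environment_has_no_split(self):
        env = Environment1D(ligand={"kind": "linear", "value_at_min": 10.0,
                                    "value_at_max": 10.0})
        assert ss.activity_difference(300.0, env, RP, MP) == pytest.approx(0.0)
        assert ss.tumbling_rate_difference(300.0, env, RP, MP) == pytest.approx(0.0)

    def test_signs_track_the_gradient(self):
        env = rt.chemo_fixture()  # attractant increases to the right
        da = ss.activity_difference(300.0, env, RP, MP)
        dz = ss.tumbling_rate_difference(300.0, env, RP, MP)
        assert da < 0  # right-movers are less active...
        assert dz < 0  # ...and tumble less

    def test_proportional_to_run_length(self):
        env = rt.chemo_fixture()
        fast = replace(MP, tau_tumble=2 * MP.tau_tumble)  # slower motor, longer runs
        assert abs(ss.activity_difference(300.0, env, RP, fast)) > abs(
            ss.activity_difference(300.0, env, RP, MP))


class TestChemotaxisClosedForm:
    def test_zero_chi_uniform(self):
        d = ss.chemotaxis_closed_form(rt.chemo_fixture(), 0.0, RP)
        assert np.ptp(d.density) < 1e-12

    def test_peak_at_high_attractant_boundary(self):
        d = ss.chemotaxis_closed_form(rt.chemo_fixture(), 10.0, RP)
        assert np.all(np.diff(d.density) > 0)
        assert np.argmax(d.density) == len(d.grid) - 1

    def test_weak_binding_exponential_limit(self):
        # L << KI: the tilt reduces to exp(chi * L * (1/KI - 1/KA))
        env = rt.chemo_fixture(L_min=0.0, L_max=0.05)
        chi = 3.0
        d = ss.chemotaxis_closed_form(env, chi, RP)
        L = np.asarray(env.signal_at(d.grid, "ligand"))
        approx = np.exp(chi * L * (1.0 / RP.KI - 1.0 / RP.KA))
        approx /= trapezoid(approx, d.grid)
        assert np.max(np.abs(d.density - approx)) / approx.max() < 1e-4

    def test_fit_chi_self_inversion(self):
        env = rt.chemo_fixture()
        d = ss.chemotaxis_closed_form(env, 2.0, RP)
        chi_hat, r2 = ss.fit_chi(d, env, RP)
        assert chi_hat == pytest.approx(2.0, abs=1e-6)
        assert r2 > 1 - 1e-12

    def test_fit_chi_degenerate_kernel_rejected(self):
        env = Environment1D(ligand={"kind": "linear", "value_at_min": 10.0,
                                    "value_at_max": 10.0})
        d = ss.steady_state_density(env, RP, MP)
        with pytest.raises(ValueError):
            ss.fit_chi(d, env, RP)


class TestEffectivePotential:
    def test_uniform_density_zero_potential(self):
        env = Environment1D(ligand={"kind": "linear", "value_at_min": 5.0,
                                    "value_at_max": 5.0})
        d = ss.steady_state_density(env, RP, MP)
        assert np.max(ss.effective_potential(d)) < 1e-10

    def test_chemotaxis_potential_monotone_down_the_gradient(self):
        d = ss.steady_state_density(rt.chemo_fixture(), RP, MP)
        U = ss.effective_potential(d)
        assert np.all(np.diff(U) < 0)  # decreases toward high attractant

    def test_wild_type_ph_has_interior_minimum(self):
        d = ss.steady_state_density(rt.ph_fixture(), RP, MP)
        U = ss.effective_potential(d)
        i = np.argmin(U)
        assert 0 < i < len(U) - 1


class TestPreferredPoint:
    def test_symmetric_mixture_prefers_the_mirror_point(self):
        ph = PHParams(pKI_tar=9.0, pKA_tar=7.5, pKI_tsr=5.0, pKA_tsr=6.5)
        rp = replace(RP, ph=ph)
        env = rt.ph_fixture(5.5, 8.5)
        pt = ss.preferred_point(env, rp, MP, mode="ph")
        assert pt["interior"]
        assert pt["pH_star"] == pytest.approx(7.0, abs=1e-6)

    def test_thermo_constant_speed_prefers_T_c(self):
        T_c = rt.critical_temperature(RP)
        pt = ss.preferred_point(rt.thermo_fixture(), RP, MP, mode="thermo")
        assert pt["T_star"] == pytest.approx(T_c, abs=1e-6)

    def test_speed_slope_shifts_preference_below_T_c(self):
        T_c = rt.critical_temperature(RP)
        env = rt.thermo_fixture(speed=rt.SpeedProfile(
            kind="linear_in_T", v0=20.0, slope=0.02, T_ref=25.0))
        pt = ss.preferred_point(env, RP, MP, mode="thermo")
        assert pt["interior"] and pt["T_star"] < T_c - 0.1

    def test_boundary_accumulation_reported(self):
        rp = replace(RP, ph=PHParams(f_a=1.0, f_s=0.0))  # Tar-only: low-pH seeker
        pt = ss.preferred_point(rt.ph_fixture(), rp, MP, mode="ph")
        assert not pt["interior"]
        assert pt["x_star"] == pytest.approx(rt.ph_fixture().grid[0])


class TestDispersion:
    def test_uniform_density_on_ph_axis(self):
        env = rt.ph_fixture(6.0, 8.0)
        # exactly uniform profile built by hand: sigma = range/sqrt(12)
        x = env.grid
        dens = np.full_like(x, 1.0 / (x[-1] - x[0]))
        dens /= trapezoid(dens, x)
        prof = rt.DensityProfile(grid=x, density=dens, activity=dens * 0 + 0.5,
                                 methylation=dens * 0 + 1.0, potential=dens * 0,
                                 signals={"pH": np.asarray(env.signal_at(x, "ph"))})
        # uniform variance over the pH span actually covered by the
        # cell-centered grid: sigma = span / sqrt(12)
        span = prof.signals["pH"].max() - prof.signals["pH"].min()
        assert ss.dispersion(prof, "pH") == pytest.approx(span / np.sqrt(12.0),
                                                          rel=1e-4)

    def test_narrow_peak_has_small_dispersion(self):
        env = rt.ph_fixture(6.0, 8.0)
        x = env.grid
        w = np.exp(-0.5 * ((x - 300.0) / 5.0) ** 2)
        w /= trapezoid(w, x)
        lnw = np.log(np.maximum(w, 1e-300))
        prof = rt.DensityProfile(grid=x, density=w, activity=w * 0 + 0.5,
                                 methylation=w * 0 + 1.0, potential=lnw.max() - lnw,
                                 signals={"pH": np.asarray(env.signal_at(x, "ph"))})
        assert ss.dispersion(prof, "pH") < 0.02


class TestThermoAndCombined:
    def test_leading_order_matches_full_solution_near_T_c(self):
        env = rt.thermo_fixture()
        mp0 = replace(MP, kappa=0.0)
        full = ss.thermo_density(env, RP, mp0)
        gauss = ss.thermo_density_leading_order(env, RP, mp0)
        mid = len(env.grid) // 2
        sl = slice(mid - 25, mid + 25)
        rel = np.max(np.abs(gauss.density[sl] - full.density[sl]) / full.density[sl])
        assert rel < 0.05

    def test_combined_reduces_to_thermo_without_ligand(self):
        envc = rt.combined_fixture(attr_gradient=0.0, L_mid=0.0)
        envt = Environment1D(x_min=envc.x_min, x_max=envc.x_max,
                             n_grid=envc.n_grid, temperature=envc.temperature)
        dc = ss.combined_density(envc, RP, MP)
        dt = ss.thermo_density(envt, RP, MP)
        assert np.max(np.abs(dc.density - dt.density)) / dt.density.max() < 1e-10

    def test_uniform_attractant_background_lowers_preference(self):
        T_c = rt.critical_temperature(RP)
        pt = ss.preferred_point(rt.combined_fixture(attr_gradient=0.0, L_mid=0.1),
                                RP, MP, mode="mixed")
        assert pt["interior"] and pt["T_star"] < T_c - 0.5
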