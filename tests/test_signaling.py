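"""Receptor-cluster signaling: MWC activity, free energies, adaptation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import runtumble as rt
from runtumble import signaling as sig
from runtumble.params import PHParams, ThermoParams
from dataclasses import replace


RP = rt.ReceptorParams()


class TestActivity:
    @pytest.mark.parametrize("f,expected", [
        (0.0, 0.5),
        (math.log(3.0), 0.25),
        (-math.log(3.0), 0.75),
    ])
    def test_two_state_points(self, f, expected):
        assert sig.activity(f) == pytest.approx(expected, abs=1e-12)

    def test_saturated_inactive(self):
        assert sig.activity(50.0) < 1e-20

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sig.activity(float("nan"))

    @given(st.floats(-30, 30), st.floats(0.01, 30))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_and_bounded(self, f, df):
        a1, a2 = sig.activity(f), sig.activity(f + df)
        assert 0.0 < a2 < a1 < 1.0


class TestChemoFreeEnergy:
    def test_reference_point_vanishes(self):
        assert sig.free_energy_chemo(RP.m0, 0.0, RP) == pytest.approx(0.0)

    def test_saturating_ligand_limit(self):
        f_inf = sig.free_energy_chemo(RP.m0, 1e12, RP)
        assert f_inf == pytest.approx(RP.N * math.log(RP.KA / RP.KI), rel=1e-6)

    def test_equal_dissociation_constants_cancel(self):
        # the ligand term itself vanishes when both conformations bind equally
        assert sig.ligand_term(123.4, 50.0, 50.0) == pytest.approx(0.0)

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            sig.free_energy_chemo(RP.m0, -1.0, RP)

    @given(st.floats(0, 1e4), st.floats(0.1, 1e3), st.floats(-1, 3), st.floats(0.01, 1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ligand_and_methylation(self, L, dL, m, dm):
        assert sig.free_energy_chemo(m, L + dL, RP) > sig.free_energy_chemo(m, L, RP)
        assert sig.free_energy_chemo(m + dm, L, RP) < sig.free_energy_chemo(m, L, RP)


class TestPHFreeEnergy:
    def test_tar_only_free_energy_falls_with_ph(self):
        # Tar responds to acidification like an attractant: f decreases as pH
        # rises, so Tar-only populations accumulate at low pH.
        rp = replace(RP, ph=PHParams(f_a=1.0, f_s=0.0, pKI_tar=9.0, pKA_tar=6.6,
                                     pKI_tsr=5.0, pKA_tsr=6.5))
        ph = np.linspace(5.5, 8.5, 50)
        f = sig.free_energy_ph(RP.m0, ph, rp)
        assert np.all(np.diff(f) < 0)

    def test_tsr_only_free_energy_rises_with_ph(self):
        rp = replace(RP, ph=PHParams(f_a=0.0, f_s=1.0, pKI_tar=9.0, pKA_tar=6.6,
                                     pKI_tsr=5.0, pKA_tsr=6.5))
        ph = np.linspace(5.5, 8.5, 50)
        f = sig.free_energy_ph(RP.m0, ph, rp)
        assert np.all(np.diff(f) > 0)

    def test_mirror_symmetric_mixture_is_balanced_at_center(self):
        # pK windows mirror-symmetric about 7.0 with equal fractions: the
        # signal part of f is even about 7.0, so its pH-derivative vanishes
        # there (the preferred point of the drift).
        rp = replace(RP, ph=PHParams(pKI_tar=9.0, pKA_tar=7.5,
                                     pKI_tsr=5.0, pKA_tsr=6.5, f_a=0.5, f_s=0.5))
        d = 0.37
        f_lo = sig.free_energy_ph(RP.m0, 7.0 - d, rp)
        f_hi = sig.free_energy_ph(RP.m0, 7.0 + d, rp)
        assert f_lo == pytest.approx(f_hi, abs=1e-9)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            PHParams(f_a=0.7, f_s=0.6)


class TestThermoFreeEnergy:
    def test_reference_reductions(self):
        T0 = RP.thermo.T0
        assert sig.free_energy_thermo(RP.m0, T0, RP) == pytest.approx(0.0)
        m = 0.6
        assert sig.free_energy_thermo(m, T0, RP) == pytest.approx(
            RP.N * RP.alpha0 * (RP.m0 - m))

    def test_thermal_response_inverts_at_critical_methylation(self):
        # sign of df/dT at fixed m flips as m crosses m_c = m0
        T0 = RP.thermo.T0
        dT = 1.0
        below = sig.free_energy_thermo(RP.m0 - 0.2, T0 + dT, RP) - sig.free_energy_thermo(
            RP.m0 - 0.2, T0, RP)
        above = sig.free_energy_thermo(RP.m0 + 0.2, T0 + dT, RP) - sig.free_energy_thermo(
            RP.m0 + 0.2, T0, RP)
        assert below > 0 > above  # warm sensor below m_c, cold sensor above

    def test_mixed_reduces_to_components(self):
        assert sig.free_energy_mixed(0.8, 27.0, 0.0, RP) == pytest.approx(
            sig.free_energy_thermo(0.8, 27.0, RP))
        L = RP.KI * RP.KA / (RP.KI + RP.KA)
        total = sig.free_energy_mixed(0.8, 27.0, L, RP)
        parts = sig.free_energy_thermo(0.8, 27.0, RP) + RP.N * sig.ligand_term(
            L, RP.KI, RP.KA)
        assert total == pytest.approx(parts, rel=1e-12)


class TestAdaptation:
    def test_adapted_activity_reference_and_slope(self):
        assert sig.adapted_activity(RP.thermo.T0, RP) == RP.a0_ref
        rp0 = replace(RP, thermo=ThermoParams(dalpha_dT=0.35, da0_dT=0.0))
        assert sig.adapted_activity(45.0, rp0) == RP.a0_ref
        T = np.linspace(20, 30, 11)
        assert np.all(np.diff(sig.adapted_activity(T, RP)) > 0)

    def test_adapted_activity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sig.adapted_activity(200.0, RP)

    def test_adapted_methylation_reference_point(self):
        # with a0 = 1/2 and no ligand the free energy must vanish: m_ss = m0
        rp = replace(RP, a0_ref=0.5)
        assert sig.adapted_methylation({"ligand": 0.0}, rp, "chemo") == pytest.approx(
            rp.m0, abs=1e-12)

    @pytest.mark.parametrize("mode,s", [
        ("chemo", {"ligand": 75.0}),
        ("ph", {"pH": 6.9}),
        ("thermo", {"T": 27.5}),
        ("mixed", {"T": 23.0, "ligand": 0.2}),
    ])
    def test_defining_property_all_modes(self, mode, s):
        # activity at the adapted methylation equals a0 to 1e-10 (the closed
        # form is cross-checked against a bracketed root inside the call)
        m_ss = sig.adapted_methylation(s, RP, mode)
        a0 = sig.adapted_activity(float(s.get("T", RP.thermo.T0)), RP) \
            if mode in ("thermo", "mixed") else RP.a0_ref
        f = sig._mode_free_energy(m_ss, s, RP, mode)
        assert sig.activity(f) == pytest.approx(a0, abs=1e-10)

    def test_thermo_adapted_methylation_crosses_m_c_at_T_c(self):
        T_c = sig.critical_temperature(RP)
        assert sig.adapted_methylation({"T": T_c}, RP, "thermo") == pytest.approx(
            RP.m_c, abs=1e-9)
        below = sig.adapted_methylation({"T": T_c - 2.0}, RP, "thermo")
        above = sig.adapted_methylation({"T": T_c + 2.0}, RP, "thermo")
        assert below < RP.m_c < above

    def test_methylation_rate_fixed_point_and_direction(self):
        assert sig.methylation_rate(RP.a0_ref, RP.a0_ref, RP) == 0.0
        assert sig.methylation_rate(RP.a0_ref - 0.1, RP.a0_ref, RP) > 0
        assert sig.methylation_rate(RP.a0_ref + 0.1, RP.a0_ref, RP) < 0

    def test_perfect_adaptation_after_step(self):
        # after a persistent stimulus the activity returns to a0 within 1%
        # of a0 in ten adaptation times
        L1 = 50.0
        m0 = sig.adapted_methylation({"ligand": 0.0}, RP, "chemo")

        def rhs(t, m):
            a = sig.activity(sig.free_energy_chemo(m[0], L1, RP))
            return [RP.k_m() * (RP.a0_ref - a)]

        sol = solve_ivp(rhs, (0, 10 * RP.tau_m), [m0], rtol=1e-9, atol=1e-12)
        a_end = sig.activity(sig.free_energy_chemo(sol.y[0, -1], L1, RP))
        assert abs(a_end - RP.a0_ref) < 0.01 * RP.a0_ref


class TestCriticalTemperature:
    def test_degenerate_configuration_detected(self):
        rp = replace(RP, a0_ref=0.5,
                     thermo=ThermoParams(dalpha_dT=0.35, da0_dT=0.0))
        with pytest.raises(ValueError):
            sig.critical_temperature(rp)

    def test_value_and_sign_flip(self):
        T_c = sig.critical_temperature(RP)
        # a0(T_c) = 1/2 under m_c = m0
        assert sig.adapted_activity(T_c, RP) == pytest.approx(0.5, abs=1e-10)

    def test_out_of_range_rejected(self):
        rp = replace(RP, thermo=ThermoParams(dalpha_dT=0.35, da0_dT=0.005, T0=25.0))
        with pytest.raises(ValueError):
            sig.critical_temperature(rp, T_range=(26.0, 30.0))
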