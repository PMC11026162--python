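import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from electrosolv.constants import E_CHARGE, kBT
from electrosolv.charge import (IonizableSurface, ionization_fraction,
                                regulation_capacity,
                                normalized_regulation_capacity, grahame_sigma,
                                solve_surface_state)
from electrosolv.solution import SolutionConditions, debye_length


class TestIonizationFraction:
    def test_half_ionized_at_pK_and_zero_potential(self):
        assert ionization_fraction(5.0, 5.0, 0.0, "acid") == pytest.approx(0.5)
        assert ionization_fraction(5.0, 5.0, 0.0, "base") == pytest.approx(0.5)

    def test_two_decades_above_pK(self):
        a = ionization_fraction(7.0, 5.0, 0.0, "acid")
        assert a == pytest.approx(1 / (1 + 1e-2), rel=1e-12)

    def test_one_decade_of_surface_potential(self):
        # psi_s = -kT ln(10)/e shifts the acid equilibrium by one pH unit
        psi = -kBT() * math.log(10) / E_CHARGE
        a = ionization_fraction(5.0, 5.0, psi, "acid")
        assert a == pytest.approx(1 / 11, rel=1e-9)

    @given(st.floats(2.0, 12.0), st.floats(-0.3, 0.3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_and_monotone_in_pH(self, pH, psi):
        a = ionization_fraction(pH, 6.0, psi, "acid")
        assert 0.0 <= a <= 1.0
        assert ionization_fraction(pH + 0.5, 6.0, psi, "acid") >= a


class TestRegulationCapacity:
    def test_vanishes_at_full_and_zero_ionization(self):
        assert regulation_capacity(0.0) == 0.0
        assert regulation_capacity(1.0) == 0.0

    def test_maximal_at_half_ionization(self):
        caps = [abs(regulation_capacity(a)) for a in np.linspace(0, 1, 101)]
        assert np.argmax(caps) == 50

    def test_signed_by_group_type(self):
        assert regulation_capacity(0.3, group_type="acid") > 0
        assert regulation_capacity(0.3, group_type="base") < 0

    def test_matches_central_difference_of_isotherm(self):
        pH, pK, psi = 6.0, 5.0, -0.030
        h = 1e-8
        num = (ionization_fraction(pH, pK, psi + h, "acid")
               - ionization_fraction(pH, pK, psi - h, "acid")) / (2 * h)
        alpha = ionization_fraction(pH, pK, psi, "acid")
        assert regulation_capacity(alpha) == pytest.approx(num, rel=1e-6)

    def test_normalized_variant_unit_maximum(self):
        assert normalized_regulation_capacity(0.5) == 1.0
        assert normalized_regulation_capacity(0.0) == 0.0


class TestGrahame:
    def test_zero_potential(self):
        scr = debye_length(SolutionConditions(c0=1e-3))
        assert grahame_sigma(0.0, scr, 78.5) == 0.0

    def test_odd_in_potential(self):
        scr = debye_length(SolutionConditions(c0=1e-3))
        assert grahame_sigma(0.05, scr, 78.5) == pytest.approx(
            -grahame_sigma(-0.05, scr, 78.5), rel=1e-12)

    def test_debye_hueckel_limit(self):
        from electrosolv.constants import EPS_0
        scr = debye_length(SolutionConditions(c0=1e-3))
        psi = 0.005
        linear = 78.5 * EPS_0 * scr.kappa * psi
        assert grahame_sigma(psi, scr, 78.5) == pytest.approx(linear, rel=0.01)

    def test_direct_evaluation_at_thermal_voltage(self):
        from electrosolv.constants import EPS_0
        scr = debye_length(SolutionConditions(c0=1e-3))
        kT = kBT()
        psi = kT / E_CHARGE  # 25.7 mV
        expected = 2 * 78.5 * EPS_0 * scr.kappa * (kT / E_CHARGE) * math.sinh(0.5)
        assert grahame_sigma(psi, scr, 78.5) == pytest.approx(expected, rel=1e-12)


class TestSelfConsistentState:
    def test_neutral_limit_at_zero_site_density(self):
        surf = IonizableSurface("acid", 6.0, site_density=0.0)
        st_ = solve_surface_state(surf, SolutionConditions(c0=1e-4, pH=6.0))
        assert st_.psi_s == 0.0
        assert st_.sigma == 0.0

    def test_saturation_far_above_pK_at_high_salt(self):
        gamma = 1e16
        surf = IonizableSurface("acid", 4.0, site_density=gamma)
        st_ = solve_surface_state(surf, SolutionConditions(c0=1.0, pH=10.0))
        assert st_.alpha > 0.99
        assert st_.sigma == pytest.approx(-E_CHARGE * gamma, rel=0.02)

    def test_residual_is_global_sign_change_on_grid(self):
        surf = IonizableSurface("acid", 6.0, site_density=2e17)
        cond = SolutionConditions(c0=5e-6, pH=5.6)
        st_ = solve_surface_state(surf, cond)
        scr = debye_length(cond)

        def resid(psi):
            a = ionization_fraction(cond.pH, surf.pK, psi, "acid")
            return grahame_sigma(psi, scr, cond.eps_r) + E_CHARGE * 2e17 * a

        grid = np.linspace(-0.3, 0.3, 6001)
        vals = np.array([resid(p) for p in grid])
        crossings = np.flatnonzero(np.diff(np.sign(vals)) != 0)
        assert len(crossings) == 1
        assert abs(grid[crossings[0]] - st_.psi_s) < 2e-4

    def test_acid_base_mirror_symmetry(self):
        """An acid at pH = pK + d mirrors a base at pH = pK - d."""
        acid = IonizableSurface("acid", 6.0, site_density=1e17)
        base = IonizableSurface("base", 6.0, site_density=1e17)
        sa = solve_surface_state(acid, SolutionConditions(c0=1e-4, pH=7.0))
        sb = solve_surface_state(base, SolutionConditions(c0=1e-4, pH=5.0))
        assert sa.psi_s == pytest.approx(-sb.psi_s, rel=1e-6)
        assert sa.alpha == pytest.approx(sb.alpha, rel=1e-6)
        assert sa.sigma == pytest.approx(-sb.sigma, rel=1e-6)

    def test_charge_monotone_in_pH_for_acids(self):
        surf = IonizableSurface("acid", 6.0, site_density=1e17)
        sig = [abs(solve_surface_state(
            surf, SolutionConditions(c0=1e-4, pH=p)).sigma)
            for p in np.linspace(4, 10, 13)]
        assert np.all(np.diff(sig) >= -1e-15)

    def test_capacity_vs_pH_single_peak_above_pK(self):
        """Charge regulation shifts the capacity peak above the pK."""
        surf = IonizableSurface("acid", 6.0, site_density=2e17)
        pHs = np.linspace(3, 12, 46)
        caps = [normalized_regulation_capacity(
            solve_surface_state(surf, SolutionConditions(c0=1e-4, pH=p)).alpha)
            for p in pHs]
        caps = np.array(caps)
        ipk = int(np.argmax(caps))
        assert pHs[ipk] > 6.0
        # single-peaked: rises before, falls after
        assert np.all(np.diff(caps[:ipk + 1]) >= -1e-12)
        assert np.all(np.diff(caps[ipk:]) <= 1e-12)

    def test_molecular_sphere_closure(self):
        surf = IonizableSurface("acid", 4.5, n_sites=5, radius=2.5e-9)
        st_ = solve_surface_state(surf, SolutionConditions(c0=0.1, pH=7.5))
        assert st_.alpha > 0.99
        assert st_.psi_s < 0
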