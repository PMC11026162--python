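import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from electrosolv.constants import kBT
from electrosolv.charge import SurfaceState
from electrosolv.potential import (PairPotentialParams, effective_radius,
                                   electrostatic_amplitude,
                                   interfacial_amplitude, vdw_energy,
                                   total_potential, params_from_minimum,
                                   predict_mixture_clustering)
from electrosolv.solution import SolutionConditions, debye_length

KT = kBT()


def make_state(psi=-0.04, sigma=-1e-3, alpha=0.3):
    from electrosolv.charge import regulation_capacity
    return SurfaceState(psi_s=psi, sigma=sigma, alpha=alpha,
                        dalpha_dpsi=regulation_capacity(alpha))


class TestElectrostaticAmplitude:
    def test_zero_at_zero_potential(self):
        scr = debye_length(SolutionConditions(c0=1e-4))
        st_ = make_state(psi=0.0)
        assert electrostatic_amplitude(st_, scr, 1e-6, 1e-6, 78.5) == 0.0

    def test_quadratic_at_small_potentials(self):
        scr = debye_length(SolutionConditions(c0=1e-4))
        a1 = electrostatic_amplitude(make_state(psi=0.0025), scr, 1e-6, 1e-6, 78.5)
        a2 = electrostatic_amplitude(make_state(psi=0.005), scr, 1e-6, 1e-6, 78.5)
        assert a2 == pytest.approx(4 * a1, rel=0.01)

    def test_effective_radius_geometry(self):
        scr = debye_length(SolutionConditions(c0=1e-4))
        st_ = make_state()
        R = 1e-6
        a_equal = electrostatic_amplitude(st_, scr, R, R, 78.5)
        a_plate = electrostatic_amplitude(st_, scr, R, 1e4 * R, 78.5)
        # R_eff = R/2 for equal spheres vs -> R against a plate
        assert a_equal / a_plate == pytest.approx(0.5, rel=1e-3)


class TestInterfacialAmplitude:
    def setup_method(self):
        self.water = SolutionConditions.for_solvent("water", c0=1e-4)
        self.ethanol = SolutionConditions.for_solvent("ethanol", c0=1e-5)

    def test_negative_particle_in_water_attracts(self):
        B = interfacial_amplitude(make_state(sigma=-1e-3), self.water,
                                  1e-6, 1e-6)
        assert B < 0

    def test_positive_particle_in_water_repels(self):
        B = interfacial_amplitude(make_state(psi=0.04, sigma=+1e-3),
                                  self.water, 1e-6, 1e-6)
        assert B > 0

    def test_positive_particle_in_ethanol_attracts(self):
        B = interfacial_amplitude(make_state(psi=0.04, sigma=+1e-3),
                                  self.ethanol, 1e-6, 1e-6)
        assert B < 0

    def test_vanishes_at_full_ionization(self):
        B = interfacial_amplitude(make_state(alpha=1.0), self.water,
                                  1e-6, 1e-6)
        assert B == 0.0

    def test_vanishes_without_charge_or_phi0(self):
        assert interfacial_amplitude(make_state(sigma=0.0), self.water,
                                     1e-6, 1e-6) == 0.0
        nophi = self.water.with_(phi0=0.0, solvent_name="custom")
        assert interfacial_amplitude(make_state(), nophi, 1e-6, 1e-6) == 0.0


class TestVdw:
    R = 2.41e-6
    A_H = 2.4e-21

    def test_printed_checkpoints(self):
        u02 = vdw_energy(0.2e-6, self.A_H, self.R, self.R) / KT
        u01 = vdw_energy(0.1e-6, self.A_H, self.R, self.R) / KT
        assert u02 < 0 and u01 < u02
        # x = 0.1 um checkpoint: ~ -1 kBT within 20%
        assert u01 == pytest.approx(-1.0, abs=0.2)

    def test_close_approach_asymptote(self):
        x = self.R / 100
        full = vdw_energy(x, self.A_H, self.R, self.R)
        assert full == pytest.approx(-self.A_H * self.R / (12 * x), rel=0.05)

    def test_strictly_negative_and_domain(self):
        xs = np.geomspace(1e-9, 1e-5, 50)
        assert np.all(vdw_energy(xs, self.A_H, self.R, self.R) < 0)
        with pytest.raises(ValueError):
            vdw_energy(0.0, self.A_H, self.R, self.R)


class TestTotalPotential:
    k1 = 1e7
    k2 = 0.95e7

    def grid(self):
        return np.linspace(1e-9, 3e-6, 5000)

    def test_pure_repulsion_has_no_minimum(self):
        p = PairPotentialParams(A=100 * KT, B=0.0, kappa1=self.k1,
                                kappa2=self.k2)
        c = total_potential(p, self.grid())
        assert c.classification == "repulsive"
        assert c.x_min is None

    def test_closed_form_minimum_matches_numeric(self):
        p = params_from_minimum(-4 * KT, 500e-9, self.k1, self.k2)
        c = total_potential(p, self.grid())
        assert c.classification == "non-monotonic"
        assert c.x_min == pytest.approx(500e-9, rel=1e-9)
        assert c.w == pytest.approx(-4 * KT, rel=1e-9)
        # numeric minimizer agreement
        i = np.argmin(c.U)
        assert abs(c.x[i] - c.x_min) < 2 * (c.x[1] - c.x[0])

    def test_decay_to_zero_and_long_range_dominance(self):
        p = params_from_minimum(-4 * KT, 500e-9, self.k1, self.k2)
        x = np.array([2e-6, 4e-6])
        u = p.energy(x)
        assert abs(u[1]) < abs(u[0])
        # interfacial term dominates at long range (kappa2 < kappa1)
        ratio = abs(p.B * np.exp(-self.k2 * 3e-6) / (p.A * np.exp(-self.k1 * 3e-6)))
        assert ratio > 1

    def test_degenerate_decay_rejected(self):
        with pytest.raises(ValueError, match="kappa1"):
            PairPotentialParams(A=1e-20, B=-1e-20, kappa1=1e7, kappa2=1e7)

    def test_vdw_refinement_shifts_minimum_inward(self):
        p0 = params_from_minimum(-2 * KT, 300e-9, self.k1, self.k2)
        p1 = p0.replace(A_H=2.4e-21, R1=2.41e-6, R2=2.41e-6, include_vdw=True)
        c0 = total_potential(p0, self.grid())
        c1 = total_potential(p1, self.grid())
        assert c1.w < c0.w          # vdW deepens the well
        assert c1.x_min < c0.x_min  # and pulls it inward


class TestParamsFromMinimum:
    k1 = 1e7
    k2 = 0.95e7

    def test_round_trip(self):
        p = params_from_minimum(-4 * KT, 500e-9, self.k1, self.k2)
        c = total_potential(p, np.linspace(1e-9, 3e-6, 100))
        assert c.x_min == pytest.approx(500e-9, rel=1e-9)
        assert c.w == pytest.approx(-4 * KT, rel=1e-9)

    def test_against_linear_solve_oracle(self):
        """(A, B) must solve the 2x2 linear system U(xm)=w, U'(xm)=0."""
        kappa1 = 1 / 136e-9
        kappa2 = 0.95 * kappa1
        w, xm = -4 * KT, 500e-9
        M = np.array([
            [math.exp(-kappa1 * xm), math.exp(-kappa2 * xm)],
            [-kappa1 * math.exp(-kappa1 * xm), -kappa2 * math.exp(-kappa2 * xm)],
        ])
        A_or, B_or = np.linalg.solve(M, [w, 0.0])
        p = params_from_minimum(w, xm, kappa1, kappa2)
        assert p.A == pytest.approx(A_or, rel=1e-9)
        assert p.B == pytest.approx(B_or, rel=1e-9)
        assert p.A > 0 > p.B

    def test_curvature_positive(self):
        p = params_from_minimum(-3 * KT, 400e-9, self.k1, self.k2)
        h = 1e-10
        u2 = (float(p.energy(400e-9 + h)) - 2 * float(p.energy(400e-9))
              + float(p.energy(400e-9 - h))) / h**2
        assert u2 == pytest.approx(-(-3 * KT) * self.k1 * self.k2, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            params_from_minimum(+1 * KT, 500e-9, self.k1, self.k2)
        with pytest.raises(ValueError, match="degenerate"):
            params_from_minimum(-1 * KT, 500e-9, 1e7, 1e7)

    @given(st.floats(-8, -0.5), st.floats(100, 1500),
           st.floats(0.85, 0.99))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip_property(self, w_kt, xm_nm, ratio):
        k1 = 1 / 100e-9
        p = params_from_minimum(w_kt * KT, xm_nm * 1e-9, k1, ratio * k1)
        from electrosolv.potential import _exp2_xmin
        xm = _exp2_xmin(p.A, p.B, p.kappa1, p.kappa2)
        assert xm == pytest.approx(xm_nm * 1e-9, rel=1e-9)
        assert float(p.energy(xm)) == pytest.approx(w_kt * KT, rel=1e-9)


class TestMixtureLogic:
    def caps_state(self, alpha, sign=-1):
        return make_state(psi=sign * 0.03, sigma=sign * 1e-3, alpha=alpha)

    def test_truth_table_or(self):
        high = self.caps_state(0.5)    # normalized capacity 1
        low = self.caps_state(0.999)   # ~ 0.004
        assert predict_mixture_clustering([high, high]) is True
        assert predict_mixture_clustering([high, low]) is True
        assert predict_mixture_clustering([low, high]) is True
        assert predict_mixture_clustering([low, low]) is False

    def test_single_species(self):
        assert predict_mixture_clustering([self.caps_state(0.4)]) is True

    def test_mixed_charge_signs_rejected(self):
        with pytest.raises(ValueError, match="hetero"):
            predict_mixture_clustering(
                [self.caps_state(0.5, -1), self.caps_state(0.5, +1)])
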