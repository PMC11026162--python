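"""Scenario presets and per-solvent calibration of the interfacial amplitude.

Each preset bundles a solvent state, a surface chemistry and a particle size,
and resolves through the model chain (self-consistent surface state ->
electrostatic amplitude A -> interfacial amplitude B) to a pair potential
whose attraction/repulsion classification follows the sign rule
sign(B) = -sign(sigma * phi0).

Calibration strategy
--------------------
The interfacial amplitude carries one dimensionless constant per solvent
(C_int).  Reference (anchor) scenarios pin it: for water, silica spheres in
5 uM electrolyte with a well of depth |w| = 4 kBT at x_min = 5 kappa^-1; for
ethanol and IPA, aminated spheres in ~0.4 uM electrolyte with ~2 kBT wells.
The closed-form inverse map (w, x_min) -> (A, B) gives the anchor amplitudes;
inverting the Derjaguin amplitude for psi_s and the Grahame relation for
sigma then yields the effective site density Gamma and C_int in closed form.
Non-anchor attractive presets reuse the solvent's C_int and solve for
(Gamma, default pH) from their own (w, x_min) anchor instead.  Repulsive
presets specify a plausible surface potential directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .constants import E_CHARGE, EPS_0, kBT
from .charge import (IonizableSurface, SurfaceState, grahame_sigma,
                     ionization_fraction, solve_surface_state)
from .potential import (KAPPA_RATIO_DEFAULT, PairPotentialParams,
                        effective_radius, electrostatic_amplitude,
                        interfacial_amplitude, params_from_minimum,
                        total_potential)
from .solution import SolutionConditions, debye_length, get_solvent

__all__ = ["Scenario", "scenario_presets", "get_scenario", "resolve_potential",
           "solvent_calibration_constant"]

HAMAKER_SILICA = 2.4e-21  # J

# anchors per solvent: (surface preset name, group, pK, c0 M, pH, diameter m,
#                       w in kBT, x_min in units of kappa^-1)
_ANCHORS = {
    "water": dict(surface="silica", group_type="acid", pK=6.0, c0=5e-6,
                  pH=5.6, diameter=4.82e-6, w_kt=-4.0, xmin_kappa=5.0),
    "ethanol": dict(surface="nh2", group_type="base", pK=9.5, c0=4e-7,
                    pH=7.0, diameter=3.92e-6, w_kt=-2.0, xmin_kappa=5.0),
    "ipa": dict(surface="nh2", group_type="base", pK=9.5, c0=4e-7,
                pH=7.0, diameter=3.92e-6, w_kt=-2.0, xmin_kappa=4.7),
}


@dataclass(frozen=True)
class Scenario:
    name: str
    conditions: SolutionConditions
    surface: IonizableSurface
    diameter_mean: float          # m
    diameter_cv: float
    C_int: float
    expected: str                 # "attractive" | "repulsive"
    description: str = ""

    @property
    def radius(self) -> float:
        return self.diameter_mean / 2


def _psi_from_amplitude(A: float, reff: float, eps_r: float, T: float,
                        sign: int) -> float:
    """Invert A = 64 pi R_eff eps eps0 (kT/e)^2 tanh^2(e psi/4kT)."""
    kT = kBT(T)
    coef = 64.0 * math.pi * reff * eps_r * EPS_0 * (kT / E_CHARGE) ** 2
    t2 = A / coef
    if t2 >= 1.0:
        raise ValueError(
            f"target electrostatic amplitude {A / kT:.0f} kBT exceeds the "
            f"weak-overlap cap {coef / kT:.0f} kBT for this geometry")
    return sign * (4.0 * kT / E_CHARGE) * math.atanh(math.sqrt(t2))


def _anchor_solve(solvent: str) -> tuple[float, float, float]:
    """Closed-form (Gamma, C_int, pH) for a solvent's anchor scenario."""
    a = _ANCHORS[solvent]
    cond = SolutionConditions.for_solvent(solvent, c0=a["c0"], pH=a["pH"])
    scr = debye_length(cond)
    kT = scr.kBT
    k1 = scr.kappa
    k2 = KAPPA_RATIO_DEFAULT * k1
    R = a["diameter"] / 2
    reff = effective_radius(R, R)
    pars = params_from_minimum(a["w_kt"] * kT, a["xmin_kappa"] / k1, k1, k2)
    sign = -1 if a["group_type"] == "acid" else +1
    psi = _psi_from_amplitude(pars.A, reff, cond.eps_r, cond.T, sign)
    alpha = ionization_fraction(a["pH"], a["pK"], psi, a["group_type"], cond.T)
    sigma = grahame_sigma(psi, scr, cond.eps_r, cond.T)
    gamma = abs(sigma) / (E_CHARGE * alpha)
    cap = 4.0 * alpha * (1.0 - alpha)
    c_int = abs(pars.B) / (2 * math.pi * reff / k2 * abs(cond.phi0)
                           * abs(sigma) * cap)
    return gamma, c_int, a["pH"]


@lru_cache(maxsize=None)
def solvent_calibration_constant(solvent: str) -> float:
    """Calibrated dimensionless C_int for a registered solvent."""
    if solvent not in _ANCHORS:
        raise KeyError(f"no calibration anchor for solvent {solvent!r}")
    return _anchor_solve(solvent)[1]


def _member_solve(solvent: str, group_type: str, pK: float, c0: float,
                  diameter: float, w_kt: float, xmin_kappa: float,
                  alpha_branch: str) -> tuple[float, float]:
    """(Gamma, pH) for a non-anchor attractive preset with C_int fixed."""
    c_int = solvent_calibration_constant(solvent)
    cond = SolutionConditions.for_solvent(solvent, c0=c0)
    scr = debye_length(cond)
    kT = scr.kBT
    k1 = scr.kappa
    k2 = KAPPA_RATIO_DEFAULT * k1
    R = diameter / 2
    reff = effective_radius(R, R)
    pars = params_from_minimum(w_kt * kT, xmin_kappa / k1, k1, k2)
    sign = -1 if group_type == "acid" else +1
    psi = _psi_from_amplitude(pars.A, reff, cond.eps_r, cond.T, sign)
    sigma = grahame_sigma(psi, scr, cond.eps_r, cond.T)
    m = abs(pars.B) / (c_int * 2 * math.pi * reff / k2 * abs(cond.phi0)
                       * abs(sigma))
    if m > 1.0:
        raise ValueError("preset target is infeasible: required regulation "
                         f"capacity {m:.3f} exceeds 1")
    root = math.sqrt(1.0 - m)
    alpha = (1.0 - root) / 2 if alpha_branch == "low" else (1.0 + root) / 2
    psi_hat = E_CHARGE * psi / kT
    if group_type == "acid":
        pH = pK - math.log10((1 - alpha) / alpha) - psi_hat / math.log(10)
    else:
        pH = pK + math.log10((1 - alpha) / alpha) - psi_hat / math.log(10)
    gamma = abs(sigma) / (E_CHARGE * alpha)
    return gamma, pH


def _gamma_from_psi(solvent: str, group_type: str, pK: float, c0: float,
                    pH: float, psi: float) -> float:
    cond = SolutionConditions.for_solvent(solvent, c0=c0, pH=pH)
    scr = debye_length(cond)
    alpha = ionization_fraction(pH, pK, psi, group_type, cond.T)
    sigma = grahame_sigma(psi, scr, cond.eps_r, cond.T)
    return abs(sigma) / (E_CHARGE * alpha)


def _make(name, solvent, surf_name, group_type, pK, c0, pH, gamma, diameter,
          cv, expected, description=""):
    cond = SolutionConditions.for_solvent(solvent, c0=c0, pH=pH)
    surface = IonizableSurface(group_type=group_type, pK=pK,
                               site_density=gamma, radius=diameter / 2,
                               label=surf_name)
    return Scenario(name=name, conditions=cond, surface=surface,
                    diameter_mean=diameter, diameter_cv=cv,
                    C_int=solvent_calibration_constant(solvent),
                    expected=expected, description=description)


@lru_cache(maxsize=1)
def scenario_presets() -> dict[str, Scenario]:
    """Catalogue of named scenarios mirroring the experimental series."""
    cat: dict[str, Scenario] = {}

    # --- water ------------------------------------------------------------
    g_si, _, ph_si = _anchor_solve("water")
    cat["silica_water"] = _make(
        "silica_water", "water", "silica", "acid", 6.0, 5e-6, ph_si, g_si,
        4.82e-6, 0.03, "attractive",
        "negatively charged silica in deionized water; hcp clusters")

    g, ph = _member_solve("water", "acid", 6.0, 1.2e-4, 4.82e-6, -3.0, 5.0,
                          "low")
    cat["silica_ph_series"] = _make(
        "silica_ph_series", "water", "silica", "acid", 6.0, 1.2e-4, ph, g,
        4.82e-6, 0.03, "attractive",
        "silica at fixed 0.12 mM ionic strength, variable pH")

    g, ph = _member_solve("water", "acid", 4.5, 2.5e-4, 3.0e-6, -3.0, 5.0,
                          "high")
    cat["cooh_water_ph_series"] = _make(
        "cooh_water_ph_series", "water", "cooh", "acid", 4.5, 2.5e-4, ph, g,
        3.0e-6, 0.02, "attractive",
        "carboxylated melamine resin at 0.25 mM, variable pH")

    g = _gamma_from_psi("water", "base", 9.5, 2.5e-4, 5.6, +0.040)
    cat["amine_water"] = _make(
        "amine_water", "water", "nh2", "base", 9.5, 2.5e-4, 5.6, g,
        3.92e-6, 0.03, "repulsive",
        "positively charged aminated silica in water; no clusters at any c0")

    # --- alcohols ---------------------------------------------------------
    g_et, _, ph_et = _anchor_solve("ethanol")
    cat["amine_ethanol"] = _make(
        "amine_ethanol", "ethanol", "nh2", "base", 9.5, 4e-7, ph_et, g_et,
        3.92e-6, 0.03, "attractive",
        "positive aminated silica in ethanol; hcp clusters (phi0 > 0)")

    g_ip, _, ph_ip = _anchor_solve("ipa")
    cat["amine_ipa"] = _make(
        "amine_ipa", "ipa", "nh2", "base", 9.5, 4e-7, ph_ip, g_ip,
        3.92e-6, 0.03, "attractive",
        "positive aminated silica in isopropanol; hcp clusters")

    g = _gamma_from_psi("ethanol", "acid", 4.5, 4e-7, 7.0, -0.040)
    cat["cooh_ethanol"] = _make(
        "cooh_ethanol", "ethanol", "cooh", "acid", 4.5, 4e-7, 7.0, g,
        3.0e-6, 0.02, "repulsive",
        "negative carboxylated particles stay dispersed in ethanol")

    return cat


def get_scenario(name: str) -> Scenario:
    cat = scenario_presets()
    try:
        return cat[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{sorted(cat)}") from None


def resolve_potential(scenario: Scenario, include_vdw: bool = False,
                      A_H: float = HAMAKER_SILICA
                      ) -> tuple[PairPotentialParams, SurfaceState]:
    """Model chain: surface state -> (A, B, kappa1, kappa2) for a preset."""
    cond = scenario.conditions
    scr = debye_length(cond)
    state = solve_surface_state(scenario.surface, cond)
    R = scenario.radius
    k1 = scr.kappa
    k2 = KAPPA_RATIO_DEFAULT * k1
    A = electrostatic_amplitude(state, scr, R, R, cond.eps_r, cond.T)
    B = interfacial_amplitude(state, cond, R, R,
                              C_int=scenario.C_int, kappa2=k2)
    params = PairPotentialParams(A=A, B=B, kappa1=k1, kappa2=k2,
                                 A_H=A_H if include_vdw else 0.0,
                                 R1=R, R2=R, include_vdw=include_vdw)
    return params, state
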