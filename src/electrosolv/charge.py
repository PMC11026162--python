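"""Surface ionization thermodynamics (charge regulation).

A surface carrying a single species of ionizable group (acid AH <-> A- + H+,
or base B + H+ <-> BH+) in contact with electrolyte regulates its charge: the
ionization fraction alpha depends on the local surface potential psi_s through
a Langmuir/Boltzmann isotherm, while psi_s in turn depends on the surface
charge density sigma through the diffuse-layer (Grahame) relation.  The
self-consistent pair (alpha, psi_s) and the regulation capacity d(alpha)/d(psi_s)
— maximal near half-ionization, vanishing at full (de)protonation — are the
quantities this module computes.  The regulation capacity is the model's
predictor of the long-ranged solvation-driven attraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .constants import E_CHARGE, EPS_0, T_DEFAULT, kBT
from .solution import ScreeningState, SolutionConditions, debye_length

__all__ = [
    "IonizableSurface",
    "SurfaceState",
    "SURFACE_PRESETS",
    "ionization_fraction",
    "regulation_capacity",
    "normalized_regulation_capacity",
    "grahame_sigma",
    "solve_surface_state",
]

_PSI_BRACKET = 0.5       # V, bisection bracket half-width
_PSI_TOL = 1e-12         # V


@dataclass(frozen=True)
class IonizableSurface:
    """Particle surface chemistry.

    site_density is the effective areal density of regulating groups (1/m^2)
    for extended surfaces, or None for molecular spheres where n_sites (groups
    per particle) is used instead.
    """

    group_type: str                  # "acid" | "base"
    pK: float
    site_density: float | None = None
    n_sites: float | None = None
    radius: float | None = None      # m
    label: str = ""

    def __post_init__(self):
        if self.group_type not in ("acid", "base"):
            raise ValueError("group_type must be 'acid' or 'base'")
        if not math.isfinite(self.pK):
            raise ValueError("pK must be finite")
        if self.site_density is not None and self.site_density < 0:
            raise ValueError("site_density must be >= 0")

    @property
    def sign(self) -> int:
        """Sign of the (maximal) surface charge: -1 acid, +1 base."""
        return -1 if self.group_type == "acid" else +1


@dataclass(frozen=True)
class SurfaceState:
    psi_s: float          # V
    sigma: float          # C/m^2
    alpha: float          # ionization fraction in [0, 1]
    dalpha_dpsi: float    # 1/V, signed (+ acid, - base)

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


def _load_surface_presets() -> dict[str, IonizableSurface]:
    text = resources.files("electrosolv.data").joinpath("surfaces.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: IonizableSurface(
            group_type=d["group_type"], pK=float(d["pK"]),
            site_density=float(d["site_density_per_m2"]), label=name,
        )
        for name, d in raw.items()
    }


SURFACE_PRESETS: dict[str, IonizableSurface] = _load_surface_presets()


def ionization_fraction(pH: float, pK: float, psi_s: float,
                        group_type: str = "acid", T: float = T_DEFAULT) -> float:
    """Langmuir/Boltzmann ionization isotherm.

    acid:  alpha = [1 + 10^(pK-pH) exp(-e psi_s / kT)]^-1
    base:  alpha = [1 + 10^(pH-pK) exp(+e psi_s / kT)]^-1
    """
    psi_hat = E_CHARGE * psi_s / kBT(T)
    if group_type == "acid":
        expo = (pK - pH) * math.log(10.0) - psi_hat
    elif group_type == "base":
        expo = (pH - pK) * math.log(10.0) + psi_hat
    else:
        raise ValueError("group_type must be 'acid' or 'base'")
    # saturates smoothly at 0/1 for extreme arguments
    if expo > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(expo))


def regulation_capacity(alpha: float, T: float = T_DEFAULT,
                        group_type: str = "acid") -> float:
    """d(alpha)/d(psi_s) at fixed pH: (e/kT) alpha (1-alpha), signed.

    Positive for acids (raising psi_s promotes deprotonation), negative for
    bases; zero at alpha in {0, 1}; maximal magnitude at alpha = 1/2.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    mag = (E_CHARGE / kBT(T)) * alpha * (1.0 - alpha)
    return mag if group_type == "acid" else -mag


def normalized_regulation_capacity(alpha: float) -> float:
    """4 alpha (1-alpha): unit-maximum variant used for pH-trend comparisons."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return 4.0 * alpha * (1.0 - alpha)


def grahame_sigma(psi_s: float, screening: ScreeningState, eps_r: float,
                  T: float = T_DEFAULT) -> float:
    """Grahame relation for a 1:1 electrolyte.

    sigma = 2 eps_r eps0 kappa (kT/e) sinh(e psi_s / 2 kT); odd in psi_s.
    """
    kT = kBT(T)
    return (2.0 * eps_r * EPS_0 * screening.kappa * kT / E_CHARGE
            * math.sinh(E_CHARGE * psi_s / (2.0 * kT)))


def _sphere_psi(q_p: float, R: float, screening: ScreeningState,
                eps_r: float) -> float:
    """Linearized-PB (Debye-Hueckel) potential of a sphere of charge q_p."""
    return q_p / (4.0 * math.pi * eps_r * EPS_0 * R * (1.0 + screening.kappa * R))


def solve_surface_state(surface: IonizableSurface,
                        conditions: SolutionConditions) -> SurfaceState:
    """Self-consistent surface state of a charged plate or molecular sphere.

    For extended surfaces (site_density set) solves

        grahame_sigma(psi_s) = sign * e * Gamma * alpha(psi_s)

    by bracketed bisection on psi_s in [-0.5, 0.5] V; for molecular spheres
    (n_sites set) solves the Debye-Hueckel sphere closure
    psi_s = q_p / (4 pi eps eps0 R (1 + kappa R)) with q_p = sign e N alpha.
    """
    scr = debye_length(conditions)
    s_e = surface.sign
    T = conditions.T

    def alpha_of(psi):
        return ionization_fraction(conditions.pH, surface.pK, psi,
                                   surface.group_type, T)

    if surface.n_sites is not None:
        if surface.radius is None or surface.radius <= 0:
            raise ValueError("molecular sphere requires a positive radius")

        def resid(psi):
            q = s_e * E_CHARGE * surface.n_sites * alpha_of(psi)
            return psi - _sphere_psi(q, surface.radius, scr, conditions.eps_r)

        area = 4.0 * math.pi * surface.radius**2
    else:
        if surface.site_density is None:
            raise ValueError("surface requires site_density or n_sites")
        gamma = surface.site_density

        def resid(psi):
            return (grahame_sigma(psi, scr, conditions.eps_r, T)
                    - s_e * E_CHARGE * gamma * alpha_of(psi))

        area = None

    lo, hi = (-_PSI_BRACKET, 0.0) if s_e < 0 else (0.0, _PSI_BRACKET)
    if surface.site_density == 0 or surface.n_sites == 0:
        psi = 0.0
    else:
        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo == 0.0:
            psi = lo
        elif r_hi == 0.0:
            psi = hi
        else:
            assert r_lo * r_hi < 0, (
                "no sign-consistent bracket for the surface-state residual; "
                "inputs are unphysical")
            psi = brentq(resid, lo, hi, xtol=_PSI_TOL)

    alpha = alpha_of(psi)
    if area is not None:
        sigma = (s_e * E_CHARGE * surface.n_sites * alpha) / area
    else:
        sigma = s_e * E_CHARGE * surface.site_density * alpha
    return SurfaceState(
        psi_s=psi, sigma=sigma, alpha=alpha,
        dalpha_dpsi=regulation_capacity(alpha, T, surface.group_type),
    )
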