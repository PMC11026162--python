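"""Molecular-scale condensation model: charge-regulated protein spheres.

A minimal protein model — a sphere of radius R = 2.5 nm carrying five
ionizable glutamate-like acidic groups (pK 4.5) — is titrated
self-consistently against the electrolyte (Langmuir-Boltzmann isotherm plus
linearized-PB sphere potential), and the pair interaction energy of two such
molecules is evaluated at a nominal intersurface separation x = 1 nm:

    u_DLVO  = screened-Coulomb (Yukawa) repulsion + molecular vdW,
    u_tot*  = u_DLVO + u_int,

where u_int is the interfacial-solvation contribution (attractive for acidic
molecules in water).  Applying a droplet-formation threshold u <= u_c
(-0.63 kBT) over a (pH, c0) grid yields a coexistence map; in DLVO mode the
solvation term is dropped.

The solvation term reuses the same amplitude parameterization as the colloid
module; at molecular scale its amplitude constant and decay-length ratio are
calibrated jointly against the two printed landmarks of the coexistence
boundary (reaching c0 ~ 0.5 M at the acidic end and pH ~ 6.5 at the low-salt
end).  Everything else on the map is then a genuine model output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from skimage import measure

from .constants import E_CHARGE, EPS_0, kBT
from .charge import IonizableSurface, solve_surface_state
from .potential import effective_radius, vdw_energy
from .solution import SolutionConditions, debye_length

__all__ = ["ProteinModel", "PhaseMap", "protein_net_charge",
           "molecular_pair_energy", "coexistence_boundary", "U_C_DEFAULT"]

U_C_DEFAULT = -0.63        # kBT, droplet-formation threshold
X_CONTACT = 1e-9           # m, nominal intersurface separation

# calibration landmarks for the electrosolvation coexistence boundary:
# (pH, c0 in M) points the u = u_c contour must pass through
_LANDMARK_LOW_SALT = (6.5, 0.01)
_LANDMARK_HIGH_SALT = (5.5, 0.5)


@dataclass(frozen=True)
class ProteinModel:
    """Sphere-with-ionizable-groups protein surrogate."""

    R: float = 2.5e-9          # m
    n_sites: int = 5
    pK: float = 4.5
    group_type: str = "acid"
    A_H: float = 0.0           # molecular Hamaker constant, J (negligible at x = 1 nm)

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("need at least one ionizable site")
        if self.R <= 0:
            raise ValueError("radius must be positive")

    def surface(self) -> IonizableSurface:
        return IonizableSurface(group_type=self.group_type, pK=self.pK,
                                n_sites=self.n_sites, radius=self.R,
                                label="protein-sphere")


@dataclass
class PhaseMap:
    pH: np.ndarray             # grid axis
    c0: np.ndarray             # grid axis, mol/L
    u: np.ndarray              # (n_pH, n_c0) pair energy at contact, kBT
    u_c: float                 # kBT
    boundary: list[np.ndarray]  # contour polylines, columns (pH, c0)
    mode: str                  # "dlvo" | "electrosolvation"

    @property
    def condensed(self) -> np.ndarray:
        return self.u <= self.u_c

    def to_dataframe(self):
        import pandas as pd
        ph_g, c_g = np.meshgrid(self.pH, self.c0, indexing="ij")
        return pd.DataFrame({
            "pH": ph_g.ravel(), "c0_M": c_g.ravel(),
            "u_kBT": self.u.ravel(),
            "condensed": self.condensed.ravel().astype(int)})


def protein_net_charge(model: ProteinModel, conditions: SolutionConditions
                       ) -> float:
    """Net molecular charge q_p in units of e (in [-n_sites, 0] for acids)."""
    state = solve_surface_state(model.surface(), conditions)
    return model.surface().sign * model.n_sites * state.alpha


def _yukawa_repulsion(q_e: float, R: float, x: float,
                      conditions: SolutionConditions) -> float:
    """Screened-Coulomb repulsion of two identical spheres, in J.

    u = (q^2 / 4 pi eps eps0 r) (e^(kappa R)/(1+kappa R))^2 e^(-kappa r),
    r = 2R + x.
    """
    scr = debye_length(conditions)
    k = scr.kappa
    r = 2 * R + x
    q = q_e * E_CHARGE
    geom = (math.exp(k * R) / (1 + k * R)) ** 2
    return q * q / (4 * math.pi * conditions.eps_r * EPS_0 * r) \
        * geom * math.exp(-k * r)


@lru_cache(maxsize=8)
def _molecular_calibration(R: float, n_sites: int, pK: float, A_H: float,
                           u_c: float) -> tuple[float, float]:
    """(C_mol, kappa_ratio) such that u_tot*(landmarks) = u_c exactly."""
    model = ProteinModel(R=R, n_sites=n_sites, pK=pK, A_H=A_H)

    def parts(pH, c0, ratio):
        cond = SolutionConditions.for_solvent("water", c0=c0, pH=pH)
        kT = kBT(cond.T)
        state = solve_surface_state(model.surface(), cond)
        q_e = model.surface().sign * n_sites * state.alpha
        u_dlvo = _yukawa_repulsion(q_e, R, X_CONTACT, cond) / kT
        if A_H > 0:
            u_dlvo += vdw_energy(X_CONTACT, A_H, R, R) / kT
        scr = debye_length(cond)
        k2 = ratio * scr.kappa
        reff = effective_radius(R, R)
        cap = 4 * state.alpha * (1 - state.alpha)
        g = (2 * math.pi * reff / k2 * abs(cond.phi0) * abs(state.sigma)
             * cap * math.exp(-k2 * X_CONTACT)) / kT
        return u_dlvo, g

    def residual(ratio):
        u1, g1 = parts(*_LANDMARK_LOW_SALT, ratio)
        u2, g2 = parts(*_LANDMARK_HIGH_SALT, ratio)
        c = (u1 - u_c) / g1
        return (u2 - c * g2) - u_c

    ratio = brentq(residual, 0.01, 0.95, xtol=1e-10)
    u1, g1 = parts(*_LANDMARK_LOW_SALT, ratio)
    c_mol = (u1 - u_c) / g1
    return c_mol, ratio


def molecular_pair_energy(model: ProteinModel, conditions: SolutionConditions,
                          x: float = X_CONTACT) -> tuple[float, float, float]:
    """(u_DLVO, u_int, u_tot*) in kBT at intersurface separation x."""
    if x <= 0:
        raise ValueError("separation must be positive")
    kT = kBT(conditions.T)
    state = solve_surface_state(model.surface(), conditions)
    q_e = model.surface().sign * model.n_sites * state.alpha
    u_dlvo = _yukawa_repulsion(q_e, model.R, x, conditions) / kT
    if model.A_H > 0:
        u_dlvo += vdw_energy(x, model.A_H, model.R, model.R) / kT

    c_mol, ratio = _molecular_calibration(model.R, model.n_sites, model.pK,
                                          model.A_H, U_C_DEFAULT)
    scr = debye_length(conditions)
    k2 = ratio * scr.kappa
    reff = effective_radius(model.R, model.R)
    cap = 4 * state.alpha * (1 - state.alpha)
    mag = c_mol * (2 * math.pi * reff / k2 * abs(conditions.phi0)
                   * abs(state.sigma) * cap * math.exp(-k2 * x)) / kT
    # sign rule: attractive iff particle charge sign matches phi0 sign
    if state.sigma == 0 or conditions.phi0 == 0:
        u_int = 0.0
    else:
        u_int = -math.copysign(mag, state.sigma * conditions.phi0)
    return u_dlvo, u_int, u_dlvo + u_int


def coexistence_boundary(model: ProteinModel, pH_grid, c0_grid,
                         u_c: float = U_C_DEFAULT,
                         mode: str = "electrosolvation") -> PhaseMap:
    """Pair energy at x = 1 nm over a (pH, c0) grid with the u <= u_c region.

    mode="dlvo" drops the solvation term (classical expectation: no phase
    separation); mode="electrosolvation" uses u_tot*.
    """
    pH_grid = np.asarray(pH_grid, dtype=float)
    c0_grid = np.asarray(c0_grid, dtype=float)
    if pH_grid.size == 0 or c0_grid.size == 0:
        raise ValueError("empty grid")
    if mode not in ("dlvo", "electrosolvation"):
        raise ValueError("mode must be 'dlvo' or 'electrosolvation'")
    u = np.empty((pH_grid.size, c0_grid.size))
    for i, pH in enumerate(pH_grid):
        for j, c0 in enumerate(c0_grid):
            cond = SolutionConditions.for_solvent("water", c0=float(c0),
                                                  pH=float(pH))
            u_dlvo, u_int, u_tot = molecular_pair_energy(model, cond)
            u[i, j] = u_dlvo if mode == "dlvo" else u_tot

    boundary: list[np.ndarray] = []
    if np.isfinite(u_c) and u.min() <= u_c <= u.max():
        for contour in measure.find_contours(u, u_c):
            # contour columns are fractional grid indices (i=pH, j=c0)
            ph = np.interp(contour[:, 0], np.arange(pH_grid.size), pH_grid)
            # interpolate c0 on a log axis (grids are log-spaced in salt)
            logc = np.interp(contour[:, 1], np.arange(c0_grid.size),
                             np.log(c0_grid))
            boundary.append(np.column_stack([ph, np.exp(logc)]))
    return PhaseMap(pH=pH_grid, c0=c0_grid, u=u, u_c=u_c, boundary=boundary,
                    mode=mode)
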