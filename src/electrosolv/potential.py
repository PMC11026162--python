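"""The electrosolvation pair potential and its geometry.

The interaction between two charged spheres at intersurface separation x is
modelled as

    U(x) = A exp(-kappa1 x) + B exp(-kappa2 x) + U_vdW(x),

where A > 0 is the screened electrostatic (double-layer) repulsion amplitude,
B is the interfacial-solvation amplitude whose sign follows the sign rule

    sign(B) = -sign(sigma * phi0),

i.e. the solvation term is attractive exactly when the particle charge sign
matches the sign of the interfacial solvation potential phi0 of the solvent
(negative particles in water, positive particles in alcohols), and U_vdW is
the non-retarded Hamaker sphere-sphere attraction.  With kappa2 < kappa1 the
solvation term dominates at long range; when it is attractive the total
potential develops a minimum of depth w < 0 at separation x_min, typically
several Debye lengths out.

The closed-form inverse map (w, x_min) -> (A, B) used to seed Brownian-dynamics
inference runs is also provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .constants import E_CHARGE, EPS_0, T_DEFAULT, kBT
from .charge import SurfaceState, normalized_regulation_capacity
from .solution import ScreeningState, SolutionConditions

__all__ = [
    "PairPotentialParams",
    "PotentialCurve",
    "electrostatic_amplitude",
    "interfacial_amplitude",
    "vdw_energy",
    "total_potential",
    "params_from_minimum",
    "predict_mixture_clustering",
    "KAPPA_RATIO_DEFAULT",
]

KAPPA_RATIO_DEFAULT = 0.95   # kappa2 / kappa1


def effective_radius(R1: float, R2: float) -> float:
    if R1 <= 0 or R2 <= 0:
        raise ValueError("radii must be positive")
    return R1 * R2 / (R1 + R2)


@dataclass(frozen=True)
class PairPotentialParams:
    """Parameters of U(x) = A e^(-k1 x) + B e^(-k2 x) + U_vdW."""

    A: float                 # J, >= 0
    B: float                 # J, signed
    kappa1: float            # 1/m
    kappa2: float            # 1/m
    A_H: float = 0.0         # J
    R1: float = 0.0          # m
    R2: float = 0.0          # m
    include_vdw: bool = False

    def __post_init__(self):
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("decay constants must be positive")
        if self.A != 0 and self.B != 0 and not self.kappa1 > self.kappa2:
            raise ValueError("require kappa1 > kappa2 when both terms present")
        if self.include_vdw and (self.R1 <= 0 or self.R2 <= 0):
            raise ValueError("vdW term requires positive radii")

    def replace(self, **kw) -> "PairPotentialParams":
        return replace(self, **kw)

    def energy(self, x):
        """U(x) in J for x in m (scalar or array); domain x > 0."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("separation must be positive")
        u = self.A * np.exp(-self.kappa1 * x) + self.B * np.exp(-self.kappa2 * x)
        if self.include_vdw:
            u = u + vdw_energy(x, self.A_H, self.R1, self.R2)
        return u

    def force(self, x):
        """-dU/dx in N (positive = repulsive)."""
        x = np.asarray(x, dtype=float)
        f = (self.A * self.kappa1 * np.exp(-self.kappa1 * x)
             + self.B * self.kappa2 * np.exp(-self.kappa2 * x))
        if self.include_vdw:
            f = f - _vdw_denergy(x, self.A_H, self.R1, self.R2)
        return f


@dataclass(frozen=True)
class PotentialCurve:
    x: np.ndarray                 # m
    U: np.ndarray                 # J
    x_min: float | None           # m
    w: float | None               # J, <= 0 when present
    classification: str           # repulsive | attractive | non-monotonic


def electrostatic_amplitude(state: SurfaceState, screening: ScreeningState,
                            R1: float, R2: float, eps_r: float,
                            T: float = T_DEFAULT) -> float:
    """Derjaguin weak-overlap amplitude of the double-layer repulsion.

    A = 64 pi R_eff eps_r eps0 (kT/e)^2 tanh^2(e psi_s / 4 kT); zero iff
    psi_s = 0 and quadratic in psi_s for small potentials.
    """
    reff = effective_radius(R1, R2)
    kT = kBT(T)
    t = math.tanh(E_CHARGE * state.psi_s / (4.0 * kT))
    return 64.0 * math.pi * reff * eps_r * EPS_0 * (kT / E_CHARGE) ** 2 * t * t


def interfacial_amplitude(state: SurfaceState, conditions: SolutionConditions,
                          R1: float, R2: float, C_int: float = 1.0,
                          kappa2: float | None = None) -> float:
    """Amplitude B of the interfacial-solvation term.

    |B| = C_int * 2 pi R_eff * kappa2^-1 * |phi0| * |sigma| * 4 alpha(1-alpha)
    with sign(B) = -sign(sigma * phi0): attractive (B < 0) exactly when the
    particle charge sign matches the solvent's interfacial potential sign.
    The decay length kappa2^-1 closes the dimensions; C_int is the single
    dimensionless per-solvent calibration constant.  B vanishes with sigma,
    phi0, or the regulation capacity (alpha in {0, 1}).
    """
    from .solution import debye_length  # local import to avoid cycle at module load

    if kappa2 is None:
        kappa2 = KAPPA_RATIO_DEFAULT * debye_length(conditions).kappa
    reff = effective_radius(R1, R2)
    cap = normalized_regulation_capacity(state.alpha)
    mag = (C_int * 2.0 * math.pi * reff / kappa2
           * abs(conditions.phi0) * abs(state.sigma) * cap)
    if state.sigma == 0.0 or conditions.phi0 == 0.0:
        return 0.0
    return -math.copysign(mag, state.sigma * conditions.phi0)


def vdw_energy(x, A_H: float, R1: float, R2: float):
    """Non-retarded Hamaker sphere-sphere attraction at surface separation x.

    Full expression in the centre distance d = x + R1 + R2; strictly negative,
    tending to -A_H R_eff / (6 x) at close approach (equal spheres:
    -A_H R / (12 x)).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("separation must be positive")
    if R1 <= 0 or R2 <= 0:
        raise ValueError("radii must be positive")
    d2 = (x + R1 + R2) ** 2
    s_plus = d2 - (R1 + R2) ** 2      # = x (x + 2 R1 + 2 R2) > 0
    s_minus = d2 - (R1 - R2) ** 2
    u = -(A_H / 6.0) * (2 * R1 * R2 / s_plus + 2 * R1 * R2 / s_minus
                        + np.log(s_plus / s_minus))
    return u if u.shape else float(u)


def _vdw_denergy(x, A_H: float, R1: float, R2: float):
    """dU_vdW/dx (analytic)."""
    x = np.asarray(x, dtype=float)
    d = x + R1 + R2
    d2 = d * d
    s_plus = d2 - (R1 + R2) ** 2
    s_minus = d2 - (R1 - R2) ** 2
    dsdx = 2.0 * d
    du = -(A_H / 6.0) * dsdx * (
        -2 * R1 * R2 / s_plus**2 - 2 * R1 * R2 / s_minus**2
        + 1.0 / s_plus - 1.0 / s_minus)
    return du


def _exp2_xmin(A: float, B: float, k1: float, k2: float) -> float | None:
    """Interior stationary point of the two-exponential part, if any.

    Stationarity A k1 e^(-k1 x) = -B k2 e^(-k2 x) gives
    x_min = ln(A k1 / (-B k2)) / (k1 - k2), interior (x_min > 0) iff
    A k1 > |B| k2; otherwise U is monotone on x > 0.
    """
    if A > 0 and B < 0:
        arg = A * k1 / (-B * k2)
        if arg > 1.0:  # x_min > 0
            return math.log(arg) / (k1 - k2)
    return None


def total_potential(params: PairPotentialParams, x) -> PotentialCurve:
    """Evaluate U on a grid and locate/classify its interior minimum.

    The two-exponential minimum has the closed form
    x_min = ln(A kappa1 / (-B kappa2)) / (kappa1 - kappa2); with the vdW term
    on, this seed is refined by bounded scalar minimization.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
        raise ValueError("x grid must be strictly increasing, length >= 2")
    if np.any(x <= 0):
        raise ValueError("x grid must be positive")
    if params.A > 0 and params.B != 0 and params.kappa1 == params.kappa2:
        raise ValueError("degenerate decay: kappa1 == kappa2 with both terms")

    U = params.energy(x)
    xm = _exp2_xmin(params.A, params.B, params.kappa1, params.kappa2)
    if params.include_vdw:
        # refine (or find) the minimum numerically; vdW can create/shift it
        lo = x[0] if xm is None else xm / 2.0
        hi = x[-1] if xm is None else 2.0 * xm
        res = minimize_scalar(lambda t: float(params.energy(t)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        cand = float(res.x)
        # accept only a genuine interior minimum
        eps = (hi - lo) * 1e-6
        if lo + eps < cand < hi - eps and res.fun < min(
                float(params.energy(lo)), float(params.energy(hi)), 0.0):
            xm = cand
        elif xm is None:
            xm = None

    if xm is not None:
        w = float(params.energy(xm))
        if w < 0:
            return PotentialCurve(x=x, U=U, x_min=float(xm), w=w,
                                  classification="non-monotonic")
    # no interior minimum below zero
    if params.A == 0 and (params.B < 0 or (params.include_vdw and params.A_H > 0)):
        cls = "attractive"
    elif params.B < 0 or (params.include_vdw and params.A_H > 0):
        # attractive tail but no resolvable minimum on this model: still
        # classify by the dominant sign at long range
        cls = "attractive" if params.B < 0 else "repulsive"
    else:
        cls = "repulsive"
    return PotentialCurve(x=x, U=U, x_min=None, w=None, classification=cls)


def params_from_minimum(w: float, x_min: float, kappa1: float, kappa2: float,
                        **kw) -> PairPotentialParams:
    """Closed-form (A, B) such that U(x_min) = w and U'(x_min) = 0.

    A = [-w kappa2/(kappa1-kappa2)] e^(kappa1 x_min)  (> 0),
    B = [ w kappa1/(kappa1-kappa2)] e^(kappa2 x_min)  (< 0),
    giving U''(x_min) = -w kappa1 kappa2 > 0.
    """
    if w >= 0:
        raise ValueError("w must be negative")
    if x_min <= 0:
        raise ValueError("x_min must be positive")
    if not kappa1 > kappa2 > 0:
        raise ValueError("degenerate decay: require kappa1 > kappa2 > 0")
    dk = kappa1 - kappa2
    A = (-w * kappa2 / dk) * math.exp(kappa1 * x_min)
    B = (w * kappa1 / dk) * math.exp(kappa2 * x_min)
    return PairPotentialParams(A=A, B=B, kappa1=kappa1, kappa2=kappa2, **kw)


def predict_mixture_clustering(states: Sequence[SurfaceState],
                               threshold: float = 0.25) -> bool:
    """Chemical-logic rule for mixed-species cluster formation.

    Each like-charged species is binarized on its normalized regulation
    capacity 4 alpha(1-alpha) >= threshold; mixed hcp clusters are predicted
    when ANY species is in the charge-regulating regime (logical OR).
    Mixtures of oppositely charged species (hetero-aggregation) are out of
    scope and rejected.
    """
    if len(states) < 1:
        raise ValueError("need at least one species")
    signs = {int(math.copysign(1, s.sigma)) for s in states if s.sigma != 0}
    if len(signs) > 1:
        raise ValueError("mixed charge signs: hetero-aggregation regime "
                         "is not supported")
    return any(normalized_regulation_capacity(s.alpha) >= threshold
               for s in states)
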