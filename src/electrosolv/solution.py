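"""Solution-state bookkeeping: electrolyte conditions, Debye screening and
conversion of measured electrical conductivity to ionic strength.

The Debye length of a 1:1 electrolyte,

    kappa^2 = 2 e^2 N_A (1000 c0) / (eps_r eps_0 k_B T),

reduces in water at 298 K to the practitioner's shortcut
kappa^-1 [nm] ~= 0.304 / sqrt(c0 [M]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .constants import CP, E_CHARGE, EPS_0, K_B, N_A, T_DEFAULT, kBT

__all__ = [
    "Solvent",
    "SOLVENTS",
    "SolutionConditions",
    "ScreeningState",
    "debye_length",
    "conductivity_to_c0",
]

# Calibration slope for conductivity -> NaCl concentration (limiting molar
# conductivity of NaCl), S cm^2/mol.
LAMBDA_NACL = 126.4


@dataclass(frozen=True)
class Solvent:
    name: str
    eps_r: float
    eta: float          # Pa.s
    phi0: float         # V, signed


def _load_solvents() -> dict[str, Solvent]:
    text = resources.files("electrosolv.data").joinpath("solvents.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: Solvent(name=name, eps_r=d["eps_r"], eta=d["eta_cp"] * CP, phi0=d["phi0_v"])
        for name, d in raw.items()
    }


SOLVENTS: dict[str, Solvent] = _load_solvents()


def get_solvent(name: str) -> Solvent:
    try:
        return SOLVENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown solvent {name!r}; registered solvents: {sorted(SOLVENTS)}"
        ) from None


@dataclass(frozen=True)
class SolutionConditions:
    """State of the electrolyte a particle pair is immersed in.

    Parameters
    ----------
    c0 : monovalent salt concentration, mol/L
    pH : solution pH (for alcohols an effective value)
    T : absolute temperature, K
    eps_r : relative permittivity
    eta : dynamic viscosity, Pa.s
    phi0 : interfacial solvation potential, V (signed; negative for water,
        positive for ethanol/IPA unless explicitly overridden)
    solvent_name : registry label
    """

    c0: float
    pH: float = 7.0
    T: float = T_DEFAULT
    eps_r: float = 78.5
    eta: float = 0.89 * CP
    phi0: float = -0.15
    solvent_name: str = "water"

    def __post_init__(self):
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.eps_r < 1:
            raise ValueError("eps_r must be >= 1")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        solvent = SOLVENTS.get(self.solvent_name)
        if solvent is not None and self.phi0 * solvent.phi0 < 0:
            raise ValueError(
                f"phi0 sign ({self.phi0:+.3g} V) contradicts the registered "
                f"convention for {self.solvent_name!r} ({solvent.phi0:+.3g} V); "
                "use an unregistered solvent_name to override"
            )

    @classmethod
    def for_solvent(cls, name: str, c0: float, pH: float = 7.0,
                    T: float = T_DEFAULT, phi0: float | None = None
                    ) -> "SolutionConditions":
        s = get_solvent(name)
        return cls(c0=c0, pH=pH, T=T, eps_r=s.eps_r, eta=s.eta,
                   phi0=s.phi0 if phi0 is None else phi0, solvent_name=name)

    def with_(self, **kw) -> "SolutionConditions":
        return replace(self, **kw)


@dataclass(frozen=True)
class ScreeningState:
    """Derived screening quantities for a set of conditions."""

    kappa: float          # 1/m
    kappa_inv_nm: float   # nm
    kBT: float            # J

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def debye_length(conditions: SolutionConditions) -> ScreeningState:
    """Inverse Debye length of a 1:1 electrolyte from the full expression.

    At 298 K in water this agrees with 0.304/sqrt(c0) nm to better than 2%.
    """
    c = conditions
    n_bulk = 1000.0 * c.c0 * N_A                       # ions of each sign, 1/m^3
    kappa2 = 2 * E_CHARGE**2 * n_bulk / (c.eps_r * EPS_0 * K_B * c.T)
    kappa = math.sqrt(kappa2)
    return ScreeningState(kappa=kappa, kappa_inv_nm=1e9 / kappa, kBT=kBT(c.T))


def conductivity_to_c0(s: float, solvent: str = "water") -> float:
    """Convert electrical conductivity (S/m) to salt concentration (mol/L).

    Water uses the linear calibration c0 = s / Lambda_NaCl.  Alcohols use the
    same aqueous calibration line with the inferred concentration multiplied
    by eta_solvent/eta_water (Walden-style viscosity correction).
    """
    if s < 0:
        raise ValueError("conductivity must be non-negative")
    sv = get_solvent(solvent)
    lam_si = LAMBDA_NACL * 1e-4                        # S m^2 / mol
    c0_water_mol_m3 = s / lam_si
    c0 = c0_water_mol_m3 / 1000.0                      # mol/L
    if solvent != "water":
        c0 *= sv.eta / SOLVENTS["water"].eta
    return c0
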