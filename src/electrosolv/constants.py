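"""Physical constants (SI, CODATA 2018) and thermal-energy helpers.

Internal unit system is SI throughout the package (m, J, V, C, s); user-facing
helpers convert to the reporting units used in the colloid literature
(nm, um, k_BT, mV, mol/L).
"""

import math

E_CHARGE = 1.602176634e-19     # C
K_B = 1.380649e-23             # J/K
N_A = 6.02214076e23            # 1/mol
EPS_0 = 8.8541878128e-12       # F/m

T_DEFAULT = 298.0              # K

NM = 1e-9
UM = 1e-6
ZJ = 1e-21
CP = 1e-3                      # centipoise in Pa.s


def kBT(T: float = T_DEFAULT) -> float:
    """Thermal energy in J at absolute temperature T (K)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return K_B * T


def thermal_voltage(T: float = T_DEFAULT) -> float:
    """k_BT/e in volts (~25.7 mV at 298 K)."""
    return kBT(T) / E_CHARGE


def bjerrum_length(eps_r: float, T: float = T_DEFAULT) -> float:
    """Bjerrum length e^2/(4 pi eps k_BT) in m."""
    return E_CHARGE**2 / (4 * math.pi * eps_r * EPS_0 * kBT(T))
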