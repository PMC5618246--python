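"""Physical constants and unit conversions used across the package.

Internal conventions: lengths in nm, times in ps, charges in elementary
charges, voltages in V, currents in nA, conductance in nS, resistance in
MOhm, diffusion coefficients in m^2/s (SI, converted at the point of use),
conductivity in S/m.
"""

from scipy import constants as _const

#: Elementary charge, C
E_CHARGE = _const.elementary_charge
#: Boltzmann constant, J/K
K_B = _const.Boltzmann
#: Avogadro constant, 1/mol
N_AVOGADRO = _const.Avogadro

#: nm -> m
NM = 1e-9
#: ps -> s
PS = 1e-12

#: m^2/s -> nm^2/ps
D_SI_TO_NM2_PER_PS = 1e6
#: m/s -> nm/ps
V_SI_TO_NM_PER_PS = 1e-3

#: Current carried by one elementary charge crossing the full box per ps:
#: (e[C] * nm) / (ps * nm) expressed in nA.  One unit of
#: sum(q_i * dz_i) / (dt * Lz)  [e * nm / (ps * nm)]  equals this many nA.
CURRENT_UNIT_NA = E_CHARGE / PS / 1e-9  # = 160.2176634 nA

#: mol/L -> 1/m^3 (number density of a 1 molar species)
MOLAR_TO_PER_M3 = N_AVOGADRO * 1e3

#: mol/L -> 1/nm^3
MOLAR_TO_PER_NM3 = MOLAR_TO_PER_M3 * NM**3


def thermal_energy(temperature_k: float) -> float:
    """k_B * T in joules."""
    return K_B * temperature_k
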