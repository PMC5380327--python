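"""Unit conventions used throughout the package.

Lengths are nanometres, forces piconewtons, times seconds, energies
pN·nm, rates 1/s, spring constants pN/nm internally (files accept N/m
and convert at the boundary: 1 N/m = 1000 pN/nm).
"""

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K expressed in pN·nm).
BOLTZMANN_PN_NM = 1.380649e-2

#: Default bath temperature in K (room-temperature AFM).
DEFAULT_TEMPERATURE = 298.0

#: Conversion factor between N/m and pN/nm.
N_PER_M_TO_PN_PER_NM = 1000.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in pN·nm (4.114 pN·nm at 298 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_PN_NM * temperature
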