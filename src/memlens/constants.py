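"""Physical constants and unit conversions.

All lengths are nm, energies kJ/mol, times ns, masses amu (GRO / Martini
conventions). Derived units follow: areas nm^2, volumes nm^3, diffusion
nm^2/ns, compressibility kJ/(mol nm^2).
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083145

#: 1 kJ/(mol nm^2) expressed in mN/m
KJ_PER_MOL_NM2_TO_MN_PER_M = 1.6606

#: 1 nm^2/ns expressed in cm^2/s
NM2_PER_NS_TO_CM2_PER_S = 1e-5


def thermal_energy(temperature: float) -> float:
    """kB*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
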