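"""Package-wide physical constants and default simulation parameters.

Units are fixed across the package: energies in kcal/mol, lengths in
angstrom, masses in amu, times in ps (timesteps are specified in fs for
convenience and converted internally), temperatures in K.
"""

#: Boltzmann constant [kcal mol^-1 K^-1]
KB = 0.0019872

#: Conversion factor: 1 kcal/mol = 418.4 amu A^2 ps^-2
KCAL_PER_MOL_TO_AMU_A2_PS2 = 418.4

#: Default thermostat temperature [K]
DEFAULT_TEMPERATURE = 310.0

#: Default Langevin collision frequency [ps^-1]
DEFAULT_FRICTION = 2.0

#: Default integration timestep [fs]
DEFAULT_TIMESTEP = 1.0


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB * temperature
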