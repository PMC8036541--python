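"""Package-wide physical constants and unit conventions.

Units everywhere: energies in kcal/mol, lengths in nm, temperatures in K,
MC displacements in nm, Langevin timestep in ps.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB = 0.0019872041


def kt(temperature: float) -> float:
    """k_B * T in kcal/mol for a temperature in Kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
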