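"""Package-wide physical constants and unit conventions.

Units everywhere: length in Angstrom, energy in kcal/mol, charge in
elementary charges, temperature in Kelvin, angles in radians.

Bond and angle energies follow the force-field convention U = K (x - x0)**2
WITHOUT the 1/2 prefactor.  The Drude spring is the one exception: its
self-energy is U = (1/2) k_D d**2 so that the charge-on-spring relations
alpha = q_D**2 / k_D and d = q_D E / k_D hold exactly.
"""

#: Coulomb constant, kcal*Angstrom/(mol*e^2)
COULOMB_K = 332.0716

#: Boltzmann constant, kcal/(mol*K)
KB = 0.0019872041

#: Temperature (K) at which beta = 1/(k_B T) equals exactly 1 mol/kcal.
#: Convenient for unit-reduced statistical tests.
UNIT_REDUCED_TEMPERATURE = 1.0 / KB

LEVEL_MM = "MM"
LEVEL_MM_PRIME = "MM'"
LEVEL_TARGET = "TARGET"
VALID_LEVELS = (LEVEL_MM, LEVEL_MM_PRIME, LEVEL_TARGET)


def beta_from_temperature(temperature: float) -> float:
    """Return beta = 1/(k_B T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
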