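"""Physical constants in the dataset unit system (kcal/mol, elementary charge, Å)."""

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Default temperature for hydration free energies, K.
DEFAULT_TEMPERATURE_K = 298.15

#: Coulomb constant, kcal Å mol^-1 e^-2.
COULOMB_KCAL_ANG_E2 = 332.0637


def beta_from_temperature(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse thermal energy beta = 1/(kB*T) in mol kcal^-1.

    At 298.15 K, kB*T = 0.5925 kcal/mol and beta = 1.688 mol/kcal.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1.0 / (KB_KCAL_PER_MOL_K * temperature_k)
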