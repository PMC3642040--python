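"""Physical constants and unit conventions.

Internal length unit is nm everywhere; Angstrom appears only at PDB I/O and
in user-facing reports. Energies are kJ/mol, times ps, temperatures K.
"""

#: Boltzmann constant in kJ mol^-1 K^-1
KB = 0.0083145

#: Default simulation temperature (K)
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kB*T in kJ/mol (2.5775 kJ/mol at 310 K)."""
    return KB * temperature


#: nm -> Angstrom
NM_TO_ANG = 10.0
ANG_TO_NM = 0.1
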