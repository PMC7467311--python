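"""Physical constants and unit conversions used throughout the package.

Unit policy: lengths in nm, pressures in bar on input (converted to Pa),
stiffnesses in kBT/nm^2, moduli in GPa, energies in kJ/mol or kBT.
"""

KB = 1.380649e-23  # Boltzmann constant, J/K
NA = 6.02214076e23  # Avogadro constant, 1/mol
BAR_TO_PA = 1.0e5
DEFAULT_TEMPERATURE = 300.0  # K

#: Effective protofilament cross-section area, nm^2. Derived from the
#: mass-per-unit-length constraint m = rho * A_z * L_z,eq with m = 100 kDa,
#: rho = 1.41 g/cm^3, L_z,eq = 8.31 nm; used for stress <-> force conversion.
A_Z_NM2 = 14.2


def kbt_joule(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kBT in joule."""
    return KB * temperature


def kbt_kj_per_mol(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kBT in kJ/mol (2.494 kJ/mol at 300 K)."""
    return KB * NA * temperature / 1000.0
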