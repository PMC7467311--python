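"""Continuum-mechanics layer: cross-section, strain energy, rigidity.

Maps the per-dimer elastic description of a protofilament (PF) onto the
hollow-cylinder continuum picture of the microtubule (MT): effective PF
cross-section from mass per unit length, per-dimer elastic strain energy,
MT outer radius and second moment of area as a function of PF number,
flexural rigidity E*I, and the inverse-variance consensus of experimental
bending-stiffness measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import NA, kbt_kj_per_mol

__all__ = [
    "ContinuumConstants", "Measurement",
    "cross_section_area", "strain_energy", "outer_radius",
    "second_moment", "bending_stiffness", "ivw_consensus",
    "load_ei_table",
]


@dataclass(frozen=True)
class ContinuumConstants:
    """Mass/geometry constants of the continuum MT model.

    m: mass per PF unit length per dimer (kDa); rho: protein mass density
    (g/cm^3, globular-protein value); R_in: inner MT radius (nm, 14_3 MT);
    T: temperature (K).
    """

    m: float = 100.0
    rho: float = 1.41
    R_in: float = 10.19
    T: float = 300.0

    def __post_init__(self):
        if min(self.m, self.rho, self.R_in, self.T) <= 0:
            raise ValueError("all continuum constants must be positive")


@dataclass(frozen=True)
class Measurement:
    """One experimental value with its standard deviation (same units)."""

    y: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def _mass_nm3(m_kda: float, rho_g_cm3: float) -> float:
    """m / rho in nm^3: kDa -> g via 1 Da = 1 g/mol; 1 cm^3 = 1e21 nm^3."""
    mass_g = m_kda * 1000.0 / NA
    rho_g_nm3 = rho_g_cm3 * 1e-21
    return mass_g / rho_g_nm3


def cross_section_area(m: float = 100.0, rho: float = 1.41,
                       L_z_eq: float = 8.31) -> float:
    """Effective PF cross-section A_z (nm^2) from m = rho * A_z * L_z,eq."""
    if min(m, rho, L_z_eq) <= 0:
        raise ValueError("all inputs must be positive")
    return _mass_nm3(m, rho) / L_z_eq


def strain_energy(E: float, eps: float, A_z: float, L_z_eq: float,
                  T: float = 300.0) -> tuple[float, float]:
    """Per-dimer elastic strain energy for axial strain ``eps``.

    Hooke's-law energy density 1/2 * E * eps^2 times the effective dimer
    volume V = A_z * L_z,eq. Returns (kJ/mol, kBT at ``T``); ``E`` in GPa,
    lengths in nm.
    """
    if min(E, A_z, L_z_eq, T) <= 0:
        raise ValueError("E, A_z, L_z_eq and T must be positive")
    g_el = 0.5 * E * 1e9 * eps**2            # J/m^3
    volume_m3 = A_z * L_z_eq * 1e-27         # nm^3 -> m^3
    joule = g_el * volume_m3
    kj_mol = joule * NA / 1000.0
    return kj_mol, kj_mol / kbt_kj_per_mol(T)


def outer_radius(n_pf: int, constants: ContinuumConstants = ContinuumConstants(),
                 L_z_eq: float = 8.31) -> float:
    """Outer MT radius (nm) from n_pf * m = rho * pi * (R_out^2 - R_in^2) * L."""
    if n_pf < 1:
        raise ValueError("n_pf must be >= 1")
    area = n_pf * _mass_nm3(constants.m, constants.rho) / (np.pi * L_z_eq)
    return float(np.sqrt(constants.R_in**2 + area))


def second_moment(R_in: float, R_out: float) -> float:
    """Second moment of the annular cross-section, pi/4 (R_out^4 - R_in^4), m^4.

    Radii in nm.
    """
    if R_in < 0 or R_out < R_in:
        raise ValueError("require R_out >= R_in >= 0")
    return float(np.pi / 4.0 * (R_out**4 - R_in**4) * 1e-36)


def bending_stiffness(E: float, I: float) -> float:
    """Flexural rigidity E*I in N m^2 (E in GPa, I in m^4)."""
    if E <= 0 or I <= 0:
        raise ValueError("E and I must be positive")
    return E * 1e9 * I


def ivw_consensus(measurements: Sequence[Measurement]) -> Measurement:
    """Inverse-variance weighted consensus of independent measurements.

    y_hat = sum(w_i y_i) / sum(w_i), sd_hat = 1/sqrt(sum(w_i)) with
    w_i = 1/sd_i^2. The consensus sd is never larger than the smallest
    input sd and the mean lies within the data range.
    """
    if len(measurements) == 0:
        raise ValueError("need at least one measurement")
    w = np.array([1.0 / m.sd**2 for m in measurements])
    y = np.array([m.y for m in measurements])
    return Measurement(y=float(np.sum(w * y) / np.sum(w)),
                       sd=float(1.0 / np.sqrt(np.sum(w))))


def load_ei_table(path=None) -> pd.DataFrame:
    """Load a bending-stiffness measurement table (CSV).

    Columns: study_key, nucleotide_or_treatment, EI_value, EI_sd (both in
    1e-24 N m^2), method. Without ``path`` the packaged synthetic example
    table is returned (representative magnitudes for thermal-fluctuation
    measurements, not transcribed literature values).
    """
    if path is None:
        ref = resources.files("pflattice.data") / "experimental_ei_synthetic.csv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def consensus_from_table(table: pd.DataFrame, group: str) -> Measurement:
    """Inverse-variance consensus for one nucleotide/treatment group."""
    sub = table[table["nucleotide_or_treatment"] == group]
    if sub.empty:
        raise ValueError(f"no measurements for group {group!r}")
    ms = [Measurement(y=row.EI_value, sd=row.EI_sd)
          for row in sub.itertuples()]
    return ivw_consensus(ms)
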