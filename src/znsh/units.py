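"""Physical constants and unit conversions.

Internal working units throughout the package are Hartree atomic units
(Hartree, Bohr, atomic time unit, electron mass).  User-facing I/O uses
the conventional chemistry units kcal/mol, Angstrom, femtosecond and amu.
"""

from __future__ import annotations

# Energy
HARTREE_TO_KCALMOL = 627.509474
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL
HARTREE_TO_EV = 27.211386245988
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

# Length
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# Time
FS_TO_AU = 41.341374575751
AU_TO_FS = 1.0 / FS_TO_AU

# Mass
AMU_TO_ME = 1822.888486209
ME_TO_AMU = 1.0 / AMU_TO_ME

# Vibrational frequency: wavenumber (cm^-1) <-> angular frequency (a.u.)
CM1_TO_AU = 1.0 / 219474.6313632
AU_TO_CM1 = 219474.6313632

# Photon energy/wavelength product: hc in eV*nm
HC_EV_NM = 1239.841984


def ev_to_nm(energy_ev: float) -> float:
    """Convert a photon energy in eV to its vacuum wavelength in nm.

    lambda = hc / E with hc = 1239.841984 eV nm.  Rounding to integer
    nanometres is left to the caller (presentation concern).
    """
    if not energy_ev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Convert a vacuum wavelength in nm to photon energy in eV."""
    if not wavelength_nm > 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_EV_NM / wavelength_nm
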