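"""Physical constants, atomic data and pipeline-wide defaults.

Internal unit system: lengths in Angstrom, masses in amu, force constants in
mdyn/A.  With these units a harmonic wavenumber is

    nu~ [cm^-1] = WAVENUMBER_CONVERSION * sqrt(lambda [mdyn A^-1 amu^-1])

where lambda is an eigenvalue of the mass-weighted Hessian.
"""

from __future__ import annotations

# sqrt(mdyn/(A*amu)) -> cm^-1
WAVENUMBER_CONVERSION = 1302.79

# h*c/k_B in cm*K: Boltzmann exponent is HC_OVER_KB * nu~ / T
HC_OVER_KB = 1.438777

# 532 nm laser excitation expressed in wavenumbers
DEFAULT_EXCITATION_WAVENUMBER = 18797.0  # cm^-1

DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_FWHM = 10.0  # cm^-1, Lorentzian full width at half maximum
DEFAULT_FREEZE_BELOW = 100.0  # cm^-1, low-frequency modes frozen in partial opt

# similarity-factor integration windows (cm^-1)
RAMAN_ROA_RANGE = (230.0, 1800.0)
IR_VCD_RANGE = (1250.0, 1800.0)

ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "S": 32.06,
}

COVALENT_RADII = {
    "H": 0.31,
    "D": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "Na": 1.66,
    "S": 1.05,
}

# backbone torsion restraint emission (flat-bottom width and force constant)
RESTRAINT_FLAT_WIDTH = 5.0  # degrees, r1/r4 half width
RESTRAINT_FORCE_CONSTANT = 128.0  # kcal/mol, rk2 = rk3
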