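"""Per-mode IR, VCD, Raman and ROA band intensities.

IR dipole strengths and VCD rotational strengths follow from the atomic
polar and axial tensors contracted along each normal coordinate; Raman and
ROA backscattering SCP intensities follow from the far-from-resonance
(Placzek) invariants a^2, beta(alpha)^2, beta(G')^2 and beta(A)^2 built from
the normal-coordinate derivatives of alpha, G' and A.  Absolute cross
sections are not calibrated: each spectroscopy carries one documented global
constant, and all scientific checks are sign-, ratio- and
invariance-based.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .cct import PropertySet, EPS
from .harmonic import NormalModes
from .constants import HC_OVER_KB, DEFAULT_TEMPERATURE


class IntensityError(ValueError):
    pass


#: global proportionality constants (arbitrary units per spectroscopy)
K_IR = 100.0
K_VCD = 100.0
K_RAMAN = 1.0e-14
K_ROA = 1.0e-14


@dataclasses.dataclass
class BandSet:
    """Stick bands (wavenumber, intensity) of one spectroscopy."""

    spectroscopy: str  # IR | VCD | Raman | ROA
    wavenumbers: np.ndarray
    intensities: np.ndarray
    polarization_scheme: str | None = None  # SCP_180 for Raman/ROA
    temperature: float | None = None
    excitation_wavenumber: float | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.spectroscopy not in ("IR", "VCD", "Raman", "ROA"):
            raise IntensityError(f"unknown spectroscopy {self.spectroscopy!r}")
        if self.wavenumbers.shape != self.intensities.shape:
            raise IntensityError("band arrays have mismatched shapes")


def mode_derivatives(modes: NormalModes, tensor_derivatives: np.ndarray) -> np.ndarray:
    """Contract per-atom Cartesian derivatives along each normal coordinate.

    tensor_derivatives has shape (n_atoms, 3, *rest): (dT/dx_{a,kappa})
    with the derivative indices first.  Returns (n_modes, *rest):
    T'_i = sum_{a,kappa} dT/dx_{a,kappa} S^a_{kappa,i}.
    """
    arr = np.asarray(tensor_derivatives, dtype=float)
    disp = modes.displacements
    if arr.shape[:2] != disp.shape[1:]:
        raise IntensityError(
            f"derivative array shape {arr.shape} does not match "
            f"{disp.shape[1]} atoms"
        )
    return np.tensordot(disp, arr, axes=([1, 2], [0, 1]))


def _mode_selection(modes: NormalModes, min_wavenumber: float | None) -> np.ndarray:
    if min_wavenumber is None:
        return np.ones(modes.n_modes, dtype=bool)
    return modes.wavenumbers >= min_wavenumber


def ir_vcd_intensities(
    modes: NormalModes, props: PropertySet, min_wavenumber: float | None = 20.0
) -> tuple[BandSet, BandSet | None]:
    """Dipole strengths D_i = |dmu/dQ_i|^2 and rotational strengths
    R_i = (dmu/dQ_i) . (dm/dQ_i).

    Returns (IR, VCD); VCD is None when the atomic axial tensors are
    missing.  Mirroring geometry and tensors together flips every R_i and
    leaves every D_i unchanged.  Modes below min_wavenumber (quasi-rigid
    and floppy torsional remnants, whose harmonic treatment is meaningless)
    are excluded; pass None to keep all modes, e.g. for sum-rule checks.
    """
    if props.apt is None:
        raise IntensityError("APT required for IR intensities")
    sel = _mode_selection(modes, min_wavenumber)
    # apt[a, alpha, beta] with beta the derivative coordinate -> move beta first
    mu = mode_derivatives(modes, np.swapaxes(props.apt, 1, 2))[sel]  # (modes, 3)
    d_strength = K_IR * np.einsum("ix,ix->i", mu, mu)
    ir = BandSet("IR", modes.wavenumbers[sel].copy(), d_strength)
    if props.aat is None:
        return ir, None
    m = mode_derivatives(modes, np.swapaxes(props.aat, 1, 2))[sel]
    r_strength = K_VCD * np.einsum("ix,ix->i", mu, m)
    return ir, BandSet("VCD", modes.wavenumbers[sel].copy(), r_strength)


def boltzmann_factor(wavenumber: float | np.ndarray, temperature: float) -> np.ndarray:
    """Vibrational population factor 1 / (1 - exp(-h c nu~ / k T))."""
    x = HC_OVER_KB * np.asarray(wavenumber, float) / temperature
    return 1.0 / (1.0 - np.exp(-x))


def scattering_prefactor(
    mode_wavenumber: np.ndarray, excitation_wavenumber: float, temperature: float
) -> np.ndarray:
    """Harmonic Stokes scattering prefactor: fourth power of the scattered
    wavenumber over the mode wavenumber, times the Boltzmann population
    factor."""
    nu = np.asarray(mode_wavenumber, float)
    safe = np.where(nu > 1e-6, nu, np.inf)
    return ((excitation_wavenumber - nu) ** 4 / safe) * boltzmann_factor(
        np.where(nu > 1e-6, nu, 1.0), temperature
    )


def raman_invariants(alpha_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic a and anisotropy beta(alpha)^2 per mode from the
    mode-contracted alpha derivatives (n_modes, 3, 3)."""
    a = np.trace(alpha_p, axis1=1, axis2=2) / 3.0
    tr = 3.0 * a
    beta2 = 0.5 * (3.0 * np.einsum("iab,iab->i", alpha_p, alpha_p) - tr * tr)
    return a, beta2


def roa_invariants(
    alpha_p: np.ndarray, gprime_p: np.ndarray, a_p: np.ndarray,
    excitation_wavenumber: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mixed invariants beta(G')^2 and beta(A)^2 per mode."""
    tr_a = np.trace(alpha_p, axis1=1, axis2=2)
    tr_g = np.trace(gprime_p, axis1=1, axis2=2)
    beta_g = 0.5 * (3.0 * np.einsum("iab,iab->i", alpha_p, gprime_p) - tr_a * tr_g)
    beta_a = 0.5 * excitation_wavenumber * np.einsum(
        "iab,agd,igdb->i", alpha_p, EPS, a_p
    )
    return beta_g, beta_a


def raman_roa_intensities(
    modes: NormalModes,
    props: PropertySet,
    scheme: str = "SCP_180",
    temperature: float = DEFAULT_TEMPERATURE,
    min_wavenumber: float | None = 20.0,
) -> tuple[BandSet, BandSet | None]:
    """Backscattering SCP Raman (I_R + I_L) and ROA (I_R - I_L) bands.

    Raman ~ K * (45 a^2 + 7 beta(alpha)^2); ROA ~ K' * (48 beta(G')^2 +
    16 beta(A)^2); both are multiplied by the harmonic scattering prefactor
    and the Boltzmann population factor.  ROA is None when the chiral
    tensors (G', A derivatives) are missing.  Modes below min_wavenumber are
    excluded (their Stokes prefactor diverges harmonically).
    """
    if scheme != "SCP_180":
        raise IntensityError(f"unsupported polarization scheme {scheme!r}")
    if props.dalpha is None:
        raise IntensityError("alpha derivatives required for Raman intensities")
    exc = props.excitation_wavenumber
    sel = _mode_selection(modes, min_wavenumber)
    nu = modes.wavenumbers[sel]
    alpha_p = mode_derivatives(modes, props.dalpha)[sel]
    a, beta2 = raman_invariants(alpha_p)
    pref = scattering_prefactor(nu, exc, temperature)
    raman = K_RAMAN * pref * (45.0 * a * a + 7.0 * beta2)
    raman_bs = BandSet("Raman", nu.copy(), raman,
                       polarization_scheme=scheme, temperature=temperature,
                       excitation_wavenumber=exc)
    if props.dgprime is None or props.da is None:
        return raman_bs, None
    gprime_p = mode_derivatives(modes, props.dgprime)[sel]
    a_p = mode_derivatives(modes, props.da)[sel]
    beta_g, beta_a = roa_invariants(alpha_p, gprime_p, a_p, exc)
    roa = K_ROA * pref * (48.0 * beta_g + 16.0 * beta_a) / exc
    roa_bs = BandSet("ROA", nu.copy(), roa,
                     polarization_scheme=scheme, temperature=temperature,
                     excitation_wavenumber=exc)
    return raman_bs, roa_bs


# ---------------------------------------------------------------------------
# stick-band serialization
# ---------------------------------------------------------------------------

def write_bands(bands: BandSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# voasim stick bands\n# spectroscopy {bands.spectroscopy}\n")
        if bands.polarization_scheme:
            fh.write(f"# scheme {bands.polarization_scheme}\n")
        for nu, inten in zip(bands.wavenumbers, bands.intensities):
            fh.write(f"{nu:16.8f} {inten:20.12e} {bands.spectroscopy}\n")


def read_bands(path: str) -> BandSet:
    spectroscopy = None
    scheme = None
    nus, ints = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["spectroscopy"]:
                    spectroscopy = parts[1]
                elif parts[:1] == ["scheme"]:
                    scheme = parts[1]
                continue
            parts = line.split()
            if len(parts) >= 2:
                nus.append(float(parts[0]))
                ints.append(float(parts[1]))
                if spectroscopy is None and len(parts) >= 3:
                    spectroscopy = parts[2]
    if spectroscopy is None:
        raise IntensityError(f"{path}: no spectroscopy tag found")
    return BandSet(spectroscopy, np.array(nus), np.array(ints),
                   polarization_scheme=scheme)
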