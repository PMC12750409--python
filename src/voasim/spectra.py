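"""Continuous spectra: broadening, scaling, averaging, background
subtraction and the normalized-overlap similarity factor.

Stick bands become smooth spectra by superposing unit-area Lorentzians
(default FWHM 10 cm^-1).  Two spectra are compared with

    s = Int S1 S2 dw / sqrt(Int S1^2 dw * Int S2^2 dw)

over a stated wavenumber window (defaults: 230-1800 cm^-1 for Raman/ROA,
1250-1800 cm^-1 for IR/VCD), a Cauchy-Schwarz-bounded score in [-1, 1] that
is invariant under positive rescaling of either spectrum.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .intensities import BandSet
from .constants import RAMAN_ROA_RANGE, IR_VCD_RANGE


class SpectrumError(ValueError):
    pass


DEFAULT_RANGES = {
    "Raman": RAMAN_ROA_RANGE,
    "ROA": RAMAN_ROA_RANGE,
    "IR": IR_VCD_RANGE,
    "VCD": IR_VCD_RANGE,
}


@dataclasses.dataclass
class Spectrum:
    """Intensity on a strictly increasing wavenumber grid."""

    grid: np.ndarray
    values: np.ndarray
    spectroscopy: str = "Raman"
    provenance: str = "calculated"  # calculated | reference | synthetic
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise SpectrumError("grid must be strictly increasing with >= 2 points")
        if self.values.shape != self.grid.shape:
            raise SpectrumError("values must match the grid")
        if not np.all(np.isfinite(self.values)):
            raise SpectrumError("spectrum values must be finite")

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid.copy(), self.values.copy(),
                        self.spectroscopy, self.provenance, dict(self.meta))


def default_grid(lo: float = 50.0, hi: float = 4000.0, step: float = 1.0) -> np.ndarray:
    return np.arange(lo, hi + 0.5 * step, step)


def broaden(bands: BandSet, grid: np.ndarray, fwhm: float = 10.0,
            provenance: str = "calculated") -> Spectrum:
    """Superpose one unit-area Lorentzian per band.

    Each band contributes intensity * (gamma/pi) / ((w - w0)^2 + gamma^2)
    with gamma = fwhm/2, so an isolated band of intensity I peaks at
    2 I / (pi fwhm) and integrates to I over the infinite line.
    """
    if fwhm <= 0:
        raise SpectrumError("fwhm must be positive")
    grid = np.asarray(grid, dtype=float)
    outside = (bands.wavenumbers < grid[0]) | (bands.wavenumbers > grid[-1])
    if np.any(outside):
        warnings.warn(f"{int(outside.sum())} bands outside the grid; "
                      "their truncated tails are still included")
    gamma = 0.5 * fwhm
    diff = grid[None, :] - bands.wavenumbers[:, None]
    values = (bands.intensities[:, None] * (gamma / np.pi)
              / (diff * diff + gamma * gamma)).sum(axis=0)
    return Spectrum(grid, values, bands.spectroscopy, provenance)


# ---------------------------------------------------------------------------
# frequency scaling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScaleMap:
    """Piecewise multiplicative frequency scaling: ordered non-overlapping
    (lo, hi, factor) intervals; wavenumbers outside every interval keep
    factor 1."""

    intervals: list[tuple[float, float, float]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for (lo, hi, f) in ivs:
            if f <= 0:
                raise SpectrumError(f"non-positive scale factor {f}")
            if hi <= lo:
                raise SpectrumError(f"empty interval [{lo}, {hi}]")
        for (_, hi1, _), (lo2, _, _) in zip(ivs, ivs[1:]):
            if lo2 < hi1:
                raise SpectrumError("overlapping scale intervals")
        self.intervals = ivs

    def factor(self, wavenumber: float) -> float:
        for lo, hi, f in self.intervals:
            if lo <= wavenumber <= hi:
                return f
        return 1.0


def scale_frequencies(bands: BandSet, scale_map: ScaleMap) -> BandSet:
    """Multiply each band position by its interval's factor; intensities
    untouched.  The identity map is a no-op."""
    factors = np.array([scale_map.factor(w) for w in bands.wavenumbers])
    return BandSet(
        bands.spectroscopy,
        bands.wavenumbers * factors,
        bands.intensities.copy(),
        polarization_scheme=bands.polarization_scheme,
        temperature=bands.temperature,
        excitation_wavenumber=bands.excitation_wavenumber,
    )


# ---------------------------------------------------------------------------
# ensemble averaging and background subtraction
# ---------------------------------------------------------------------------

def _common_grid(spectra: Sequence[Spectrum]) -> None:
    g0 = spectra[0]
    for s in spectra[1:]:
        if s.grid.shape != g0.grid.shape or not np.array_equal(s.grid, g0.grid):
            raise SpectrumError("spectra are not on a common grid (no silent resampling)")
        if s.spectroscopy != g0.spectroscopy:
            raise SpectrumError("spectroscopy tags differ")


def average_spectra(spectra: Sequence[Spectrum],
                    weights: Sequence[float] | None = None) -> Spectrum:
    """Pointwise (weighted) mean of snapshot spectra on one shared grid."""
    if not spectra:
        raise SpectrumError("no spectra to average")
    _common_grid(spectra)
    stack = np.stack([s.values for s in spectra])
    values = np.average(stack, axis=0, weights=weights)
    return Spectrum(spectra[0].grid.copy(), values, spectra[0].spectroscopy,
                    spectra[0].provenance)


def subtract_background(sample: Spectrum, background: Spectrum,
                        scale: "float | str" = 1.0,
                        auto_window: tuple[float, float] = (1750.0, 1900.0)
                        ) -> tuple[Spectrum, float]:
    """sample - scale * background on a shared grid.

    scale="auto" chooses the factor minimizing the squared residual over a
    signal-sparse window (default 1750-1900 cm^-1).  Returns the corrected
    spectrum and the scale used.
    """
    if sample.grid.shape != background.grid.shape or \
            not np.array_equal(sample.grid, background.grid):
        raise SpectrumError("sample and background grids differ")
    if scale == "auto":
        sel = (sample.grid >= auto_window[0]) & (sample.grid <= auto_window[1])
        if not np.any(sel) or np.allclose(background.values[sel], 0.0):
            raise SpectrumError("auto background window is empty or silent")
        b = background.values[sel]
        used = float(np.dot(sample.values[sel], b) / np.dot(b, b))
    else:
        used = float(scale)
    out = sample.copy()
    out.values = sample.values - used * background.values
    return out, used


# ---------------------------------------------------------------------------
# similarity factor
# ---------------------------------------------------------------------------

def similarity(s_cal: Spectrum, s_exp: Spectrum,
               window: tuple[float, float] | None = None) -> float:
    """Normalized overlap of two spectra over a wavenumber window.

    Trapezoidal integration on the shared grid restricted to the window;
    raises on zero-norm input.  Symmetric, scale-invariant and bounded by
    |s| <= 1.
    """
    if s_cal.grid.shape != s_exp.grid.shape or \
            not np.array_equal(s_cal.grid, s_exp.grid):
        raise SpectrumError("similarity needs a common grid (no silent resampling)")
    if window is None:
        window = DEFAULT_RANGES.get(s_cal.spectroscopy, (s_cal.grid[0], s_cal.grid[-1]))
    sel = (s_cal.grid >= window[0]) & (s_cal.grid <= window[1])
    if sel.sum() < 2:
        raise SpectrumError(f"window {window} covers fewer than 2 grid points")
    w = s_cal.grid[sel]
    a = s_cal.values[sel]
    b = s_exp.values[sel]
    num = np.trapezoid(a * b, w)
    na = np.trapezoid(a * a, w)
    nb = np.trapezoid(b * b, w)
    if na <= 0 or nb <= 0:
        raise SpectrumError("zero-norm spectrum over the similarity window")
    return float(np.clip(num / np.sqrt(na * nb), -1.0, 1.0))


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new grid -- only ever on explicit request."""
    grid = np.asarray(grid, dtype=float)
    values = np.interp(grid, spectrum.grid, spectrum.values)
    return Spectrum(grid, values, spectrum.spectroscopy, spectrum.provenance)


# ---------------------------------------------------------------------------
# two-column text files
# ---------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spectroscopy {spectrum.spectroscopy}\n")
        fh.write(f"# provenance {spectrum.provenance}\n")
        for w, v in zip(spectrum.grid, spectrum.values):
            fh.write(f"{w:14.6f} {v:20.12e}\n")


def read_spectrum(path: str) -> Spectrum:
    spectroscopy, provenance = "Raman", "reference"
    grid, values = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["spectroscopy"]:
                    spectroscopy = parts[1]
                elif parts[:1] == ["provenance"]:
                    provenance = parts[1]
                continue
            parts = line.split()
            if len(parts) >= 2:
                grid.append(float(parts[0]))
                values.append(float(parts[1]))
    return Spectrum(np.array(grid), np.array(values), spectroscopy, provenance)
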