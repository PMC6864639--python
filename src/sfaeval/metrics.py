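"""Evaluation metrics: spectral RMSE, CIEDE2000 and oxygenation difference.

The application-specific metric estimates tissue oxygen saturation from a
reflectance spectrum by multiple regression of the Beer-Lambert absorbance
A(l) = -log10 R(l) onto the extinction spectra of melanin, bilirubin and
oxy-/deoxy-hemoglobin:

    A(l_i) = cm eps_m(l_i) + cbi eps_bi(l_i) + cob eps_ob(l_i) + cdb eps_db(l_i)

solved in least squares for the dimensionless contributions c, giving
S_oxy = cob / (cob + cdb).  The difference metric between two saturation
estimates is their absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import ciede2000, spectrum_to_xyz, xyz_to_lab
from .grids import Illuminant, Spectrum
from .reference_data import load_cmf, load_d65
from .skin import ChromophoreLibrary

__all__ = [
    "SIX_WAVELENGTHS",
    "THREE_WAVELENGTHS",
    "OxygenationEstimate",
    "MetricResult",
    "rmse",
    "delta_e00",
    "reflectance_to_absorbance",
    "estimate_oxygenation",
    "delta_oxy",
    "summarize",
]

#: Default regression wavelength sets (nm): the six-wavelength set spanning
#: the hemoglobin Q bands, and a reduced three-wavelength set.
SIX_WAVELENGTHS = (500.0, 520.0, 540.0, 560.0, 580.0, 600.0)
THREE_WAVELENGTHS = (480.0, 560.0, 600.0)

#: Reflectance floor applied before the log10 (reconstructions can dip to or
#: below zero; the floor keeps absorbance finite).
REFLECTANCE_FLOOR = 1e-6


def rmse(a: Spectrum, b: Spectrum) -> float:
    """Root mean square difference over the common wavelength lattice."""
    if a.grid != b.grid:
        raise ValueError("spectra are on different grids")
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


def delta_e00(a: Spectrum, b: Spectrum, illum: Illuminant | None = None, cmf=None) -> float:
    """CIEDE2000 difference of two reflectances under D65 / CIE 1931 2deg."""
    if a.grid != b.grid:
        raise ValueError("spectra are on different grids")
    illum = illum or load_d65(a.grid)
    cmf = load_cmf(a.grid) if cmf is None else cmf
    white = spectrum_to_xyz(Spectrum(a.grid, np.ones(a.grid.n_points)), illum, cmf)
    lab_a = xyz_to_lab(spectrum_to_xyz(a, illum, cmf), white)
    lab_b = xyz_to_lab(spectrum_to_xyz(b, illum, cmf), white)
    return ciede2000(lab_a, lab_b)


def reflectance_to_absorbance(r: Spectrum, floor: float = REFLECTANCE_FLOOR) -> Spectrum:
    """A(l) = -log10 R(l), with reflectance clamped at ``floor`` from below."""
    return Spectrum(r.grid, -np.log10(np.clip(r.values, floor, None)), r.label)


@dataclass(frozen=True)
class OxygenationEstimate:
    """Regression contributions of the four chromophores and the derived
    oxygen saturation; ``defined`` is False when cob + cdb = 0 makes the
    saturation ratio meaningless (distinct from a numeric NaN)."""

    c_melanin: float
    c_bilirubin: float
    c_oxy: float
    c_deoxy: float

    @property
    def defined(self) -> bool:
        return (self.c_oxy + self.c_deoxy) != 0.0

    @property
    def s_oxy(self) -> float | None:
        if not self.defined:
            return None
        return self.c_oxy / (self.c_oxy + self.c_deoxy)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c_melanin, self.c_bilirubin, self.c_oxy, self.c_deoxy])


def estimate_oxygenation(
    r: Spectrum,
    wavelengths=SIX_WAVELENGTHS,
    lib: ChromophoreLibrary | None = None,
    floor: float = REFLECTANCE_FLOOR,
) -> OxygenationEstimate:
    """Multiple-regression oxygenation estimate from a reflectance spectrum.

    Builds the absorbance at the chosen wavelengths and solves the n x 4
    extinction system c = eps^+ a: ordinary least squares when
    overdetermined, minimum-norm pseudo-inverse when underdetermined (e.g.
    the three-wavelength set against four chromophores).  Coefficients are
    unconstrained; negative values are permitted.
    """
    if len(wavelengths) < 1:
        raise ValueError("at least one wavelength is required")
    lib = lib or ChromophoreLibrary.from_reference(grid=r.grid)
    if lib.grid != r.grid:
        raise ValueError("spectrum and chromophore library are on different grids")
    absorb = reflectance_to_absorbance(r, floor)
    idx = [r.grid.index_of(w) for w in wavelengths]
    a = absorb.values[idx]
    eps = lib.extinction_matrix(wavelengths)
    c, *_ = np.linalg.lstsq(eps, a, rcond=None)
    return OxygenationEstimate(*(float(v) for v in c))


def delta_oxy(s1: float | None, s2: float | None) -> float | None:
    """Absolute difference of two saturation estimates; None propagates."""
    if s1 is None or s2 is None:
        return None
    return abs(float(s1) - float(s2))


@dataclass(frozen=True)
class MetricResult:
    """Per-sample metric values with the five-number summary used in
    camera-comparison tables: min, max, mean, sample std and the 98th
    percentile."""

    values: np.ndarray
    min: float
    max: float
    mean: float
    std: float
    p98: float

    def row(self) -> tuple:
        return (self.min, self.max, self.mean, self.std, self.p98)


def summarize(values) -> MetricResult:
    """Five-number summary: sample (n-1) standard deviation, linear-
    interpolation 98th percentile; std of a single value is 0 by
    convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty sequence")
    std = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return MetricResult(
        values=arr,
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        std=std,
        p98=float(np.percentile(arr, 98.0, method="linear")),
    )
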