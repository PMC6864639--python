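"""Bundled reference tables and synthetic fixture generators.

Ships the CIE 1931 2-degree colour-matching functions, the D65 spectral
power distribution and a compiled visible-range chromophore extinction
table, all as plain-text tables resampled onto the requested wavelength
grid at load time.  A fully synthetic chromophore library (triangular
extinction curves) and a synthetic skin-like reflectance generator are
provided so the whole test suite runs without any real-world table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .grids import DEFAULT_GRID, Spectrum, SpectrumSet, WavelengthGrid, resample

__all__ = [
    "BundledTable",
    "load_reference",
    "load_cmf",
    "load_d65",
    "make_synthetic_skin_like_set",
]

_AVAILABLE = ("cmf_1931_2deg", "d65", "chromophores_jacques", "chromophores_synthetic")


@dataclass(frozen=True)
class BundledTable:
    name: str
    grid: WavelengthGrid
    columns: dict
    source: str

    def column(self, name: str) -> np.ndarray:
        return self.columns[name]

    def as_array(self, names=None) -> np.ndarray:
        names = names or list(self.columns)
        return np.column_stack([self.columns[n] for n in names])

    def to_spectrum_set(self) -> SpectrumSet:
        return SpectrumSet(
            self.grid,
            np.stack(list(self.columns.values())),
            tuple(self.columns),
            kind="reference",
        )


def _read_bundled_csv(filename: str):
    text = resources.files("sfaeval.data").joinpath(filename).read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split(",")
    arr = np.array([[float(c) for c in ln.split(",")] for ln in lines[1:]])
    return header, arr


def _resample_columns(header, arr, grid: WavelengthGrid) -> dict:
    src_wl = arr[:, 0]
    src = WavelengthGrid(float(src_wl[0]), float(src_wl[-1]), float(src_wl[1] - src_wl[0]))
    out = {}
    for j, name in enumerate(header[1:], start=1):
        out[name] = resample(Spectrum(src, arr[:, j]), grid).values
    return out


def _synthetic_chromophores(grid: WavelengthGrid) -> dict:
    """Four triangular extinction curves with distinct peaks.

    Peaks at 460, 480, 540 and 580 nm with half-widths wide enough that the
    extinction matrix at the six oxygenation wavelengths (500-600 nm) keeps
    full column rank.
    """
    wl = grid.wavelengths

    def tri(center, halfwidth, height):
        return np.clip(height * (1.0 - np.abs(wl - center) / halfwidth), 0.0, None)

    return {
        "eps_melanin": tri(460.0, 160.0, 1.0e4),
        "eps_bilirubin": tri(480.0, 90.0, 5.0e4),
        "eps_oxy_hb": tri(540.0, 120.0, 5.5e4),
        "eps_deoxy_hb": tri(580.0, 140.0, 5.0e4),
    }


def load_reference(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> BundledTable:
    """Load a bundled table by name, resampled onto ``grid``."""
    if name == "cmf_1931_2deg":
        header, arr = _read_bundled_csv("cie_1931_2deg_cmf.csv")
        return BundledTable(
            name,
            grid,
            _resample_columns(header, arr, grid),
            "CIE 1931 2-deg observer, Wyman/Sloan/Shirley analytic fits",
        )
    if name == "d65":
        header, arr = _read_bundled_csv("d65.csv")
        return BundledTable(
            name, grid, _resample_columns(header, arr, grid), "CIE standard illuminant D65"
        )
    if name == "chromophores_jacques":
        header, arr = _read_bundled_csv("chromophores.csv")
        cols = _resample_columns(header, arr, grid)
        # Melanin follows the classical melanosome power law ~ lambda^-3.33,
        # supplied on the extinction scale for the regression design matrix.
        cols["eps_melanin"] = 6.6e11 * grid.wavelengths**-3.33
        return BundledTable(
            name,
            grid,
            cols,
            "compiled visible-range hemoglobin/bilirubin extinctions "
            "(approximate) + melanosome power law",
        )
    if name == "chromophores_synthetic":
        return BundledTable(
            name, grid, _synthetic_chromophores(grid), "synthetic triangular fixtures"
        )
    raise KeyError(f"unknown reference table {name!r}; available: {_AVAILABLE}")


def load_cmf(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """N x 3 colour-matching-function array (xbar, ybar, zbar)."""
    return load_reference("cmf_1931_2deg", grid).as_array(["xbar", "ybar", "zbar"])


def load_d65(grid: WavelengthGrid = DEFAULT_GRID):
    from .grids import Illuminant

    return Illuminant(grid, load_reference("d65", grid).column("d65"), name="D65")


def make_synthetic_skin_like_set(
    n: int, seed: int = 0, grid: WavelengthGrid = DEFAULT_GRID
) -> SpectrumSet:
    """Synthetic stand-in for a measured skin-reflectance test database.

    Each spectrum combines a melanin-like short-wavelength absorption slope,
    the hemoglobin W-shaped dip around 540-580 nm and a rising red edge,
    with per-sample jitter of the underlying strengths.  Values land in
    [0, 1]; fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    rows = np.empty((n, grid.n_points))
    for i in range(n):
        mel = rng.uniform(0.3, 1.5)
        blood = rng.uniform(0.3, 1.2)
        base = rng.uniform(0.02, 0.12)
        absorb = (
            mel * (wl / 500.0) ** -3.0
            + blood * 0.55 * np.exp(-0.5 * ((wl - 542.0) / 12.0) ** 2)
            + blood * 0.60 * np.exp(-0.5 * ((wl - 577.0) / 11.0) ** 2)
            + blood * 0.25 * np.exp(-0.5 * ((wl - 430.0) / 25.0) ** 2)
        )
        rows[i] = np.clip(10.0 ** (-(absorb + base)), 0.0, 1.0)
    labels = tuple(f"skin_like_{i}" for i in range(n))
    return SpectrumSet(grid, rows, labels, kind="test")
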