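"""Wavelength grids, spectra containers, resampling, scaling and file I/O.

Everything downstream (sensor simulation, reconstruction, metrics) operates
on a shared sampling lattice.  The default lattice covers the visible range
400-700 nm in 2 nm steps, i.e. 151 samples, which is the native resolution
of the sensor-sensitivity and reflectance tables this package consumes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectrumSet",
    "Illuminant",
    "DEFAULT_GRID",
    "resample",
    "resample_set",
    "feature_scale",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_spectrum_h5",
    "write_spectrum_h5",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength lattice ``start..stop`` inclusive, in nm."""

    start: float = 400.0
    stop: float = 700.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(f"stop ({self.stop}) must exceed start ({self.start})")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid {self.start}-{self.stop} nm is not an integer number "
                f"of {self.step} nm steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def index_of(self, wavelength: float) -> int:
        """Index of an exact lattice point; raises if not on the lattice."""
        pos = (wavelength - self.start) / self.step
        idx = int(round(pos))
        if abs(pos - idx) > 1e-9 or not 0 <= idx < self.n_points:
            raise ValueError(f"{wavelength} nm is not on grid {self}")
        return idx

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start:g}, {self.stop:g}] nm @ {self.step:g} nm"


DEFAULT_GRID = WavelengthGrid()


def _as_grid_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{name} must be a length-{n} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum (reflectance, sensitivity or power) on a grid."""

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _as_grid_array(self.values, self.grid.n_points, "values")
        )

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


@dataclass(frozen=True)
class SpectrumSet:
    """J spectra sharing one grid, stored as a J x N array.

    ``meta`` optionally carries one record per row (e.g. the skin parameters
    that generated a simulated spectrum) for later inspection.
    """

    grid: WavelengthGrid
    values: np.ndarray
    labels: tuple = ()
    kind: str = "test"
    meta: tuple = ()

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if arr.shape[1] != self.grid.n_points:
            raise ValueError(
                f"spectra have {arr.shape[1]} samples but grid has "
                f"{self.grid.n_points} points"
            )
        if arr.shape[0] < 1:
            raise ValueError("a SpectrumSet needs at least one spectrum")
        if not np.all(np.isfinite(arr)):
            raise ValueError("spectrum values contain NaN or inf")
        object.__setattr__(self, "values", arr)
        labels = tuple(self.labels) if self.labels else tuple(
            f"s{i}" for i in range(arr.shape[0])
        )
        if len(labels) != arr.shape[0]:
            raise ValueError("number of labels does not match number of spectra")
        object.__setattr__(self, "labels", labels)
        if self.meta and len(self.meta) != arr.shape[0]:
            raise ValueError("number of meta records does not match number of spectra")
        object.__setattr__(self, "meta", tuple(self.meta))

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n_spectra

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.values[i], self.labels[i])

    def with_values(self, values: np.ndarray) -> "SpectrumSet":
        return replace(self, values=values)


@dataclass(frozen=True)
class Illuminant:
    """Spectral power distribution of a light source."""

    grid: WavelengthGrid
    spd: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        arr = _as_grid_array(self.spd, self.grid.n_points, "spd")
        if np.any(arr < 0):
            raise ValueError("illuminant power must be non-negative")
        object.__setattr__(self, "spd", arr)

    @classmethod
    def equi_energy(cls, grid: WavelengthGrid = DEFAULT_GRID) -> "Illuminant":
        """Flat (equal power per wavelength) illuminant, the default study condition."""
        return cls(grid, np.ones(grid.n_points), name="E")


# ---------------------------------------------------------------------------
# resampling and scaling


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Query points outside the source support are zero-filled; the source and
    target ranges must overlap.
    """
    src = spectrum.grid
    if src.stop < target.start or src.start > target.stop:
        raise ValueError(
            f"source range {src} does not overlap target range {target}"
        )
    out = np.interp(
        target.wavelengths, src.wavelengths, spectrum.values, left=0.0, right=0.0
    )
    return Spectrum(target, out, spectrum.label)


def resample_set(sset: SpectrumSet, target: WavelengthGrid) -> SpectrumSet:
    src = sset.grid
    if src.stop < target.start or src.start > target.stop:
        raise ValueError(f"source range {src} does not overlap target range {target}")
    out = np.stack(
        [
            np.interp(target.wavelengths, src.wavelengths, row, left=0.0, right=0.0)
            for row in sset.values
        ]
    )
    return SpectrumSet(target, out, sset.labels, sset.kind, sset.meta)


def feature_scale(sset: SpectrumSet) -> SpectrumSet:
    """Min-max normalise a set so all its values jointly span [0, 1].

    One affine map is applied to the whole set (not per spectrum, not per
    wavelength) so relative brightness between spectra is preserved.
    """
    lo = float(sset.values.min())
    hi = float(sset.values.max())
    if hi == lo:
        raise ValueError("cannot feature-scale a constant set (min == max)")
    return sset.with_values((sset.values - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Dialect: UTF-8 text, comma or tab delimited (autodetected), one header row,
# first column "wavelength_nm", one column per spectrum.  ``transpose=True``
# reads the row-wise variant (one spectrum per row, wavelengths in the header).


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_cell(cell: str, lineno: int, path) -> float:
    cell = cell.strip()
    if not cell:
        raise ValueError(f"{path}: missing value on line {lineno}")
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"{path}: non-numeric value {cell!r} on line {lineno}") from None


def read_spectrum_table(path, kind: str = "test", transpose: bool = False) -> SpectrumSet:
    """Read a spectrum set from delimited text (see module notes for dialect)."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    delim = _detect_delimiter(lines[0])
    rows = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delim))
    header, data = rows[0], rows[1:]
    ncol = len(header)
    table = []
    for lineno, row in enumerate(data, start=2):
        if len(row) != ncol:
            raise ValueError(
                f"{path}: line {lineno} has {len(row)} fields, expected {ncol}"
            )
        table.append([_parse_cell(c, lineno, path) for c in row])
    arr = np.asarray(table, dtype=float)

    if transpose:
        wl = np.array([_parse_cell(h, 1, path) for h in header[1:]])
        labels = tuple(str(r[0]) for r in data)
        values = arr[:, 1:]
    else:
        wl = arr[:, 0]
        labels = tuple(h.strip() for h in header[1:])
        values = arr[:, 1:].T

    dif = np.diff(wl)
    if np.any(dif <= 0):
        bad = int(np.argmax(dif <= 0))
        raise ValueError(
            f"{path}: wavelengths must be strictly increasing "
            f"(violation after {wl[bad]:g} nm, line {bad + 2})"
        )
    step = dif[0]
    if not np.allclose(dif, step, atol=1e-9):
        raise ValueError(f"{path}: wavelength spacing is not uniform")
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    return SpectrumSet(grid, values, labels, kind)


def write_spectrum_table(sset: SpectrumSet, path, delimiter: str = ",") -> None:
    """Write a set in the delimited-text dialect (lossless via repr precision)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["wavelength_nm", *sset.labels])
        for k, wl in enumerate(sset.grid.wavelengths):
            w.writerow([f"{wl:g}", *(repr(float(v)) for v in sset.values[:, k])])


def write_spectrum_h5(sset: SpectrumSet, path, name: str = "spectra") -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group(name)
        g.create_dataset("values", data=sset.values)
        g.create_dataset("wavelength_nm", data=sset.grid.wavelengths)
        g.attrs["labels"] = list(sset.labels)
        g.attrs["kind"] = sset.kind


def read_spectrum_h5(path, name: str = "spectra") -> SpectrumSet:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh[name]
        wl = np.asarray(g["wavelength_nm"])
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
        return SpectrumSet(
            grid,
            np.asarray(g["values"]),
            tuple(str(s) for s in g.attrs["labels"]),
            str(g.attrs["kind"]),
        )
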