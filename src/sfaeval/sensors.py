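"""Sensor models and the forward imaging model for filter-array cameras.

A sensor is an N x I table of per-channel spectral sensitivities Q.  Channel
responses to a reflectance R under illumination E are the discrete products

    P[j, i] = sum_k E(l_k) R_j(l_k) Q_i(l_k)

with no noise term: the evaluation deliberately compares cameras under an
idealised noiseless, equi-energy-illuminated imaging model so that spectral
sensitivity shape and band count are the only factors.

Gaussian-band (GSB) virtual sensors place a unit-peak Gaussian of standard
deviation sigma (default 15 nm) at each requested centre wavelength,
truncated - not renormalised - at the grid edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Illuminant, SpectrumSet, WavelengthGrid, read_spectrum_table

__all__ = [
    "SensorModel",
    "ResponseSet",
    "GaussianBandSpec",
    "CorrectionMatrix",
    "simulate_responses",
    "make_gaussian_sensor",
    "evenly_spread_gsb",
    "peak_wavelengths",
    "apply_correction",
    "apply_correction_to_sensor",
    "read_sensor_table",
]


@dataclass(frozen=True)
class SensorModel:
    """Named set of per-channel spectral sensitivities on a grid (N x I)."""

    name: str
    grid: WavelengthGrid
    sensitivities: np.ndarray
    channel_names: tuple = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.sensitivities, dtype=float)
        if q.ndim == 1:
            q = q[:, None]
        if q.shape[0] != self.grid.n_points:
            raise ValueError(
                f"sensitivities have {q.shape[0]} rows but grid has "
                f"{self.grid.n_points} points"
            )
        if q.shape[1] < 1:
            raise ValueError("a sensor needs at least one channel")
        if np.any(q < 0) or not np.all(np.isfinite(q)):
            raise ValueError("sensitivities must be finite and non-negative")
        if np.any(q.max(axis=0) <= 0):
            dead = [int(i) for i in np.flatnonzero(q.max(axis=0) <= 0)]
            raise ValueError(f"channels {dead} of sensor {self.name!r} are all zero")
        object.__setattr__(self, "sensitivities", q)
        names = tuple(self.channel_names) if self.channel_names else tuple(
            f"ch{i}" for i in range(q.shape[1])
        )
        if len(names) != q.shape[1]:
            raise ValueError("channel_names does not match the number of channels")
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[1]


@dataclass(frozen=True)
class ResponseSet:
    """J x I channel responses with provenance."""

    values: np.ndarray
    sensor_name: str = ""
    illuminant_name: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GaussianBandSpec:
    """Centre wavelengths and common width of a Gaussian-band sensor."""

    peaks: tuple
    sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        object.__setattr__(self, "peaks", tuple(float(p) for p in self.peaks))
        if len(self.peaks) < 1:
            raise ValueError("at least one peak is required")


@dataclass(frozen=True)
class CorrectionMatrix:
    """Linear response transform, e.g. a manufacturer crosstalk correction."""

    matrix: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.isfinite(m)):
            raise ValueError("correction matrix must be finite")
        object.__setattr__(self, "matrix", m)


def simulate_responses(
    sset: SpectrumSet, illum: Illuminant, sensor: SensorModel
) -> ResponseSet:
    """Noiseless channel responses P = (R * E) Q for every spectrum in the set."""
    if sset.grid != sensor.grid or sset.grid != illum.grid:
        raise ValueError("spectra, illuminant and sensor must share one grid")
    p = (sset.values * illum.spd) @ sensor.sensitivities
    return ResponseSet(p, sensor.name, illum.name)


def make_gaussian_sensor(
    spec: GaussianBandSpec, grid: WavelengthGrid, name: str = ""
) -> SensorModel:
    """Unit-peak Gaussian channels at the given centres, clipped at grid edges."""
    for p in spec.peaks:
        if not grid.start <= p <= grid.stop:
            raise ValueError(f"peak {p} nm lies outside grid {grid}")
    wl = grid.wavelengths[:, None]
    centers = np.asarray(spec.peaks)[None, :]
    q = np.exp(-((wl - centers) ** 2) / (2.0 * spec.sigma**2))
    label = name or "gsb_" + "_".join(f"{p:g}" for p in spec.peaks)
    ch = tuple(f"g{p:g}" for p in spec.peaks)
    return SensorModel(label, grid, q, ch)


def evenly_spread_gsb(
    n_channels: int,
    grid: WavelengthGrid,
    sigma: float = 15.0,
    lo: float | None = None,
    hi: float | None = None,
    name: str = "",
) -> SensorModel:
    """GSB sensor with ``n_channels`` peaks evenly spaced over [lo, hi]."""
    lo = grid.start + 20.0 if lo is None else lo
    hi = grid.stop - 20.0 if hi is None else hi
    peaks = tuple(np.linspace(lo, hi, n_channels))
    return make_gaussian_sensor(
        GaussianBandSpec(peaks, sigma), grid, name or f"gsb{n_channels}"
    )


def peak_wavelengths(sensor: SensorModel) -> list:
    """Per-channel argmax wavelength; ties resolve to the shorter wavelength."""
    wl = sensor.grid.wavelengths
    # np.argmax returns the first (shortest-wavelength) maximiser on ties
    return [float(wl[int(np.argmax(sensor.sensitivities[:, i]))])
            for i in range(sensor.n_channels)]


def gsb_twin(sensor: SensorModel, sigma: float = 15.0) -> SensorModel:
    """The Gaussian-band virtual version of a sensor: one unit-peak Gaussian
    per channel, centred at that channel's sensitivity peak."""
    spec = GaussianBandSpec(tuple(peak_wavelengths(sensor)), sigma)
    return make_gaussian_sensor(spec, sensor.grid, name=f"G{sensor.name}")


def apply_correction(responses: ResponseSet, m: CorrectionMatrix) -> ResponseSet:
    """Right-multiply every response row by the correction matrix."""
    if responses.values.shape[1] != m.matrix.shape[0]:
        raise ValueError(
            f"responses have {responses.values.shape[1]} channels but the "
            f"correction matrix expects {m.matrix.shape[0]}"
        )
    return ResponseSet(
        responses.values @ m.matrix,
        responses.sensor_name + "+corr",
        responses.illuminant_name,
    )


def apply_correction_to_sensor(
    sensor: SensorModel, m: CorrectionMatrix, name: str = ""
) -> SensorModel:
    """Fold a response-space correction into the sensitivities (Q' = Q M).

    Because the imaging model is linear, correcting responses and correcting
    sensitivities are algebraically identical; this lifted form lets a
    corrected camera be treated as an independent first-class sensor.
    Negative lobes produced by the correction are clipped at zero to keep
    the sensor-model invariant.
    """
    if sensor.n_channels != m.matrix.shape[0]:
        raise ValueError("correction matrix does not conform to the sensor")
    q = np.clip(sensor.sensitivities @ m.matrix, 0.0, None)
    return SensorModel(name or sensor.name + "_corrected", sensor.grid, q)


def read_sensor_table(path, name: str = "") -> SensorModel:
    """Read channel sensitivities from the delimited spectrum-table dialect."""
    sset = read_spectrum_table(path, kind="sensor")
    import os

    label = name or os.path.splitext(os.path.basename(str(path)))[0]
    return SensorModel(label, sset.grid, sset.values.T, tuple(sset.labels))
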