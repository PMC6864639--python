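"""Wiener estimation: linear minimum-square-error spectral reconstruction.

Given training reflectances R (J x N) and their simulated channel responses
P (J x I), the Wiener matrix in sample-correlation form is

    W = K_rp (K_pp + ridge I)^-1,   K_rp = R^T P / J,   K_pp = P^T P / J,

which minimises the summed squared reconstruction error || R - P W^T ||_F^2
over the training set (with the Moore-Penrose pseudo-inverse replacing the
inverse when K_pp is singular and ridge = 0).  Reconstruction is then the
linear map r_hat = W p.  No noise term enters: the framework evaluates
cameras under a noiseless imaging model.

The estimator follows the scikit-learn protocol (``fit`` / ``predict``,
``get_params``) so it composes with sklearn model-selection tooling;
:func:`train_wiener` and :func:`reconstruct` are thin functional wrappers.
"""

from __future__ import annotations

import io

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .grids import Illuminant, SpectrumSet, WavelengthGrid
from .sensors import ResponseSet, SensorModel, simulate_responses

__all__ = ["WienerEstimator", "train_wiener", "reconstruct"]


class WienerEstimator(BaseEstimator, RegressorMixin):
    """Wiener spectral-reflectance reconstructor for one sensor.

    Parameters
    ----------
    sensor : SensorModel
        The camera whose responses will be inverted.
    illuminant : Illuminant, optional
        Illumination used to simulate training responses (default:
        equi-energy on the sensor grid).
    ridge : float
        Tikhonov term added to the response autocorrelation; 0 (default)
        falls back to the pseudo-inverse for singular systems.
    clip : bool
        If True, reconstructed reflectances are clamped to [0, 1].
        Off by default: metrics are computed on raw reconstructions.

    Attributes
    ----------
    w_ : ndarray of shape (n_wavelengths, n_channels)
        The Wiener estimation matrix.
    grid_ : WavelengthGrid
    sensor_name_ : str
    training_label_ : str
    """

    def __init__(self, sensor=None, illuminant=None, ridge=0.0, clip=False):
        self.sensor = sensor
        self.illuminant = illuminant
        self.ridge = ridge
        self.clip = clip

    # -- sklearn-style API -------------------------------------------------
    def fit(self, X, y=None):
        """Train on a reflectance set (SpectrumSet or J x N array).

        Training responses are always simulated internally with the same
        illuminant and sensor that will be used at prediction time.
        """
        if self.sensor is None:
            raise ValueError("WienerEstimator needs a sensor before fitting")
        if isinstance(X, SpectrumSet):
            if X.grid != self.sensor.grid:
                raise ValueError("training set and sensor are on different grids")
            training = X
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            training = SpectrumSet(self.sensor.grid, arr, kind="training")
        if training.n_spectra < 1:
            raise ValueError("training set is empty")
        illum = self.illuminant or Illuminant.equi_energy(self.sensor.grid)

        p = simulate_responses(training, illum, self.sensor).values  # J x I
        r = training.values  # J x N
        j = r.shape[0]
        k_rp = r.T @ p / j
        k_pp = p.T @ p / j
        if self.ridge > 0:
            self.w_ = k_rp @ np.linalg.inv(k_pp + self.ridge * np.eye(k_pp.shape[0]))
        else:
            self.w_ = k_rp @ np.linalg.pinv(k_pp)
        if not np.all(np.isfinite(self.w_)):
            raise ValueError("Wiener matrix contains non-finite entries")
        self.grid_ = self.sensor.grid
        self.sensor_name_ = self.sensor.name
        self.training_label_ = training.kind
        self.n_features_in_ = p.shape[1]
        self.illuminant_ = illum
        return self

    def predict(self, X) -> np.ndarray:
        """Reconstruct spectra (J x N array) from responses (ResponseSet or
        J x I array)."""
        if not hasattr(self, "w_"):
            raise ValueError("estimator is not fitted")
        p = X.values if isinstance(X, ResponseSet) else np.atleast_2d(np.asarray(X, float))
        if p.shape[1] != self.w_.shape[1]:
            raise ValueError(
                f"responses have {p.shape[1]} channels, Wiener matrix expects "
                f"{self.w_.shape[1]}"
            )
        out = p @ self.w_.T
        if self.clip:
            out = np.clip(out, 0.0, 1.0)
        return out

    def predict_set(self, X) -> SpectrumSet:
        return SpectrumSet(self.grid_, self.predict(X), kind="reconstructed")

    # -- serialisation -----------------------------------------------------
    def to_text(self) -> str:
        """Matrix plus metadata header, delimited text."""
        buf = io.StringIO()
        buf.write(f"# sensor: {self.sensor_name_}\n")
        buf.write(f"# training: {self.training_label_}\n")
        buf.write(f"# ridge: {self.ridge!r}\n")
        buf.write(f"# grid: {self.grid_.start:g} {self.grid_.stop:g} {self.grid_.step:g}\n")
        for row in self.w_:
            buf.write(",".join(repr(float(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "WienerEstimator":
        meta, rows = {}, []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append([float(v) for v in line.split(",")])
        est = cls(ridge=float(meta.get("ridge", 0.0)))
        est.w_ = np.asarray(rows)
        start, stop, step = (float(v) for v in meta["grid"].split())
        est.grid_ = WavelengthGrid(start, stop, step)
        est.sensor_name_ = meta.get("sensor", "")
        est.training_label_ = meta.get("training", "")
        est.n_features_in_ = est.w_.shape[1]
        return est


def train_wiener(
    training: SpectrumSet,
    illum: Illuminant,
    sensor: SensorModel,
    ridge: float = 0.0,
) -> WienerEstimator:
    """Fit a Wiener reconstructor for ``sensor`` on a training set."""
    return WienerEstimator(sensor=sensor, illuminant=illum, ridge=ridge).fit(training)


def reconstruct(rec: WienerEstimator, responses) -> SpectrumSet:
    """Apply a trained reconstructor to channel responses."""
    return rec.predict_set(responses)
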