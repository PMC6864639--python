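"""Framework orchestration: per-sensor evaluation runs, diversity analysis.

``run_evaluation`` executes the full pipeline for a roster of sensors:
simulate training responses -> fit the Wiener matrix -> simulate test
responses -> reconstruct the test spectra -> score RMSE, CIEDE2000 and
oxygenation-difference metrics against the ground truth -> summarise per
sensor.  Everything is deterministic under a fixed seed and a report can be
regenerated byte for byte.

``pca_diversity`` quantifies how diverse each reflectance set is inside the
principal-component space of all sets combined: sets are stacked, centred
at the combined mean, and each set's variance along the first k components
is reported as a percentage of that set's total variance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import spectrum_to_xyz, xyz_to_srgb
from .grids import Illuminant, Spectrum, SpectrumSet, feature_scale
from .metrics import (
    SIX_WAVELENGTHS,
    THREE_WAVELENGTHS,
    delta_e00,
    delta_oxy,
    estimate_oxygenation,
    rmse,
    summarize,
)
from .reconstruction import WienerEstimator
from .reference_data import load_cmf, load_d65
from .sensors import SensorModel, gsb_twin, simulate_responses
from .skin import ChromophoreLibrary

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "PCADiversityResult",
    "run_evaluation",
    "pca_diversity",
    "extreme_members",
    "format_report",
]


@dataclass(frozen=True)
class EvaluationConfig:
    """Inputs of one evaluation run.

    ``sensors`` is the roster of SensorModel objects; sensors listed in
    ``gsb_for`` additionally get their Gaussian-band virtual twin evaluated
    (unit-peak Gaussians of width ``gsb_sigma`` at the sensitivity peaks).
    """

    training: SpectrumSet
    test: SpectrumSet
    sensors: tuple
    illuminant: Illuminant | None = None
    metrics: tuple = ("rmse", "delta_e00", "delta_oxy_6", "delta_oxy_3")
    oxy_wavelengths_6: tuple = SIX_WAVELENGTHS
    oxy_wavelengths_3: tuple = THREE_WAVELENGTHS
    ridge: float = 0.0
    seed: int = 0
    scale_sets: bool = True
    gsb_for: tuple = ()
    gsb_sigma: float = 15.0
    chromophore_library: str = "chromophores_jacques"

    def __post_init__(self) -> None:
        if not self.sensors:
            raise ValueError("the sensor roster is empty")
        if not self.metrics:
            raise ValueError("at least one metric is required")
        if self.training.grid != self.test.grid:
            raise ValueError("training and test sets are on different grids")


@dataclass(frozen=True)
class EvaluationReport:
    """One five-number summary row per (sensor, metric) pair."""

    rows: dict  # {(sensor_name, metric): MetricResult}
    sensor_names: tuple
    metrics: tuple
    provenance: dict


def _evaluate_sensor(
    sensor: SensorModel,
    training: SpectrumSet,
    test: SpectrumSet,
    illum: Illuminant,
    cfg: EvaluationConfig,
    lib: ChromophoreLibrary,
    cmf,
    d65,
) -> dict:
    stage = "train"
    try:
        est = WienerEstimator(sensor=sensor, illuminant=illum, ridge=cfg.ridge).fit(
            training
        )
        stage = "simulate"
        responses = simulate_responses(test, illum, sensor)
        stage = "reconstruct"
        recon = est.predict_set(responses)
        stage = "evaluate"
        out = {}
        if "rmse" in cfg.metrics:
            out["rmse"] = summarize(
                [rmse(test[j], recon[j]) for j in range(len(test))]
            )
        if "delta_e00" in cfg.metrics:
            out["delta_e00"] = summarize(
                [delta_e00(test[j], recon[j], d65, cmf) for j in range(len(test))]
            )
        for metric, wls in (
            ("delta_oxy_6", cfg.oxy_wavelengths_6),
            ("delta_oxy_3", cfg.oxy_wavelengths_3),
        ):
            if metric not in cfg.metrics:
                continue
            vals = []
            for j in range(len(test)):
                s_ref = estimate_oxygenation(test[j], wls, lib).s_oxy
                s_rec = estimate_oxygenation(recon[j], wls, lib).s_oxy
                d = delta_oxy(s_ref, s_rec)
                if d is not None:
                    vals.append(d)
            out[metric] = summarize(vals)
        return out
    except Exception as exc:  # noqa: BLE001 - re-raise with run context
        raise RuntimeError(
            f"evaluation failed at stage {stage!r} for sensor {sensor.name!r}: {exc}"
        ) from exc


def run_evaluation(config: EvaluationConfig) -> EvaluationReport:
    """Run the full framework for every sensor in the roster."""
    training = feature_scale(config.training) if config.scale_sets else config.training
    test = feature_scale(config.test) if config.scale_sets else config.test
    illum = config.illuminant or Illuminant.equi_energy(training.grid)
    lib = ChromophoreLibrary.from_reference(config.chromophore_library, training.grid)
    cmf = load_cmf(training.grid)
    d65 = load_d65(training.grid)

    roster = []
    for sensor in config.sensors:
        roster.append(sensor)
        if sensor.name in config.gsb_for:
            roster.append(gsb_twin(sensor, config.gsb_sigma))

    rows = {}
    for sensor in roster:
        res = _evaluate_sensor(sensor, training, test, illum, config, lib, cmf, d65)
        for metric, summary in res.items():
            rows[(sensor.name, metric)] = summary

    prov = {
        "seed": config.seed,
        "ridge": config.ridge,
        "n_training": training.n_spectra,
        "n_test": test.n_spectra,
        "scale_sets": config.scale_sets,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "sensors": [s.name for s in roster],
                    "metrics": list(config.metrics),
                    "ridge": config.ridge,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    return EvaluationReport(
        rows=rows,
        sensor_names=tuple(s.name for s in roster),
        metrics=tuple(config.metrics),
        provenance=prov,
    )


def format_report(report: EvaluationReport, swatches: bool = False) -> str:
    """Camera-comparison table: one block per metric, five summary columns
    per sensor, fixed formatting so identical runs give identical bytes."""
    lines = []
    lines.append("# evaluation report")
    for key in sorted(report.provenance):
        lines.append(f"# {key}: {report.provenance[key]}")
    for metric in report.metrics:
        lines.append("")
        lines.append(metric)
        lines.append(
            f"{'sensor':<16}{'min':>12}{'max':>12}{'mean':>12}{'std':>12}{'p98':>12}"
        )
        for name in report.sensor_names:
            if (name, metric) not in report.rows:
                continue
            r = report.rows[(name, metric)]
            lines.append(
                f"{name:<16}"
                + "".join(f"{v:>12.6f}" for v in (r.min, r.max, r.mean, r.std, r.p98))
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# training-set diversity analysis


@dataclass(frozen=True)
class PCADiversityResult:
    """Per-set variance percentages along the combined-space components."""

    set_labels: tuple
    percentages: dict  # {label: k-vector of % of that set's total variance}
    combined_percentages: np.ndarray
    components: np.ndarray  # k x N loadings
    scores: dict  # {label: (J_set x k) projections}
    k: int


def pca_diversity(sets, k: int = 4) -> PCADiversityResult:
    """Principal components of all sets stacked; per-set variance shares.

    All sets are centred at the *combined* mean so the components describe
    the joint space; each set's variance along a component is then taken
    about that set's own projected mean and expressed as a percentage of
    the set's total variance.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two sets to compare diversity")
    grid = sets[0].grid
    for s in sets:
        if s.grid != grid:
            raise ValueError("all sets must share one grid")
    stacked = np.vstack([s.values for s in sets])
    if stacked.shape[0] < 2:
        raise ValueError("need at least two spectra overall")
    mean = stacked.mean(axis=0)
    centred = stacked - mean
    # principal axes of the combined covariance via SVD
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(k, vt.shape[0])
    components = vt[:k]
    total_var = (svals**2).sum()
    combined_pct = 100.0 * (svals[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)

    labels, percentages, scores = [], {}, {}
    for s in sets:
        label = s.kind
        if label in percentages:  # disambiguate duplicate kinds
            label = f"{label}_{len(labels)}"
        proj = (s.values - mean) @ components.T  # J_set x k
        set_centred = s.values - s.values.mean(axis=0)
        tot = float((set_centred**2).sum())
        if tot == 0.0:
            pct = np.zeros(k)
        else:
            var_along = ((proj - proj.mean(axis=0)) ** 2).sum(axis=0)
            pct = 100.0 * var_along / tot
        labels.append(label)
        percentages[label] = pct
        scores[label] = proj
    return PCADiversityResult(
        set_labels=tuple(labels),
        percentages=percentages,
        combined_percentages=combined_pct,
        components=components,
        scores=scores,
        k=k,
    )


@dataclass(frozen=True)
class ExtremeMember:
    which: str  # e.g. "max_pc1"
    label: str
    spectrum: Spectrum
    parameters: object  # SkinParameters for simulated sets, else None
    srgb: tuple | None = None


def extreme_members(
    sset: SpectrumSet, result: PCADiversityResult, set_label: str | None = None,
    swatches: bool = False,
) -> list:
    """The four spectra at min/max projection on PC1 and PC2.

    Ties resolve to the lowest row index (argmin/argmax convention), so the
    output is deterministic.  For simulated sets the generating skin
    parameters ride along for inspection; optional sRGB swatches are
    rendered under D65.
    """
    if result.k < 2:
        raise ValueError("extreme-member analysis needs at least two components")
    label = set_label or sset.kind
    if label not in result.scores:
        raise ValueError(f"set {label!r} was not part of the PCA result")
    proj = result.scores[label]
    if proj.shape[0] != sset.n_spectra:
        raise ValueError("PCA result does not match this set")
    picks = {
        "min_pc1": int(np.argmin(proj[:, 0])),
        "max_pc1": int(np.argmax(proj[:, 0])),
        "min_pc2": int(np.argmin(proj[:, 1])),
        "max_pc2": int(np.argmax(proj[:, 1])),
    }
    cmf = load_cmf(sset.grid) if swatches else None
    d65 = load_d65(sset.grid) if swatches else None
    out = []
    for which, j in picks.items():
        srgb = None
        if swatches:
            srgb = xyz_to_srgb(spectrum_to_xyz(sset[j], d65, cmf))
        out.append(
            ExtremeMember(
                which=which,
                label=sset.labels[j],
                spectrum=sset[j],
                parameters=sset.meta[j] if sset.meta else None,
                srgb=srgb,
            )
        )
    return out
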