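# sfaeval

**Measurement-free evaluation of spectral filter array (SFA) cameras for
skin imaging and tissue-oxygenation estimation.**

Choosing an SFA camera for a clinical application normally requires
extensive measurements with every candidate device. `sfaeval` instead
ranks cameras from their spectral sensitivities alone: it simulates channel
responses to a reflectance database, reconstructs full spectra from those
few channels, and scores each camera by how well the reconstructions
support the application — here, estimating skin oxygen saturation. It is
aimed at biomedical-optics and spectral-imaging researchers comparing
multi-band sensors, or designing virtual ones, before any hardware exists.

## What it computes

**Forward imaging model.** A camera with channels *i* = 1..I and spectral
sensitivities Qᵢ(λ) viewing reflectance Rⱼ(λ) under illumination E(λ)
produces noiseless responses on an N-point wavelength lattice
(400–700 nm, 2 nm steps, N = 151):

    Pⱼᵢ = Σₖ E(λₖ) Rⱼ(λₖ) Qᵢ(λₖ)

**Wiener reconstruction.** The estimation matrix W (N×I) minimises the
squared reconstruction error over a training set, in sample-correlation
form W = K_rp (K_pp + ridge·I)⁻¹ with K_rp = RᵀP/J and K_pp = PᵀP/J
(pseudo-inverse when singular); full spectra are recovered as r̃ = W p.
`WienerEstimator` follows the scikit-learn fit/predict protocol.

**Simulated skin.** Training spectra come from a three-layer
(epidermis/dermis/bone) optical model parameterised by oxygen saturation
S, blood volume fraction f_bl, bilirubin concentration C_bi and melanin
volume fraction f_mel, with per-layer absorption

    μa,epi = f_mel·μa,mel(λ)
    μa,derm = f_bl·[S·μa,oxy(λ) + (1−S)·μa,deoxy(λ)] + ln10·(C_bi/PM_bi)·ε_bi(λ)

The default 10-level grid per parameter gives 10,000 combinations.
Reflectance is produced either by a weighted-photon Monte Carlo transport
engine (Henyey–Greenstein scattering, Fresnel boundaries, Russian
roulette) or by a fast Beer–Lambert forward model that the oxygenation
estimator inverts exactly.

**Metrics.** Per test spectrum: spectral RMSE; CIEDE2000 colour difference
(D65, CIE 1931 2° observer); and ΔOxy = |S_oxy(reference) −
S_oxy(reconstruction)|, where S_oxy = c_ob/(c_ob + c_db) comes from
regressing the absorbance A(λ) = −log₁₀R(λ) onto the four chromophore
extinction spectra at six (500–600 nm) or three (480/560/600 nm)
wavelengths. Reports give min / max / mean / std / 98th percentile per
sensor.

## Worked example

```python
import numpy as np
from sfaeval import (
    ChromophoreLibrary, EvaluationConfig, SkinParameters, SpectrumSet,
    beer_lambert_forward, evenly_spread_gsb, format_report,
    generate_parameter_grid, generate_training_set, run_evaluation,
)

lib = ChromophoreLibrary.from_reference()

# training: 4 levels per parameter -> 256 simulated skin spectra
levels = {
    "s_oxy": tuple(np.linspace(0.1, 1.0, 4)),
    "f_blood": tuple(np.linspace(0.001, 0.01, 4)),
    "c_bilirubin": tuple(np.linspace(0.0, 0.225, 4)),
    "f_melanin": tuple(np.linspace(0.0, 0.1, 4)),
}
training = generate_training_set(generate_parameter_grid(levels), lib)

# test: 50 random skin realisations off the training lattice
rng = np.random.default_rng(1)
params = [SkinParameters(rng.uniform(0.1, 1.0), rng.uniform(0.001, 0.01),
                         rng.uniform(0.0, 0.225), rng.uniform(0.0, 0.1))
          for _ in range(50)]
test = SpectrumSet(lib.grid,
                   np.stack([beer_lambert_forward(p, lib).values for p in params]),
                   kind="test")

config = EvaluationConfig(
    training=training, test=test,
    sensors=(evenly_spread_gsb(3, lib.grid, name="rgb_like"),
             evenly_spread_gsb(9, lib.grid, name="sfa9")),
    seed=0,
)
print(format_report(run_evaluation(config)))
```

prints

```
rmse
sensor                   min         max        mean         std         p98
rgb_like            0.006848    0.074111    0.029920    0.016992    0.068842
sfa9                0.000647    0.007405    0.002641    0.001427    0.005765

delta_e00
sensor                   min         max        mean         std         p98
rgb_like            0.365471    5.215784    2.219832    1.173772    4.556978
sfa9                0.004078    0.124588    0.036923    0.026842    0.089924

delta_oxy_6
sensor                   min         max        mean         std         p98
rgb_like            0.011577    0.448059    0.216401    0.127287    0.428806
sfa9                0.000508    0.101392    0.025348    0.021980    0.068215

delta_oxy_3
sensor                   min         max        mean         std         p98
rgb_like            0.020033   83.841011    8.673870   19.165409   75.308365
sfa9                0.000203   18.696725    1.087310    3.426575   12.329010
```

(provenance header omitted). Reading the numbers: the 9-band Gaussian
camera reconstructs the simulated skin an order of magnitude better than
the 3-band one — mean RMSE 0.0026 vs 0.030 on feature-scaled reflectance,
mean ΔE00 0.04 vs 2.2 (≈2 is one just-noticeable colour difference) — and
its six-wavelength oxygenation estimates land within 2.5 saturation points
of the reference on average, versus 22 points for three bands. The
three-wavelength ΔOxy column illustrates why that estimator needs care:
with three equations for four chromophores the saturation ratio is
unbounded, and occasional near-cancellation of c_ob + c_db produces
extreme outliers.

Real cameras enter through delimited sensitivity tables
(`read_sensor_table`), get Gaussian-band virtual twins via `gsb_twin`
(σ = 15 nm at each sensitivity peak), and crosstalk corrections via
`CorrectionMatrix`. A `sfaeval` CLI exposes `simulate-skin`, `train`,
`evaluate`, `pca` and `report` subcommands.

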