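# Methods

This note documents the models, numerical choices and known limitations of
`sfaeval`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Imaging model and its idealisations

Channel responses are the discrete products Pⱼᵢ = Σₖ E(λₖ)Rⱼ(λₖ)Qᵢ(λₖ) on a
uniform wavelength lattice (default 400–700 nm at 2 nm, N = 151). Two
idealisations are deliberate: **no noise term** and an **equi-energy
illuminant** by default. Both would otherwise interact with the camera
under test — a noise model or a peaked illuminant can favour one sensor
over another — so the comparison is run with neither; the Wiener estimator
exposes a `ridge` parameter through which a noise/regularisation term can
be reintroduced when wanted. Spatial effects (mosaic layout, demosaicing,
PSFs) are out of scope: oxygenation read-outs are averaged over a
homogeneous patch.

## Wiener estimation

The reconstructor is trained in sample-correlation form,
W = K_rp(K_pp + ridge·I)⁻¹ with K_rp = RᵀP/J and K_pp = PᵀP/J. The /J
normalisation cancels in W, so any correlation convention gives the same
matrix; with ridge = 0 and singular K_pp the Moore–Penrose pseudo-inverse
is used, which coincides with the minimum-norm least-squares solution.
Training responses are always simulated internally with the same
illuminant and sensor used at prediction time.

Two practical caveats, both visible in the tests:

- **Conditioning.** Forming K_pp explicitly squares the condition number
  of P. For heavily overlapping bands on near-collinear training spectra,
  agreement with an SVD least-squares solve degrades from machine
  precision to ~1e-8 in the worst random instances. The `ridge` parameter
  is the remedy when this matters.
- **Training-set density.** With a sparse simulated training set (a few
  dozen spectra) a many-channel camera *overfits*: the inverse amplifies
  response directions with tiny training variance, and reconstruction of
  off-training spectra deteriorates with channel count. The expected
  ordering — more Gaussian bands reconstruct better — emerges reliably
  once the training grid is dense (the suite uses 4–5 levels per
  parameter, 256–625 spectra, as the scaled-down analogue of the full
  10⁴-combination design).

Reconstructed reflectances are **not clipped** to [0, 1] by default;
metrics operate on raw reconstructions. An optional `clip` flag clamps
them.

## Skin model

Three plane-parallel homogeneous layers: epidermis (100 µm), dermis
(1 mm), semi-infinite bone; tissue refractive index 1.4 against ambient
1.0. Absorption is assembled from the four simulation parameters
(saturation S, blood volume fraction f_bl, bilirubin concentration C_bi,
melanin volume fraction f_mel):

- epidermis: μa = f_mel · μa,mel(λ), with the melanosome power law
  μa,mel = 6.6·10¹¹ · λ⁻³·³³ cm⁻¹;
- dermis: μa = f_bl·[S·μa,oxy + (1−S)·μa,deoxy] + ln10·(C_bi/PM_bi)·ε_bi,
  with whole-blood absorption from a 150 g/L, 64.5 kg/mol hemoglobin
  molarity and PM_bi = 585 g/mol (bilirubin molar mass);
- bone: flat μa = 0.5 cm⁻¹ baseline.

Scattering is shared by the layers through a reduced-scattering power law
μs′(λ) = a(λ/500 nm)⁻ᵇ with a = 46 cm⁻¹, b = 1.4 (typical dermis),
g = 0.9 and μs = μs′/(1−g). All geometric and scattering values are
configurable (`LayerGeometry`, `ScatteringConfig`); they are stated
defaults, not fitted quantities.

The default parameter grid is 10 levels per parameter — S: 10–100%, f_bl:
0.1–1%, C_bi: 0–0.225 (model units), f_mel: 0 and 2–10% — a full
factorial of 10,000 combinations in deterministic lexicographic order
(S outermost, f_mel innermost). The melanin range corresponds to fair
skin; the model is not validated for darker skin types, which is a known
limitation inherited from its three-layer design.

The bilirubin concentration unit in the level table is not standardised;
the Monte Carlo engine applies the ε→μa conversion literally (C_bi/PM_bi
in mol/L), which makes the blue-region absorption of the highest bilirubin
levels strong. This affects realism of the blue end only; every
quantitative check in the suite is unit-consistent by construction.

## Monte Carlo transport

A standard weighted-photon walk: dimensionless step −ln ξ scaled by μt,
weight deposition μa/μt per interaction, Henyey–Greenstein scattering,
unpolarised Fresnel reflection/refraction at index mismatches, Russian
roulette below weight 1e-4 with survival chance 0.1. The loop is
numba-compiled; a fixed seed gives bitwise-reproducible results, and
per-wavelength/per-spectrum seeds are derived from the master seed via
`SeedSequence`, so generated sets are reproducible as a whole.

Validation uses two independent routes rather than published benchmark
tables: (1) energy conservation in a purely scattering matched slab
(Rd + Td = 1 within Monte Carlo error); (2) an exact closed form — for a
semi-infinite isotropically scattering matched medium the diffuse
reflectance under normal incidence is R = 1 − H(1)√(1−ω) with
Chandrasekhar's H-function, solved by fixed-point iteration of its
integral equation (itself verified against the conservative-limit value
H(1) = 2.90781 and the moment identity ∫H = 2(1−√(1−ω))/ω). For ω = 0.9
this gives R = 0.41495, which the walk reproduces within its standard
error. An analog (unweighted) walker provides a third cross-check for
anisotropic scattering.

The default photon budget is 10⁴ photons per wavelength — a desk-scale
regime chosen so a full spectrum simulates in seconds; the budget is a
`TransportConfig` field. Tests that need spectra from the Monte Carlo
engine simulate a wavelength subset and interpolate, which is the
supported resolution/time trade-off.

## Beer–Lambert engine and oxygenation estimation

The fast engine writes total absorbance as A(λ) = c_m·l_e·ε_m +
l_d·(c_bi·ε_bi + c_ob·ε_ob + c_db·ε_db) + D(λ) and returns R = 10⁻ᴬ. The
default path-length model is deliberately degenerate — l_e = l_d = 1,
D ≡ 0 — because the multiple-regression estimator assumes exactly
A = Σc·ε; with this default, forward simulation and estimation are exact
inverses (coefficients recover to ~1e-10, property-tested). Mapping the
simulation parameters to contributions uses fixed documented scales
(`ContributionScales`): the blood scale is ln10 × hemoglobin molarity × an
effective 0.2 cm dermal path; melanin and bilirubin scales are effective
path factors chosen once so mid-range parameters give absorbances of
order 0.1–1. Because S_oxy = c_ob/(c_ob+c_db) is scale-free in the blood
pair, the saturation recovered from these spectra equals the simulation
parameter S exactly.

The estimator solves the n×4 extinction system by `lstsq`: ordinary least
squares when overdetermined; for the three-wavelength set (3 equations, 4
chromophores) the minimum-norm pseudo-inverse solution is used — no
chromophore is dropped. Coefficients are unconstrained (negative values
allowed). When c_ob + c_db = 0 the saturation is reported as *undefined*
(a typed signal, not NaN) and propagates through ΔOxy. Reflectance is
floored at 1e-6 before the log so reconstructed spectra that dip to or
below zero stay finite. The three-wavelength estimator is fragile by
construction: near-cancellation of c_ob + c_db can produce saturations
far outside [0, 1], and ΔOxy outliers in the hundreds are possible on
spectra that do not live in the chromophore span.

Both reference and reconstructed saturations are computed on the same
representation the reconstruction pipeline uses (feature-scaled
reflectance when scaling is enabled), so the ΔOxy comparison is
like-for-like.

## Feature scaling, colorimetry, PCA

- Feature scaling is one global affine map per set onto [0, 1] — not
  per-spectrum (which would destroy relative brightness between skin
  tones) and not per-wavelength.
- XYZ uses k = 100/Σ(E·ȳ·Δλ) so the perfect reflector has Y = 100; Lab is
  the standard transform with the linear branch at (6/29)³; ΔE00
  implements the full CIEDE2000 formula (SL, SC, SH, RT) and is verified
  against published verification pairs and an independently coded
  reference.
- Set-diversity PCA stacks all sets, centres at the **combined** mean and
  takes principal axes of the joint covariance; each set's variance along
  a component is measured about that set's own projected mean and
  reported as a percentage of the set's total variance. Per-set
  re-centring before projection is *not* applied; this is one of two
  defensible conventions and is the documented one. Extreme members
  (min/max on PC1/PC2) resolve ties to the lowest row index and carry
  their generating skin parameters when the set is simulated.

## Bundled reference data

Colour-matching functions are generated from the published multi-lobe
piecewise-Gaussian analytic fits of the CIE 1931 2° observer (~1%
accuracy); D65 is the canonical 10 nm tabulation; hemoglobin and
bilirubin extinctions are approximate compiled literature values at 10 nm,
linearly interpolated. These tables set the *realism* of colour
rendering and simulated spectra; no quantitative check in the suite
depends on their absolute accuracy, because every such check is either an
internal-consistency property (forward model vs inverse on the same
library) or a closed-form/independent-implementation comparison. A fully
synthetic chromophore library (triangular extinction curves with full
column rank at the six regression wavelengths) ships so unit tests run
without any real-world table.

## What the synthetic data does and does not show

The simulated-skin generator and the synthetic "skin-like" test set
emulate: reflectances in [0, 1] on the common lattice, the hemoglobin
W-shaped dip at 540–580 nm, a melanin short-wavelength slope, and
parameter-driven family structure. They do not emulate: measurement
noise, specular glare, inter-patient texture, darker skin types, or
wavelength-dependent path-length effects (the degenerate Beer–Lambert
default). Passing tests therefore demonstrate the correctness of the
pipeline's algebra, transport physics and orderings under the stated
model, not clinical accuracy on measured skin; real sensitivity tables
and measured reflectance databases plug in through the delimited-text
loaders.
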