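"""Three-layer optical skin model and simulated-reflectance generation.

The model is the classical epidermis / dermis / bone stack parameterised by
four chromophore parameters: oxygen saturation S, dermal blood volume
fraction f_bl, bilirubin concentration C_bi and epidermal melanin volume
fraction f_mel.  Per-layer absorption is assembled as

    mu_a,epi(l)  = f_mel * mu_a,mel(l)
    mu_a,derm(l) = f_bl * mu_a,blood(l) + mu_a,bili(l)
    mu_a,bili(l) = ln(10) * (C_bi / PM_bi) * eps_bi(l)
    mu_a,blood(l) = S * mu_a,oxy(l) + (1 - S) * mu_a,deoxy(l)

while scattering follows a reduced-scattering power law applied uniformly
to both tissue layers.  Reflectance spectra can be produced either with the
Monte Carlo transport engine (physical, slow) or with a simplified
Beer-Lambert forward model (fast, and exactly invertible by the
multiple-regression oxygenation estimator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .grids import DEFAULT_GRID, Spectrum, SpectrumSet, WavelengthGrid
from .mcml import MCResult, TransportConfig, run_transport
from .reference_data import load_reference

__all__ = [
    "SkinParameters",
    "ChromophoreLibrary",
    "LayerOpticalProperties",
    "ScatteringConfig",
    "LayerGeometry",
    "PathLengthModel",
    "ContributionScales",
    "TABLE2_LEVELS",
    "build_optical_properties",
    "mc_reflectance",
    "beer_lambert_forward",
    "beer_lambert_from_contributions",
    "contributions_from_parameters",
    "generate_parameter_grid",
    "generate_training_set",
]

WHOLE_BLOOD_HB_MOLARITY = 150.0 / 64500.0  # mol/L: 150 g/L hemoglobin, 64.5 kg/mol


@dataclass(frozen=True)
class SkinParameters:
    """The four simulation parameters of one skin realisation."""

    s_oxy: float  # oxygen saturation of dermal blood, [0, 1]
    f_blood: float  # dermal blood volume fraction
    c_bilirubin: float  # bilirubin concentration (model units, g/L scale)
    f_melanin: float  # epidermal melanin (melanosome) volume fraction

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_oxy <= 1.0:
            raise ValueError(f"s_oxy must lie in [0, 1], got {self.s_oxy}")
        for name in ("f_blood", "c_bilirubin", "f_melanin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {
            "s_oxy": self.s_oxy,
            "f_blood": self.f_blood,
            "c_bilirubin": self.c_bilirubin,
            "f_melanin": self.f_melanin,
        }


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Absorption/extinction spectra of the four modelled chromophores."""

    grid: WavelengthGrid
    mu_a_melanin: np.ndarray  # 1/cm, melanosome interior
    mu_a_blood_oxy: np.ndarray  # 1/cm, fully oxygenated whole blood
    mu_a_blood_deoxy: np.ndarray  # 1/cm, fully deoxygenated whole blood
    eps_bilirubin: np.ndarray  # molar extinction, cm^-1/M
    eps_oxy: np.ndarray
    eps_deoxy: np.ndarray
    eps_melanin: np.ndarray
    pm_bilirubin: float = 585.0  # bilirubin molar mass, g/mol

    def __post_init__(self) -> None:
        n = self.grid.n_points
        for name in (
            "mu_a_melanin",
            "mu_a_blood_oxy",
            "mu_a_blood_deoxy",
            "eps_bilirubin",
            "eps_oxy",
            "eps_deoxy",
            "eps_melanin",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have {n} samples")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)

    def extinction_matrix(self, wavelengths) -> np.ndarray:
        """n x 4 design matrix (eps_mel, eps_bi, eps_oxy, eps_deoxy) at the
        requested lattice wavelengths - the regression matrix for
        oxygenation estimation."""
        idx = [self.grid.index_of(w) for w in wavelengths]
        return np.column_stack(
            [
                self.eps_melanin[idx],
                self.eps_bilirubin[idx],
                self.eps_oxy[idx],
                self.eps_deoxy[idx],
            ]
        )

    @classmethod
    def from_reference(
        cls, name: str = "chromophores_jacques", grid: WavelengthGrid = DEFAULT_GRID
    ) -> "ChromophoreLibrary":
        tab = load_reference(name, grid)
        eps_ob = tab.column("eps_oxy_hb")
        eps_db = tab.column("eps_deoxy_hb")
        ln10 = np.log(10.0)
        if name == "chromophores_jacques":
            mu_mel = tab.column("eps_melanin")  # already on the 1/cm power law
        else:
            mu_mel = tab.column("eps_melanin") * 1e-2
        return cls(
            grid=grid,
            mu_a_melanin=mu_mel,
            mu_a_blood_oxy=ln10 * eps_ob * WHOLE_BLOOD_HB_MOLARITY,
            mu_a_blood_deoxy=ln10 * eps_db * WHOLE_BLOOD_HB_MOLARITY,
            eps_bilirubin=tab.column("eps_bilirubin"),
            eps_oxy=eps_ob,
            eps_deoxy=eps_db,
            eps_melanin=tab.column("eps_melanin"),
        )


@dataclass(frozen=True)
class ScatteringConfig:
    """Reduced-scattering power law mu_s'(l) = a * (l / l0)^-b, shared by the
    tissue layers; mu_s = mu_s' / (1 - g)."""

    a: float = 46.0  # cm^-1 at the reference wavelength (typical dermis)
    b: float = 1.4
    reference_nm: float = 500.0
    g: float = 0.9

    def mu_s(self, wavelengths: np.ndarray) -> np.ndarray:
        mus_prime = self.a * (np.asarray(wavelengths) / self.reference_nm) ** (-self.b)
        return mus_prime / (1.0 - self.g)


@dataclass(frozen=True)
class LayerGeometry:
    """Layer thicknesses (cm), refractive indices and bone baseline absorption."""

    epidermis_cm: float = 0.01
    dermis_cm: float = 0.1
    n_tissue: float = 1.4
    n_ambient: float = 1.0
    bone_mu_a: float = 0.5  # flat baseline absorption of the bottom layer, 1/cm


@dataclass(frozen=True)
class LayerOpticalProperties:
    """Spectral optical properties of one homogeneous layer."""

    name: str
    mu_a: np.ndarray  # 1/cm (spectrum or scalar)
    mu_s: np.ndarray
    g: float
    n: float
    thickness: float  # cm; inf = semi-infinite

    def at(self, k: int) -> tuple:
        """(mu_a, mu_s, g, n, thickness) at wavelength index k."""
        mu_a = np.atleast_1d(self.mu_a)
        mu_s = np.atleast_1d(self.mu_s)
        return (
            float(mu_a[k if mu_a.size > 1 else 0]),
            float(mu_s[k if mu_s.size > 1 else 0]),
            self.g,
            self.n,
            self.thickness,
        )


def build_optical_properties(
    params: SkinParameters,
    lib: ChromophoreLibrary,
    scatter: ScatteringConfig = ScatteringConfig(),
    geometry: LayerGeometry = LayerGeometry(),
) -> tuple:
    """Assemble (epidermis, dermis, bone) optical properties for one
    parameter combination."""
    wl = lib.grid.wavelengths
    mu_s = scatter.mu_s(wl)
    mu_a_epi = params.f_melanin * lib.mu_a_melanin
    mu_a_blood = params.s_oxy * lib.mu_a_blood_oxy + (1.0 - params.s_oxy) * lib.mu_a_blood_deoxy
    mu_a_bili = np.log(10.0) * (params.c_bilirubin / lib.pm_bilirubin) * lib.eps_bilirubin
    mu_a_derm = params.f_blood * mu_a_blood + mu_a_bili
    epi = LayerOpticalProperties(
        "epidermis", mu_a_epi, mu_s, scatter.g, geometry.n_tissue, geometry.epidermis_cm
    )
    derm = LayerOpticalProperties(
        "dermis", mu_a_derm, mu_s, scatter.g, geometry.n_tissue, geometry.dermis_cm
    )
    bone = LayerOpticalProperties(
        "bone",
        np.full_like(wl, geometry.bone_mu_a),
        mu_s,
        scatter.g,
        geometry.n_tissue,
        np.inf,
    )
    return epi, derm, bone


def mc_reflectance(
    layers,
    config: TransportConfig = TransportConfig(),
    grid: WavelengthGrid = DEFAULT_GRID,
    n_ambient: float = 1.0,
    wavelength_indices=None,
) -> Spectrum:
    """Diffuse reflectance spectrum of a layer stack by Monte Carlo transport.

    One independent photon walk per wavelength; the per-wavelength seed is
    derived deterministically from ``config.seed`` so a fixed seed gives a
    bitwise reproducible spectrum.  ``wavelength_indices`` restricts the
    simulation to a subset of lattice points (the rest are linearly
    interpolated), which is the supported way to trade resolution for time.
    """
    n = grid.n_points
    idx = np.arange(n) if wavelength_indices is None else np.asarray(wavelength_indices)
    rd = np.empty(idx.size)
    for j, k in enumerate(idx):
        sub_seed = int(
            np.random.SeedSequence([int(config.seed), int(k)]).generate_state(1)[0]
            % (2**31)
        )
        cfg = TransportConfig(
            config.photons_per_wavelength,
            sub_seed,
            config.weight_threshold,
            config.roulette_chance,
        )
        res = run_transport(
            [lay.at(int(k)) for lay in layers], cfg, n_above=n_ambient, n_below=n_ambient
        )
        rd[j] = res.rd
    if wavelength_indices is None:
        values = rd
    else:
        values = np.interp(grid.wavelengths, grid.wavelengths[idx], rd)
    return Spectrum(grid, values)


# ---------------------------------------------------------------------------
# Beer-Lambert fast forward model


@dataclass(frozen=True)
class PathLengthModel:
    """Mean optical path lengths and scattering attenuation for the
    Beer-Lambert engine.

    The degenerate default (unit paths, zero scattering loss) makes the
    total absorbance exactly the linear combination sum(c_i * eps_i) that
    the multiple-regression oxygenation estimator assumes, so forward
    simulation and estimation are exact inverses of one another.
    """

    l_epi: float | np.ndarray = 1.0
    l_derm: float | np.ndarray = 1.0
    d_scatter: float | np.ndarray = 0.0


@dataclass(frozen=True)
class ContributionScales:
    """Unit conversions from the simulation parameters to the dimensionless
    extinction contributions of the Beer-Lambert engine.

    The blood scale is ln(10) x hemoglobin molarity of whole blood x an
    effective dermal path of 0.2 cm; melanin and bilirubin scales are
    effective-path factors chosen so mid-range parameter values produce
    skin-like absorbances of order 0.1-1.
    """

    melanin: float = 7.0e-3
    bilirubin: float = 2.8e-5
    blood: float = float(np.log(10.0) * WHOLE_BLOOD_HB_MOLARITY * 0.2)


def contributions_from_parameters(
    params: SkinParameters, scales: ContributionScales = ContributionScales()
) -> np.ndarray:
    """(c_mel, c_bi, c_oxy, c_deoxy) for the Beer-Lambert forward model."""
    return np.array(
        [
            scales.melanin * params.f_melanin,
            scales.bilirubin * params.c_bilirubin,
            scales.blood * params.f_blood * params.s_oxy,
            scales.blood * params.f_blood * (1.0 - params.s_oxy),
        ]
    )


def beer_lambert_from_contributions(
    c, lib: ChromophoreLibrary, plm: PathLengthModel = PathLengthModel()
) -> Spectrum:
    """Reflectance 10^-A with A = cm*le*eps_m + (cbi*eps_bi + cob*eps_ob +
    cdb*eps_db)*ld + D."""
    cm, cbi, cob, cdb = (float(v) for v in c)
    absorbance = (
        cm * np.asarray(plm.l_epi) * lib.eps_melanin
        + np.asarray(plm.l_derm)
        * (cbi * lib.eps_bilirubin + cob * lib.eps_oxy + cdb * lib.eps_deoxy)
        + np.asarray(plm.d_scatter)
    )
    return Spectrum(lib.grid, 10.0 ** (-absorbance))


def beer_lambert_forward(
    params: SkinParameters,
    lib: ChromophoreLibrary,
    plm: PathLengthModel = PathLengthModel(),
    scales: ContributionScales = ContributionScales(),
) -> Spectrum:
    """Fast skin reflectance from the simplified Beer-Lambert law."""
    return beer_lambert_from_contributions(
        contributions_from_parameters(params, scales), lib, plm
    )


# ---------------------------------------------------------------------------
# parameter grid and set generation

#: Default simulation levels: 10 values per parameter, full factorial =
#: 10,000 combinations.  Saturation spans 10-100%, blood volume 0.1-1%,
#: bilirubin 0-0.225 (model units) and melanin 0 plus 2-10%.
TABLE2_LEVELS = {
    "s_oxy": tuple(np.round(np.arange(1, 11) * 0.1, 10)),
    "f_blood": tuple(np.round(np.arange(1, 11) * 0.001, 10)),
    "c_bilirubin": tuple(np.round(np.arange(0, 10) * 0.025, 10)),
    "f_melanin": (0.0, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10),
}


def generate_parameter_grid(levels: dict | None = None) -> list:
    """Full Cartesian product of the per-parameter levels.

    Deterministic lexicographic order with s_oxy outermost and f_melanin
    innermost.
    """
    levels = dict(TABLE2_LEVELS if levels is None else levels)
    for key in ("s_oxy", "f_blood", "c_bilirubin", "f_melanin"):
        if key not in levels or len(levels[key]) == 0:
            raise ValueError(f"parameter {key!r} needs at least one level")
    return [
        SkinParameters(s, fb, cb, fm)
        for s, fb, cb, fm in itertools.product(
            levels["s_oxy"], levels["f_blood"], levels["c_bilirubin"], levels["f_melanin"]
        )
    ]


def generate_training_set(
    grid_params,
    lib: ChromophoreLibrary,
    engine: str = "beer_lambert",
    config: TransportConfig | None = None,
    plm: PathLengthModel = PathLengthModel(),
    scales: ContributionScales = ContributionScales(),
    scatter: ScatteringConfig = ScatteringConfig(),
    geometry: LayerGeometry = LayerGeometry(),
    wavelength_indices=None,
) -> SpectrumSet:
    """One reflectance spectrum per parameter combination.

    ``engine`` selects the fast Beer-Lambert model or the Monte Carlo
    transport engine.  Monte Carlo runs derive a per-spectrum seed from the
    master seed in ``config`` so the whole set is reproducible bit for bit.
    """
    grid_params = list(grid_params)
    if not grid_params:
        raise ValueError("no parameter combinations supplied")
    rows = np.empty((len(grid_params), lib.grid.n_points))
    if engine == "beer_lambert":
        for j, p in enumerate(grid_params):
            rows[j] = beer_lambert_forward(p, lib, plm, scales).values
    elif engine == "monte_carlo":
        config = config or TransportConfig()
        for j, p in enumerate(grid_params):
            layers = build_optical_properties(p, lib, scatter, geometry)
            sub_seed = int(
                np.random.SeedSequence([int(config.seed), 7919, j]).generate_state(1)[0]
                % (2**31)
            )
            cfg = TransportConfig(
                config.photons_per_wavelength,
                sub_seed,
                config.weight_threshold,
                config.roulette_chance,
            )
            rows[j] = mc_reflectance(
                layers,
                cfg,
                lib.grid,
                n_ambient=geometry.n_ambient,
                wavelength_indices=wavelength_indices,
            ).values
    else:
        raise ValueError(f"unknown engine {engine!r}; use beer_lambert or monte_carlo")
    labels = tuple(f"sim{j}" for j in range(len(grid_params)))
    return SpectrumSet(lib.grid, rows, labels, kind="simulated", meta=tuple(grid_params))
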