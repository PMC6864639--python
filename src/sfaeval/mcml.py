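"""Weighted-photon Monte Carlo transport in plane-parallel layered tissue.

Implements the standard multi-layer MCML random walk: photons carry a
weight, take steps of dimensionless length -ln(xi) scaled by the local
interaction coefficient, deposit the fraction mu_a/mu_t of their weight at
each interaction, scatter into new directions drawn from the
Henyey-Greenstein phase function, undergo Fresnel reflection/refraction at
refractive-index boundaries, and are terminated by Russian roulette once
their weight falls below a threshold.  The tallies are total diffuse
reflectance Rd, total transmittance Td and absorbed fraction Ad, with
Monte Carlo standard errors for the escaping quantities.

The photon loop is compiled with numba; a fixed seed gives bitwise
reproducible results on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["TransportConfig", "MCResult", "run_transport"]


@dataclass(frozen=True)
class TransportConfig:
    """Engine controls: photon budget, seed and Russian-roulette policy."""

    photons_per_wavelength: int = 10_000
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_chance: float = 0.1

    def __post_init__(self) -> None:
        if self.photons_per_wavelength < 1:
            raise ValueError("need at least one photon")
        if not 0.0 < self.roulette_chance <= 1.0:
            raise ValueError("roulette_chance must be in (0, 1]")
        if self.weight_threshold < 0:
            raise ValueError("weight_threshold must be non-negative")


@dataclass(frozen=True)
class MCResult:
    rd: float  # diffuse reflectance (specular excluded)
    td: float  # diffuse transmittance
    ad: float  # absorbed fraction
    specular: float  # specular reflection at the top surface
    se_rd: float
    se_td: float
    n_photons: int


@njit(cache=False)
def _fresnel(ni, nt, cos_i):
    """Unpolarised Fresnel reflectance and transmitted cosine."""
    if ni == nt:
        return 0.0, cos_i
    if cos_i > 0.99999:  # normal incidence
        r = ((ni - nt) / (ni + nt)) ** 2
        return r, 1.0
    sin_i = np.sqrt(1.0 - cos_i * cos_i)
    sin_t = ni * sin_i / nt
    if sin_t >= 1.0:  # total internal reflection
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    cap = cos_i * cos_t - sin_i * sin_t
    cam = cos_i * cos_t + sin_i * sin_t
    sap = sin_i * cos_t + cos_i * sin_t
    sam = sin_i * cos_t - cos_i * sin_t
    r = 0.5 * sam * sam * (cap * cap + cam * cam) / (sap * sap * cam * cam)
    return r, cos_t


@njit(cache=False)
def _transport_kernel(
    n_photons, mu_a, mu_s, g, n_layer, z0, z1, n_above, n_below, seed, wth, pchance
):
    np.random.seed(seed)
    n_lay = mu_a.shape[0]

    # specular reflection of the collimated beam at the top surface
    rsp = 0.0
    if n_above != n_layer[0]:
        rsp = ((n_above - n_layer[0]) / (n_above + n_layer[0])) ** 2

    sum_r = 0.0
    sum_r2 = 0.0
    sum_t = 0.0
    sum_t2 = 0.0
    sum_a = 0.0

    for _ in range(n_photons):
        w = 1.0 - rsp
        lay = 0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        sleft = 0.0
        esc_r = 0.0
        esc_t = 0.0
        alive = True
        while alive:
            mt = mu_a[lay] + mu_s[lay]
            if sleft <= 0.0:
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                sleft = -np.log(xi)
            # distance to the layer boundary along the current direction
            if uz > 0.0:
                db = (z1[lay] - z) / uz
            elif uz < 0.0:
                db = (z0[lay] - z) / uz
            else:
                db = 1.0e30
            step = sleft / mt
            if db < step:
                # move to the boundary, bank the unused dimensionless step
                z += db * uz
                sleft -= db * mt
                going_down = uz > 0.0
                ni = n_layer[lay]
                if going_down:
                    nt = n_layer[lay + 1] if lay + 1 < n_lay else n_below
                else:
                    nt = n_layer[lay - 1] if lay - 1 >= 0 else n_above
                cos_i = abs(uz)
                r, cos_t = _fresnel(ni, nt, cos_i)
                if np.random.random() > r:
                    # transmit
                    scale = ni / nt
                    ux *= scale
                    uy *= scale
                    if going_down:
                        if lay + 1 < n_lay:
                            lay += 1
                            uz = cos_t
                        else:
                            esc_t = w
                            alive = False
                    else:
                        if lay - 1 >= 0:
                            lay -= 1
                            uz = -cos_t
                        else:
                            esc_r = w
                            alive = False
                else:
                    uz = -uz
            else:
                # full interaction inside the layer
                z += step * uz
                sleft = 0.0
                dw = w * mu_a[lay] / mt
                w -= dw
                sum_a += dw
                # Henyey-Greenstein scattering
                gl = g[lay]
                if gl == 0.0:
                    cost = 2.0 * np.random.random() - 1.0
                else:
                    tmp = (1.0 - gl * gl) / (1.0 - gl + 2.0 * gl * np.random.random())
                    cost = (1.0 + gl * gl - tmp * tmp) / (2.0 * gl)
                    if cost < -1.0:
                        cost = -1.0
                    elif cost > 1.0:
                        cost = 1.0
                sint = np.sqrt(1.0 - cost * cost)
                phi = 2.0 * np.pi * np.random.random()
                cosp = np.cos(phi)
                sinp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux = sint * cosp
                    uy = sint * sinp
                    uz = cost if uz >= 0.0 else -cost
                else:
                    tmp = np.sqrt(1.0 - uz * uz)
                    nux = sint * (ux * uz * cosp - uy * sinp) / tmp + ux * cost
                    nuy = sint * (uy * uz * cosp + ux * sinp) / tmp + uy * cost
                    nuz = -sint * cosp * tmp + uz * cost
                    ux, uy, uz = nux, nuy, nuz
                # Russian roulette
                if w < wth:
                    if np.random.random() < pchance:
                        w /= pchance
                    else:
                        alive = False
        sum_r += esc_r
        sum_r2 += esc_r * esc_r
        sum_t += esc_t
        sum_t2 += esc_t * esc_t

    return sum_r, sum_r2, sum_t, sum_t2, sum_a, rsp


def run_transport(
    layers,
    config: TransportConfig = TransportConfig(),
    n_above: float = 1.0,
    n_below: float = 1.0,
) -> MCResult:
    """Run the photon walk through a stack of single-wavelength layers.

    ``layers`` is a sequence of objects (or 5-tuples) providing scalar
    ``mu_a``, ``mu_s``, ``g``, ``n`` and ``thickness`` (cm; ``inf`` for a
    semi-infinite bottom layer).  ``n_above``/``n_below`` are the ambient
    refractive indices.
    """
    mu_a, mu_s, g, n_idx, thick = [], [], [], [], []
    for lay in layers:
        if isinstance(lay, tuple):
            a, s, gg, nn, th = lay
        else:
            a, s, gg, nn, th = lay.mu_a, lay.mu_s, lay.g, lay.n, lay.thickness
        a, s = float(np.asarray(a)), float(np.asarray(s))
        if a < 0 or s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if a == 0.0 and s == 0.0 and np.isfinite(th):
            raise ValueError(
                "a finite layer with mu_a = mu_s = 0 has an infinite free path"
            )
        mu_a.append(a)
        mu_s.append(s)
        g.append(float(gg))
        n_idx.append(float(nn))
        thick.append(float(th))
    thick = np.asarray(thick)
    if not np.all(thick > 0):
        raise ValueError("layer thicknesses must be positive")
    z0 = np.concatenate(([0.0], np.cumsum(thick[:-1])))
    z1 = z0 + thick

    n_ph = config.photons_per_wavelength
    sr, sr2, st, st2, sa, rsp = _transport_kernel(
        n_ph,
        np.asarray(mu_a),
        np.asarray(mu_s),
        np.asarray(g),
        np.asarray(n_idx),
        z0,
        z1,
        float(n_above),
        float(n_below),
        int(config.seed) % (2**32),
        config.weight_threshold,
        config.roulette_chance,
    )
    rd = sr / n_ph
    td = st / n_ph
    se_rd = np.sqrt(max(sr2 / n_ph - rd**2, 0.0) / n_ph)
    se_td = np.sqrt(max(st2 / n_ph - td**2, 0.0) / n_ph)
    return MCResult(rd, td, sa / n_ph, rsp, se_rd, se_td, n_ph)
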