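"""Colorimetric conversions: reflectance -> XYZ -> CIELAB, CIEDE2000, sRGB.

Conventions follow standard CIE practice: tristimulus values are normalised
so a perfect reflector has Y = 100 under the working illuminant, and CIELAB
uses the cube-root transform with the linear branch below (6/29)^3.  The
default observer is the CIE 1931 2 degree standard observer and the default
illuminant for colour difference is D65.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Illuminant, Spectrum, WavelengthGrid

__all__ = [
    "ColorValue",
    "spectrum_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "ciede2000",
    "xyz_to_srgb",
    "CIEDE2000_TEST_PAIRS",
]


@dataclass(frozen=True)
class ColorValue:
    space: str  # "XYZ" or "Lab"
    components: tuple
    illuminant: str = "D65"
    observer: str = "CIE 1931 2deg"

    def __post_init__(self) -> None:
        if self.space not in ("XYZ", "Lab"):
            raise ValueError(f"unknown color space {self.space!r}")
        if len(self.components) != 3:
            raise ValueError("a color has exactly three components")
        object.__setattr__(self, "components", tuple(float(c) for c in self.components))


def spectrum_to_xyz(
    r: Spectrum, illum: Illuminant, cmf: np.ndarray, illuminant_name: str = "D65"
) -> ColorValue:
    """Integrate a reflectance against an illuminant and colour-matching functions.

    ``cmf`` is an N x 3 array of (xbar, ybar, zbar) on the spectrum's grid.
    The normalisation constant k = 100 / sum(E * ybar * dl) makes the perfect
    reflector come out at Y = 100.
    """
    if illum.grid != r.grid:
        raise ValueError("spectrum and illuminant are on different grids")
    cmf = np.asarray(cmf, dtype=float)
    if cmf.shape != (r.grid.n_points, 3):
        raise ValueError(
            f"cmf must be {r.grid.n_points} x 3 for this grid, got {cmf.shape}"
        )
    dl = r.grid.step  # constant on a uniform lattice; cancels in k
    k = 100.0 / np.sum(illum.spd * cmf[:, 1] * dl)
    xyz = k * np.sum((illum.spd * r.values)[:, None] * cmf * dl, axis=0)
    return ColorValue("XYZ", tuple(xyz), illuminant_name)


_DELTA3 = (6.0 / 29.0) ** 3


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA3, np.cbrt(t), t / (3 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)


def xyz_to_lab(c: ColorValue, white: ColorValue) -> ColorValue:
    """CIE 1976 L*a*b* relative to a white point with Y = 100."""
    if c.space != "XYZ" or white.space != "XYZ":
        raise ValueError("xyz_to_lab needs XYZ inputs")
    wn = np.asarray(white.components)
    if np.any(wn <= 0):
        raise ValueError("white point components must be positive")
    fx, fy, fz = _lab_f(np.asarray(c.components) / wn)
    lab = (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))
    return ColorValue("Lab", lab, c.illuminant, c.observer)


def lab_to_xyz(c: ColorValue, white: ColorValue) -> ColorValue:
    """Inverse of :func:`xyz_to_lab` (used for round-trip checks)."""
    if c.space != "Lab":
        raise ValueError("lab_to_xyz needs a Lab input")
    L, a, b = c.components
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0

    def finv(f):
        d = 6.0 / 29.0
        return f**3 if f > d else 3 * d**2 * (f - 4.0 / 29.0)

    wn = np.asarray(white.components)
    xyz = wn * np.array([finv(fx), finv(fy), finv(fz)])
    return ColorValue("XYZ", tuple(xyz), c.illuminant, c.observer)


def ciede2000(lab1, lab2) -> float:
    """CIEDE2000 colour difference between two CIELAB triples.

    Full formula including the lightness, chroma and hue weighting functions
    SL, SC, SH and the rotation term RT, with the parametric factors kL = kC
    = kH = 1.
    """
    if isinstance(lab1, ColorValue):
        lab1 = lab1.components
    if isinstance(lab2, ColorValue):
        lab2 = lab2.components
    L1, a1, b1 = (float(v) for v in lab1)
    L2, a2, b2 = (float(v) for v in lab2)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p, a2p = (1.0 + G) * a1, (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    def hue(a, b):
        if a == 0.0 and b == 0.0:
            return 0.0
        h = np.degrees(np.arctan2(b, a))
        return h + 360.0 if h < 0 else h

    h1p, h2p = hue(a1p, b1), hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p
    if C1p * C2p == 0.0:
        dhp = 0.0
    else:
        d = h2p - h1p
        if abs(d) <= 180.0:
            dhp = d
        elif d > 180.0:
            dhp = d - 360.0
        else:
            dhp = d + 360.0
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    if C1p * C2p == 0.0:
        hbp = h1p + h2p
    else:
        s = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbp = 0.5 * s
        elif s < 360.0:
            hbp = 0.5 * (s + 360.0)
        else:
            hbp = 0.5 * (s - 360.0)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    return float(
        np.sqrt(
            (dLp / SL) ** 2
            + (dCp / SC) ** 2
            + (dHp / SH) ** 2
            + RT * (dCp / SC) * (dHp / SH)
        )
    )


#: Published verification pairs for the CIEDE2000 formula: (L1, a1, b1, L2,
#: a2, b2, expected dE00).  These exercise every branch of the formula (hue
#: discontinuity, the G chroma correction, the rotation term).
CIEDE2000_TEST_PAIRS = (
    (50.0, 2.6772, -79.7751, 50.0, 0.0, -82.7485, 2.0425),
    (50.0, 3.1571, -77.2803, 50.0, 0.0, -82.7485, 2.8615),
    (50.0, 2.8361, -74.0200, 50.0, 0.0, -82.7485, 3.4412),
    (50.0, -1.3802, -84.2814, 50.0, 0.0, -82.7485, 1.0000),
    (50.0, -1.1848, -84.8006, 50.0, 0.0, -82.7485, 1.0000),
    (50.0, -0.9009, -85.5211, 50.0, 0.0, -82.7485, 1.0000),
    (50.0, 0.0, 0.0, 50.0, -1.0, 2.0, 2.3669),
    (50.0, -1.0, 2.0, 50.0, 0.0, 0.0, 2.3669),
    (50.0, 2.49, -0.001, 50.0, -2.49, 0.0009, 7.1792),
    (50.0, 2.49, -0.001, 50.0, -2.49, 0.0010, 7.1792),
    (50.0, 2.49, -0.001, 50.0, -2.49, 0.0011, 7.2195),
    (50.0, 2.49, -0.001, 50.0, -2.49, 0.0012, 7.2195),
    (50.0, -0.001, 2.49, 50.0, 0.0009, -2.49, 4.8045),
    (50.0, -0.001, 2.49, 50.0, 0.0010, -2.49, 4.8045),
    (50.0, -0.001, 2.49, 50.0, 0.0011, -2.49, 4.7461),
    (50.0, 2.5, 0.0, 73.0, 25.0, -18.0, 27.1492),
    (50.0, 2.5, 0.0, 61.0, -5.0, 29.0, 22.8977),
    (50.0, 2.5, 0.0, 56.0, -27.0, -3.0, 31.9030),
    (50.0, 2.5, 0.0, 58.0, 24.0, 15.0, 19.4535),
    (50.0, 2.5, 0.0, 50.0, 3.1736, 0.5854, 1.0000),
    (50.0, 2.5, 0.0, 50.0, 3.2972, 0.0, 1.0000),
    (50.0, 2.5, 0.0, 50.0, 1.8634, 0.5757, 1.0000),
    (50.0, 2.5, 0.0, 50.0, 3.2592, 0.3350, 1.0000),
    (60.2574, -34.0099, 36.2677, 60.4626, -34.1751, 39.4387, 1.2644),
    (63.0109, -31.0961, -5.8663, 62.8187, -29.7946, -4.0864, 1.2630),
    (61.2901, 3.7196, -5.3901, 61.4292, 2.2480, -4.9620, 1.8731),
    (35.0831, -44.1164, 3.7933, 35.0232, -40.0716, 1.5901, 1.8645),
    (22.7233, 20.0904, -46.6940, 23.0331, 14.9730, -42.5619, 2.0373),
    (36.4612, 47.8580, 18.3852, 36.2715, 50.5065, 21.2231, 1.4146),
    (90.8027, -2.0831, 1.4410, 91.1528, -1.6435, 0.0447, 1.4441),
    (90.9257, -0.5406, -0.9208, 88.6381, -0.8985, -0.7239, 1.5381),
    (6.7747, -0.2908, -2.4247, 5.8714, -0.0985, -2.2286, 0.6377),
    (2.0776, 0.0795, -1.1350, 0.9033, -0.0636, -0.5514, 0.9082),
)


# sRGB (IEC 61966-2-1) primaries under D65; used only for colour swatches in
# reports, with XYZ on the 0-100 scale.
_XYZ_TO_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def xyz_to_srgb(c: ColorValue) -> tuple:
    """Gamma-encoded sRGB in [0, 1], gamut-clipped; for visual swatches only."""
    if c.space != "XYZ":
        raise ValueError("xyz_to_srgb needs an XYZ input")
    rgb = _XYZ_TO_SRGB @ (np.asarray(c.components) / 100.0)
    rgb = np.clip(rgb, 0.0, None)
    enc = np.where(rgb <= 0.0031308, 12.92 * rgb, 1.055 * rgb ** (1 / 2.4) - 0.055)
    return tuple(np.clip(enc, 0.0, 1.0))
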