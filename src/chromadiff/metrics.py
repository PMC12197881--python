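"""Pixel-wise color-difference metrics.

Six formulas, each mapping a reference image and a sample image (or per-pixel
color triples) to a non-negative difference per pixel:

``euclidean``
    Euclidean distance straight in 8-bit RGB space.
``cie76lab`` / ``cie76luv``
    CIE 1976 Euclidean distances in L*a*b* and L*u*v*.
``cie94``
    CIE94 with chroma/hue weighting functions S_C = 1 + k1*C1 and
    S_H = 1 + k2*C2 evaluated on the reference and sample chroma
    respectively (an optional switch symmetrizes both with the geometric
    mean sqrt(C1*C2)).
``cie00``
    CIEDE2000, including the chroma rescaling a' = a(1+G), the hue-dependent
    weighting T, the lightness weighting S_L centered at L* = 50, and the
    blue-region rotation term R_T.
``cmc``
    CMC l:c with the ellipsoidal tolerance semi-axes S_L, S_C, S_H evaluated
    on the reference color (first argument).

Argument order is semantic everywhere: the first image is the reference, the
second the sample. Euclidean, CIE76 and CIEDE2000 are symmetric under swap;
CIE94 and CMC are not, because their weights are anchored on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import colorspaces as cs
from .errors import DimensionMismatchError, ParameterError

__all__ = [
    "MetricParams",
    "GRAPHIC_ARTS",
    "TEXTILES",
    "METRIC_NAMES",
    "delta_e_rgb",
    "cie76_lab",
    "cie76_luv",
    "cie94",
    "cie00",
    "cmc",
    "compute_metric",
]

_POW7_25 = 25.0**7


@dataclass(frozen=True)
class MetricParams:
    """Weighting constants shared by the parametric metrics.

    k_L, k_C, k_H divide the lightness/chroma/hue terms in CIE94 and
    CIEDE2000; k_1, k_2 build the CIE94 chroma/hue tolerances; l and c set
    the CMC lightness:chroma ratio (2:1 acceptability, 1:1 perceptibility).
    `cie94_symmetric` replaces CIE94's per-argument chromas in S_C/S_H by
    sqrt(C1*C2), making the formula symmetric under argument swap.
    """

    k_L: float = 1.0
    k_C: float = 1.0
    k_H: float = 1.0
    k_1: float = 0.045
    k_2: float = 0.015
    l: float = 2.0
    c: float = 1.0
    cie94_symmetric: bool = False

    def __post_init__(self) -> None:
        for name in ("k_L", "k_C", "k_H", "l", "c"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.k_1 < 0 or self.k_2 < 0:
            raise ParameterError("k_1 and k_2 must be non-negative")


#: CIE94 application presets: inks/paints/plastics and textiles.
GRAPHIC_ARTS = MetricParams(k_L=1.0, k_1=0.045, k_2=0.015)
TEXTILES = MetricParams(k_L=2.0, k_1=0.048, k_2=0.014)

METRIC_NAMES = ("euclidean", "cie76lab", "cie76luv", "cie94", "cie00", "cmc")


def _check_shapes(ref: np.ndarray, sam: np.ndarray) -> None:
    if ref.shape != sam.shape:
        raise DimensionMismatchError(
            f"image dimensions differ: {ref.shape} vs {sam.shape}; "
            "pre-align the pair with an external registration tool"
        )


def delta_e_rgb(ref: np.ndarray, sam: np.ndarray) -> np.ndarray:
    """Euclidean distance per pixel on the 0-255 RGB integer scale."""
    r = cs.validate_rgb8(ref)
    s = cs.validate_rgb8(sam)
    _check_shapes(r, s)
    return np.sqrt(np.sum((s - r) ** 2, axis=-1))


def _euclidean_triplet(ref: np.ndarray, sam: np.ndarray) -> np.ndarray:
    r = np.asarray(ref, dtype=np.float64)
    s = np.asarray(sam, dtype=np.float64)
    _check_shapes(r, s)
    return np.sqrt(np.sum((s - r) ** 2, axis=-1))


def cie76_lab(ref_lab: np.ndarray, sam_lab: np.ndarray) -> np.ndarray:
    """CIE76: Euclidean distance in L*a*b*."""
    return _euclidean_triplet(ref_lab, sam_lab)


def cie76_luv(ref_luv: np.ndarray, sam_luv: np.ndarray) -> np.ndarray:
    """CIE76 companion metric: Euclidean distance in L*u*v*."""
    return _euclidean_triplet(ref_luv, sam_luv)


def cie94(
    ref_lab: np.ndarray, sam_lab: np.ndarray, p: MetricParams = GRAPHIC_ARTS
) -> np.ndarray:
    """CIE94 with chroma/hue weightings S_C, S_H (S_L = 1).

    The chroma difference is dC = C1 - C2 and the hue-difference term is
    recovered from dH^2 = da^2 + db^2 - dC^2, clamped at zero before the
    square root (it can dip below zero only by rounding).
    """
    r = np.asarray(ref_lab, dtype=np.float64)
    s = np.asarray(sam_lab, dtype=np.float64)
    _check_shapes(r, s)
    dL = r[..., 0] - s[..., 0]
    da = r[..., 1] - s[..., 1]
    db = r[..., 2] - s[..., 2]
    C1 = np.hypot(r[..., 1], r[..., 2])
    C2 = np.hypot(s[..., 1], s[..., 2])
    dC = C1 - C2
    dH2 = np.maximum(da**2 + db**2 - dC**2, 0.0)
    if p.cie94_symmetric:
        Cg = np.sqrt(C1 * C2)
        S_C = 1.0 + p.k_1 * Cg
        S_H = 1.0 + p.k_2 * Cg
    else:
        S_C = 1.0 + p.k_1 * C1
        S_H = 1.0 + p.k_2 * C2
    return np.sqrt(
        (dL / p.k_L) ** 2 + (dC / (p.k_C * S_C)) ** 2 + dH2 / (p.k_H * S_H) ** 2
    )


def cie00(
    ref_lab: np.ndarray, sam_lab: np.ndarray, p: MetricParams = MetricParams()
) -> np.ndarray:
    """CIEDE2000 color difference.

    Uses the standard term set: chroma rescaling via G with the 25^7
    constant, primed hue angles from atan2(b, a') folded to [0, 360), the
    half-angle hue difference dH' = 2*sqrt(C1'C2')*sin(dh'/2), mean-hue
    weighting T, the Gaussian rotation angle centered at 275 degrees, and
    R_T = -sin(2*dTheta)*R_C coupling the chroma and hue terms.
    """
    r = np.asarray(ref_lab, dtype=np.float64)
    s = np.asarray(sam_lab, dtype=np.float64)
    _check_shapes(r, s)
    L1, a1, b1 = r[..., 0], r[..., 1], r[..., 2]
    L2, a2, b2 = s[..., 0], s[..., 1], s[..., 2]

    Cbar = 0.5 * (np.hypot(a1, b1) + np.hypot(a2, b2))
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + _POW7_25)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.where(C1p == 0.0, 0.0, np.degrees(np.arctan2(b1, a1p)) % 360.0)
    h2p = np.where(C2p == 0.0, 0.0, np.degrees(np.arctan2(b2, a2p)) % 360.0)

    dLp = L2 - L1
    dCp = C2p - C1p

    hdiff = h2p - h1p
    dhp = np.where(
        np.abs(hdiff) <= 180.0,
        hdiff,
        np.where(hdiff > 180.0, hdiff - 360.0, hdiff + 360.0),
    )
    # When either color is achromatic the hue difference is undefined: dH'=0.
    dhp = np.where(C1p * C2p == 0.0, 0.0, dhp)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    hbr = np.radians(hbp)
    T = (
        1.0
        - 0.17 * np.cos(hbr - np.radians(30.0))
        + 0.24 * np.cos(2.0 * hbr)
        + 0.32 * np.cos(3.0 * hbr + np.radians(6.0))
        - 0.20 * np.cos(4.0 * hbr - np.radians(63.0))
    )
    dTheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    R_C = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + _POW7_25))
    R_T = -np.sin(np.radians(2.0 * dTheta)) * R_C

    S_L = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    S_C = 1.0 + 0.045 * Cbp
    S_H = 1.0 + 0.015 * Cbp * T

    tL = dLp / (p.k_L * S_L)
    tC = dCp / (p.k_C * S_C)
    tH = dHp / (p.k_H * S_H)
    return np.sqrt(np.maximum(tL**2 + tC**2 + tH**2 + R_T * tC * tH, 0.0))


def cmc(
    ref_lch: np.ndarray, sam_lch: np.ndarray, p: MetricParams = MetricParams()
) -> np.ndarray:
    """CMC l:c difference on LCh triples; all weights anchor on the reference.

    S_L takes the 0.511 branch below L1 = 16; the hue factor T switches
    branch on h1 in [164, 345] (boundaries inclusive); F = sqrt(C1^4 /
    (C1^4 + 1900)) blends T into S_H. At C1 = 0 this gives F = 0 and
    S_H = S_C. The hue-difference term is recovered from the chord:
    dH^2 = 2*C1*C2*(1 - cos(dh)), clamped at zero.
    """
    r = np.asarray(ref_lch, dtype=np.float64)
    s = np.asarray(sam_lch, dtype=np.float64)
    _check_shapes(r, s)
    L1, C1, h1 = r[..., 0], r[..., 1], r[..., 2]
    L2, C2, h2 = s[..., 0], s[..., 1], s[..., 2]

    dL = L2 - L1
    dC = C2 - C1
    dH2 = np.maximum(2.0 * C1 * C2 * (1.0 - np.cos(np.radians(h2 - h1))), 0.0)

    T = np.where(
        (h1 >= 164.0) & (h1 <= 345.0),
        0.56 + np.abs(0.2 * np.cos(np.radians(h1 + 168.0))),
        0.36 + np.abs(0.4 * np.cos(np.radians(h1 + 35.0))),
    )
    C1_4 = C1**4
    F = np.sqrt(C1_4 / (C1_4 + 1900.0))
    S_L = np.where(L1 < 16.0, 0.511, 0.040975 * L1 / (1.0 + 0.01765 * L1))
    S_C = 0.0638 * C1 / (1.0 + 0.0131 * C1) + 0.638
    S_H = S_C * (F * T + 1.0 - F)

    return np.sqrt((dL / (p.l * S_L)) ** 2 + (dC / (p.c * S_C)) ** 2 + dH2 / S_H**2)


_RGB_METRICS = {"euclidean"}


def compute_metric(
    name: str,
    ref: np.ndarray,
    sam: np.ndarray,
    p: MetricParams = MetricParams(),
    wp: cs.WhitePoint = cs.D65,
) -> np.ndarray:
    """Convert a pair of 8-bit RGB images and evaluate the named metric.

    The first argument is always the reference image (the anchor of the
    CIE94/CMC weighting terms). Returns the H x W error matrix as float64.
    """
    if name not in METRIC_NAMES:
        raise ParameterError(
            f"unknown metric {name!r}; valid names: {', '.join(METRIC_NAMES)}"
        )
    if name == "euclidean":
        return delta_e_rgb(ref, sam)
    if name == "cie76luv":
        return cie76_luv(cs.srgb_to_luv(ref, wp), cs.srgb_to_luv(sam, wp))
    ref_lab = cs.srgb_to_lab(ref, wp)
    sam_lab = cs.srgb_to_lab(sam, wp)
    if name == "cie76lab":
        return cie76_lab(ref_lab, sam_lab)
    if name == "cie94":
        return cie94(ref_lab, sam_lab, p)
    if name == "cie00":
        return cie00(ref_lab, sam_lab, p)
    return cmc(cs.lab_to_lch(ref_lab), cs.lab_to_lch(sam_lab), p)
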