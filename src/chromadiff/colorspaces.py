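"""sRGB to perceptual color space conversions (CIE XYZ, L*a*b*, L*u*v*, LCh).

All conversions are pixel-wise and vectorized: inputs are ``(..., 3)`` arrays
and outputs have the same leading shape. 8-bit sRGB values are decoded with
the IEC 61966-2-1 piecewise companding (linear segment below 0.04045), then
mapped to CIE XYZ with the sRGB primaries. Lab and Luv use the CIE 1976
definitions against a configurable reference white, defaulting to D65 with
the 2-degree standard observer, which is the white sRGB is referenced to.

Lightness L* is on the 0-100 scale. All arithmetic is double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError

__all__ = [
    "WhitePoint",
    "D65",
    "validate_rgb8",
    "srgb_to_xyz",
    "xyz_to_lab",
    "xyz_to_luv",
    "lab_to_lch",
    "srgb_to_lab",
    "srgb_to_luv",
    "srgb_to_lch",
]


@dataclass(frozen=True)
class WhitePoint:
    """Reference-white tristimulus values, with Yn normalized to 1.0."""

    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if not (self.Xn > 0 and self.Yn > 0 and self.Zn > 0):
            raise ParameterError("white point tristimulus values must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn], dtype=np.float64)


#: D65, 2-degree standard observer.
D65 = WhitePoint(0.95047, 1.00000, 1.08883)

# sRGB (linear) -> XYZ for the D65-referenced sRGB primaries.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ],
    dtype=np.float64,
)

# CIE 1976 threshold (6/29)^3 and the linear-segment slope terms.
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3


def validate_rgb8(img: np.ndarray) -> np.ndarray:
    """Check an 8-bit RGB image and return it as a float64 array in [0, 255].

    Raises
    ------
    FormatError
        If the array is not (..., 3) with integer values in [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim < 2 or arr.shape[-1] != 3:
        raise FormatError(
            f"expected an RGB array with 3 channels last, got shape {arr.shape}"
        )
    if arr.dtype.kind not in "ui":
        # Accept floats only if they hold exact 8-bit integer values.
        if arr.dtype.kind != "f" or not np.array_equal(arr, np.round(arr)):
            raise FormatError(f"expected 8-bit integer pixel values, got dtype {arr.dtype}")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise FormatError("pixel values outside the 8-bit range [0, 255]")
    return arr.astype(np.float64)


def srgb_to_xyz(img: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """Decode 8-bit sRGB and convert to CIE XYZ tristimulus values.

    The linear transform is normalized so that (255, 255, 255) maps exactly
    to the configured white point.
    """
    rgb = validate_rgb8(img) / 255.0
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    # Column scaling so that white -> wp exactly (the nominal matrix rows sum
    # to D65 within ~1e-7; this absorbs both that residual and non-D65 whites).
    m = _SRGB_TO_XYZ * (wp.as_array() / _SRGB_TO_XYZ.sum(axis=1))[:, None]
    return lin @ m.T


def _f_lab(t: np.ndarray) -> np.ndarray:
    """CIE cube-root function with the linear segment below (6/29)^3."""
    t = np.asarray(t, dtype=np.float64)
    return np.where(t > _DELTA3, np.cbrt(np.maximum(t, 0.0)), t / (3 * _DELTA**2) + 4.0 / 29.0)


def xyz_to_lab(xyz: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """CIE 1976 L*a*b* relative to the white point. L* in [0, 100] for valid sRGB."""
    xyz = np.asarray(xyz, dtype=np.float64)
    fx, fy, fz = (_f_lab(xyz[..., i] / w) for i, w in enumerate(wp.as_array()))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def xyz_to_luv(xyz: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    """CIE 1976 L*u*v* relative to the white point.

    Pixels with X = Y = Z = 0 map to (0, 0, 0): the u', v' chromaticities are
    undefined there and the black-point convention avoids NaN.
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    denom = X + 15.0 * Y + 3.0 * Z
    wn = wp.as_array()
    denom_n = wn[0] + 15.0 * wn[1] + 3.0 * wn[2]
    un, vn = 4.0 * wn[0] / denom_n, 9.0 * wn[1] / denom_n
    safe = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(safe, 4.0 * X / denom, un)
        vp = np.where(safe, 9.0 * Y / denom, vn)
    L = 116.0 * _f_lab(Y / wn[1]) - 16.0
    u = 13.0 * L * (up - un)
    v = 13.0 * L * (vp - vn)
    return np.stack([L, u, v], axis=-1)


def lab_to_lch(lab: np.ndarray) -> np.ndarray:
    """Cylindrical LCh form of Lab: C = sqrt(a^2+b^2), h = atan2(b, a) in degrees.

    Hue is folded to [0, 360); achromatic pixels (C = 0) carry h = 0.
    """
    lab = np.asarray(lab, dtype=np.float64)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    C = np.hypot(a, b)
    h = np.degrees(np.arctan2(b, a)) % 360.0
    h = np.where(C == 0.0, 0.0, h)
    return np.stack([L, C, h], axis=-1)


def srgb_to_lab(img: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    return xyz_to_lab(srgb_to_xyz(img, wp), wp)


def srgb_to_luv(img: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    return xyz_to_luv(srgb_to_xyz(img, wp), wp)


def srgb_to_lch(img: np.ndarray, wp: WhitePoint = D65) -> np.ndarray:
    return lab_to_lch(srgb_to_lab(img, wp))
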