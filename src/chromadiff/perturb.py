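"""Controlled single-channel intensity reductions.

The benchmark corrupts a base image by reducing one RGB channel at a time by
a small fraction (the study grid is 2 %, 5 % and 10 %), emulating minor
lighting or staining shifts. The default reading of "subtracting x %
intensity of each pixel" is multiplicative — each value v becomes
round(v * (1 - f)) — so a zero stays zero and the reduction scales with the
pixel. An ``absolute`` mode computing round(v - f * 255) is provided as the
alternative reading. Rounding is half away from zero; this module is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import validate_rgb8
from .errors import ParameterError

__all__ = ["CHANNELS", "DEFAULT_FRACTIONS", "PerturbationSpec", "reduce_channel", "generate_set"]

CHANNELS = ("R", "G", "B")
DEFAULT_FRACTIONS = (0.02, 0.05, 0.10)

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class PerturbationSpec:
    """One channel reduction: which channel, by what fraction, how."""

    channel: str
    fraction: float
    mode: str = "scale"  # "scale": v*(1-f); "absolute": v - f*255

    def __post_init__(self) -> None:
        if self.channel not in _CHANNEL_INDEX:
            raise ParameterError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not (0.0 < self.fraction < 1.0):
            raise ParameterError(f"fraction must be in (0, 1), got {self.fraction}")
        if self.mode not in ("scale", "absolute"):
            raise ParameterError(f"mode must be 'scale' or 'absolute', got {self.mode!r}")

    @property
    def label(self) -> str:
        """Systematic suffix, e.g. ``R05`` for a 5 % red reduction."""
        return f"{self.channel}{round(self.fraction * 100):02d}"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def reduce_channel(img: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Return a copy of `img` with one channel reduced; others untouched."""
    arr = validate_rgb8(img)
    idx = _CHANNEL_INDEX[spec.channel]
    out = np.asarray(img).copy()
    v = arr[..., idx]
    if spec.mode == "scale":
        reduced = _round_half_away(v * (1.0 - spec.fraction))
    else:
        reduced = _round_half_away(v - spec.fraction * 255.0)
    out[..., idx] = np.clip(reduced, 0, 255).astype(out.dtype)
    return out


def generate_set(
    img: np.ndarray,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    channels: tuple[str, ...] = CHANNELS,
    mode: str = "scale",
) -> list[tuple[PerturbationSpec, np.ndarray]]:
    """All channel x fraction perturbations of a base image.

    Ordering is channel-major, fraction-minor: R02, R05, R10, G02, ... The
    default grid yields 9 altered images per base.
    """
    return [
        (spec, reduce_channel(img, spec))
        for ch in channels
        for f in fractions
        for spec in (PerturbationSpec(ch, f, mode),)
    ]
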