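"""Synthetic brightfield-like test images.

The benchmark in this package needs base images resembling stained
brightfield microscopy slides: a bright near-white background with textured,
colored tissue occupying part of the field, each image dominated by one RGB
channel. This module generates such images deterministically from a seed so
the full benchmark runs without any external data.

An image is built by compositing soft-edged elliptical "tissue" blobs onto a
neutral near-white background and applying mild multiplicative shading
noise. Blob colors put the dominant channel in 160-186 and the other two in
128-154 (a muted stain-like tint; the ranges are disjoint, so the
dominant-channel mean strictly exceeds the other channel means whenever any
blob is present). The three images of a trio share the palette construction
and differ in layout (each has its own derived seed) and in which channel
dominates: they emulate three comparably stained, comparably exposed slides,
so their per-channel intensity means are matched to within ~15 gray levels
while their hues differ. Keeping that spread small is what makes the trio a
usable linearity testbed: the benchmark pools the trio per channel, and a
pooled mean-error-vs-fraction regression is only as linear as the trio's
per-channel means are homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .perturb import CHANNELS

__all__ = ["SyntheticImageSpec", "make_base_image", "make_dataset_trio"]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}

#: Neutral near-white background level (all channels).
_BACKGROUND = 234.0


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic base image."""

    dominant_channel: str = "R"
    height: int = 256
    width: int = 256
    n_blobs: int = 40
    background: tuple[float, float, float] = (_BACKGROUND, _BACKGROUND, _BACKGROUND)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dominant_channel not in _CHANNEL_INDEX:
            raise ParameterError(f"dominant_channel must be one of {CHANNELS}")
        if self.height < 8 or self.width < 8:
            raise ParameterError("image size must be at least 8 x 8")
        if self.n_blobs < 1:
            raise ParameterError("n_blobs must be >= 1")
        if any(not (200.0 <= v <= 255.0) for v in self.background):
            raise ParameterError("background must be near-white (all channels in [200, 255])")


def make_base_image(spec: SyntheticImageSpec) -> np.ndarray:
    """Render one synthetic slide as an H x W x 3 uint8 array.

    Deterministic given the spec (seeded generator, no global state); the
    mean of the dominant channel exceeds the mean of each other channel.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background, dtype=np.float64)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dom = _CHANNEL_INDEX[spec.dominant_channel]
    scale = min(h, w)

    for _ in range(spec.n_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ay = rng.uniform(0.04, 0.13) * scale
        ax = rng.uniform(0.04, 0.13) * scale
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        q = (u / ax) ** 2 + (v / ay) ** 2
        alpha = np.exp(-(q**2))  # flat core, soft rim

        color = np.empty(3)
        others = [i for i in range(3) if i != dom]
        color[dom] = rng.uniform(160.0, 186.0)
        color[others[0]] = rng.uniform(128.0, 154.0)
        color[others[1]] = rng.uniform(128.0, 154.0)
        img = img * (1.0 - alpha[..., None]) + alpha[..., None] * color

    # Mild multiplicative shading, shared across channels to preserve hue.
    img *= rng.normal(1.0, 0.02, size=(h, w, 1))
    out = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    means = out.reshape(-1, 3).mean(axis=0)
    if not all(means[dom] > means[i] for i in range(3) if i != dom):
        raise RuntimeError(
            "dominance invariant violated; increase n_blobs or image size"
        )
    return out


def make_dataset_trio(
    size: int = 256, seed: int = 0, n_blobs: int = 40
) -> list[np.ndarray]:
    """One image per dominant channel (R, G, B), with derived seeds.

    Per-image seeds are ``seed + channel_index`` — plain integer arithmetic,
    reproducible across platforms.
    """
    return [
        make_base_image(
            SyntheticImageSpec(
                dominant_channel=ch,
                height=size,
                width=size,
                n_blobs=n_blobs,
                seed=seed + i,
            )
        )
        for i, ch in enumerate(CHANNELS)
    ]
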