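"""Image pair ingestion, difference-map computation, and output writing.

Inputs are 8-bit RGB JPEG/PNG/TIFF files with identical dimensions. Outputs
are a plain-text float error matrix (``<prefix>.txt``: one image row per
line, tab-separated, fixed-point with 6 decimals, LF line endings) and an
8-bit single-channel uncompressed TIFF (``<prefix>.tiff``) holding the
rounded-and-clamped matrix. The 8-bit image is NOT rescaled by default —
values are metric units rounded half-up and clamped to [0, 255], which keeps
grayscale outputs comparable across image pairs; an optional normalization
rescales min->0 / max->255 for display only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from PIL import Image

from .colorspaces import WhitePoint, D65
from .errors import DimensionMismatchError, FormatError, OutputError
from .metrics import MetricParams, compute_metric

__all__ = [
    "SUPPORTED_EXTENSIONS",
    "read_image",
    "quantize",
    "normalize_for_display",
    "diff",
    "write_outputs",
    "read_error_matrix",
]

logger = logging.getLogger(__name__)

SUPPORTED_EXTENSIONS = {".jpg", ".jpeg", ".png", ".tif", ".tiff"}

ImageLike = Union[str, Path, np.ndarray]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image as an H x W x 3 uint8 array.

    Alpha channels are stripped with a logged warning; grayscale and
    non-8-bit inputs are rejected.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise FormatError(
            f"unsupported extension {path.suffix!r}; expected one of "
            f"{sorted(SUPPORTED_EXTENSIONS)}"
        )
    if not path.is_file():
        raise FormatError(f"cannot read image file: {path}")
    try:
        im = Image.open(path)
        im.load()
    except OSError as exc:
        raise FormatError(f"unreadable image file {path}: {exc}") from exc

    mode = im.mode
    if mode == "P":
        im = im.convert("RGBA" if "transparency" in im.info else "RGB")
        mode = im.mode
    if mode == "RGBA":
        logger.warning("stripping alpha channel from %s", path)
        im = im.convert("RGB")
        mode = "RGB"
    if mode in ("I", "I;16", "I;16B", "I;16L", "F", "RGB;16"):
        raise FormatError(f"{path}: not an 8-bit image (mode {im.mode})")
    if mode in ("L", "LA", "1"):
        raise FormatError(f"{path}: grayscale input; an RGB image is required")
    if mode != "RGB":
        raise FormatError(f"{path}: unsupported color mode {mode!r}")
    arr = np.asarray(im, dtype=np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected H x W x 3 pixels, got {arr.shape}")
    return arr


def quantize(error: np.ndarray) -> np.ndarray:
    """Round half-up, clamp to [0, 255], return uint8 (idempotent)."""
    values = np.asarray(error, dtype=np.float64)
    return np.clip(np.floor(values + 0.5), 0, 255).astype(np.uint8)


def normalize_for_display(error: np.ndarray) -> np.ndarray:
    """Rescale min->0, max->255 for visualization (constant maps go to 0)."""
    values = np.asarray(error, dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint8)
    return quantize((values - lo) / (hi - lo) * 255.0)


def _as_image(img: ImageLike) -> np.ndarray:
    if isinstance(img, (str, Path)):
        return read_image(img)
    return np.asarray(img)


def diff(
    ref: ImageLike,
    sam: ImageLike,
    metric: str = "cie00",
    params: MetricParams = MetricParams(),
    wp: WhitePoint = D65,
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the pixel-wise difference map for an image pair.

    Returns ``(error, quantized)``: the float64 H x W error matrix in metric
    units, and its 8-bit rounded/clamped grayscale rendering.
    """
    ref_img = _as_image(ref)
    sam_img = _as_image(sam)
    if ref_img.shape != sam_img.shape:
        raise DimensionMismatchError(
            f"image dimensions differ ({ref_img.shape[:2]} vs {sam_img.shape[:2]}); "
            "pre-align the pair with an external registration tool"
        )
    error = compute_metric(metric, ref_img, sam_img, params, wp)
    return error, quantize(error)


def write_outputs(
    error: np.ndarray, quantized: np.ndarray, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.txt`` (float matrix) and ``<prefix>.tiff`` (8-bit).

    The text dialect is fixed — tab separators, 6-decimal fixed point, LF
    endings — so outputs are bit-reproducible across runs.
    """
    out_prefix = Path(out_prefix)
    txt_path = out_prefix.with_name(out_prefix.name + ".txt")
    tiff_path = out_prefix.with_name(out_prefix.name + ".tiff")
    try:
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(txt_path, "w", newline="\n") as fh:
            for row in np.atleast_2d(np.asarray(error, dtype=np.float64)):
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")
        tifffile.imwrite(
            tiff_path,
            np.asarray(quantized, dtype=np.uint8),
            photometric="minisblack",
            compression=None,
        )
    except OSError as exc:
        raise OutputError(f"failed to write outputs at {out_prefix}: {exc}") from exc
    return txt_path, tiff_path


def read_error_matrix(txt_path: str | Path) -> np.ndarray:
    """Re-read a ``.txt`` error matrix written by :func:`write_outputs`."""
    return np.loadtxt(txt_path, delimiter="\t", ndmin=2)
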