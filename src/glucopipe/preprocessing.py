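"""Three-stage image preprocessing: grayscale, percentile stretch, resize.

Raw RGB captures are reduced to fixed-size grayscale classifier inputs:

1. luma grayscale conversion (ITU-R BT.601 weights 0.299/0.587/0.114),
2. contrast stretch saturating the bottom 1 % and top 1 % of pixel values,
3. bilinear resize to 100 x 100 (half-pixel-center alignment).

Every stage is deterministic and preserves the 8-bit [0, 255] contract;
intermediate results are rounded half-away-from-zero back to integers.
The contrast stretch is computed per image, mirroring a single-image
point-of-care workflow: each photo is normalized against its own histogram,
which cancels overall illumination differences between captures.
"""

from __future__ import annotations

import logging

import numpy as np

from glucopipe.synthetic_imaging import RawImage

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Classifier input side length.
INPUT_SIZE = (100, 100)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_grayscale(img: RawImage | np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit luma grayscale.

    Per pixel: ``round(0.299 R + 0.587 G + 0.114 B)``.
    """
    pixels = img.pixels if isinstance(img, RawImage) else np.asarray(img)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {pixels.shape}")
    luma = pixels.astype(float) @ LUMA_WEIGHTS
    return np.clip(_round_half_away(luma), 0, 255).astype(np.uint8)


def stretch_contrast(
    img: np.ndarray, low_tail: float = 0.01, high_tail: float = 0.01
) -> np.ndarray:
    """Saturate intensity tails and stretch the remainder onto [0, 255].

    Let ``q_lo`` and ``q_hi`` be the ``low_tail`` and ``1 - high_tail``
    linear-interpolation quantiles of the pixel multiset.  Pixels at or
    below ``q_lo`` map to 0, at or above ``q_hi`` to 255, and the interval
    between them is mapped linearly.  A degenerate image (``q_lo == q_hi``,
    e.g. a constant frame) is returned unchanged with a warning.
    """
    if low_tail < 0 or high_tail < 0 or low_tail + high_tail >= 1:
        raise ValueError("tails must be >= 0 and sum to < 1")
    gray = np.asarray(img, dtype=float)
    q_lo, q_hi = np.quantile(gray, [low_tail, 1.0 - high_tail])
    if q_hi <= q_lo:
        logger.warning(
            "degenerate contrast stretch (q_lo == q_hi == %.1f); image passed through",
            q_lo,
        )
        return np.asarray(img).astype(np.uint8)
    scaled = (np.clip(gray, q_lo, q_hi) - q_lo) * (255.0 / (q_hi - q_lo))
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


def resize_to_input(
    img: np.ndarray, target: tuple[int, int] = INPUT_SIZE, *, method: str = "bilinear"
) -> np.ndarray:
    """Resample a grayscale image to the classifier input size.

    Bilinear interpolation with half-pixel-center alignment: output pixel
    ``i`` samples source coordinate ``(i + 0.5) * scale - 0.5``, clamped to
    the source grid.  ``method='nearest'`` is available for ablation.  A
    target equal to the source size returns the image unchanged.
    """
    gray = np.asarray(img)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {gray.shape}")
    h, w = gray.shape
    th, tw = target
    if h < 2 or w < 2:
        raise ValueError("source image must be at least 2x2")
    if (h, w) == (th, tw):
        return gray.astype(np.uint8)

    src_y = np.clip((np.arange(th) + 0.5) * (h / th) - 0.5, 0, h - 1)
    src_x = np.clip((np.arange(tw) + 0.5) * (w / tw) - 0.5, 0, w - 1)
    if method == "nearest":
        out = gray[np.rint(src_y).astype(int)][:, np.rint(src_x).astype(int)].astype(float)
    elif method == "bilinear":
        y0 = np.floor(src_y).astype(int)
        x0 = np.floor(src_x).astype(int)
        y1 = np.minimum(y0 + 1, h - 1)
        x1 = np.minimum(x0 + 1, w - 1)
        fy = (src_y - y0)[:, None]
        fx = (src_x - x0)[None, :]
        g = gray.astype(float)
        top = g[y0][:, x0] * (1 - fx) + g[y0][:, x1] * fx
        bot = g[y1][:, x0] * (1 - fx) + g[y1][:, x1] * fx
        out = top * (1 - fy) + bot * fy
    else:
        raise ValueError(f"unknown resize method {method!r}")
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)


def preprocess(
    img: RawImage | np.ndarray,
    *,
    low_tail: float = 0.01,
    high_tail: float = 0.01,
    target: tuple[int, int] = INPUT_SIZE,
    method: str = "bilinear",
) -> np.ndarray:
    """Full chain: grayscale -> contrast stretch -> resize, in that order."""
    gray = to_grayscale(img)
    stretched = stretch_contrast(gray, low_tail=low_tail, high_tail=high_tail)
    return resize_to_input(stretched, target=target, method=method)
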