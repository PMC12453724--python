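"""Grayscale image and mask I/O, resizing, and intensity histograms.

All images are 2-D ``numpy.uint8`` arrays in row-major, 0-based ``(row, col)``
convention with intensities in [0, 255].  Color inputs are collapsed to
grayscale with the ITU-R BT.601 luma weights.  These helpers are the plumbing
layer consumed by the enhancement, segmentation and evaluation modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "Histogram",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "to_grayscale",
    "resize",
    "histogram",
]

#: BT.601 luma weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])


def _validate_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale array, got shape {img.shape}")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("grayscale image must be integer-valued in [0, 255]")
    return img


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram of an 8-bit image over the 256 levels.

    ``counts[k]`` is the number of pixels at level ``k``; ``probabilities``
    is the relative frequency P_x, and ``quality`` the per-level quality
    measure Q_k = m_k / sum(m_k) — numerically identical to P_x, kept as a
    named view because it plays a distinct role (pixel weighting) downstream.
    """

    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("histogram needs exactly 256 bins")
        if counts.min() < 0 or counts.sum() == 0:
            raise ValueError("histogram counts must be non-negative and not all zero")
        object.__setattr__(self, "counts", counts)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Relative frequency P_x per level; sums to 1."""
        return self.counts / self.counts.sum()

    @property
    def quality(self) -> np.ndarray:
        """Quality measure Q_k (relative frequency), element-wise equal to P_x."""
        return self.probabilities

    @classmethod
    def uniform(cls) -> "Histogram":
        """The maximally mixed histogram: one count per level (P_x = 1/256)."""
        return cls(np.ones(256, dtype=np.int64))


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) or (H, W, 4) array to BT.601 grayscale uint8."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return _validate_gray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        gray = pixels[..., :3].astype(float) @ _LUMA
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot interpret array of shape {pixels.shape} as an image")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as a grayscale uint8 array.

    RGB(A) inputs are converted with the BT.601 luma weights and rounded to
    the nearest integer; grayscale inputs pass through bit-exactly.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise FileNotFoundError(f"image file not found: {path}") from None
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a readable image file: {path}") from exc
    return to_grayscale(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a grayscale uint8 array as a single-channel PNG (or JPEG by suffix)."""
    img = _validate_gray(img)
    Image.fromarray(img, mode="L").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask stored as a single-channel PNG (label values as intensities)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise FileNotFoundError(f"mask file not found: {path}") from None
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a readable mask file: {path}") from exc
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel, got shape {arr.shape}")
    return arr.astype(np.int64)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask labels must be 2-D integers in [0, 255] for PNG storage")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(Path(path))


def resize(img: np.ndarray, side: int = 380) -> np.ndarray:
    """Resize to ``side`` x ``side`` pixels with bilinear interpolation.

    380 is the working resolution of the analysis pipeline.  Values are
    rounded back to uint8; a same-size resize is the identity.
    """
    img = _validate_gray(img)
    if side < 2:
        raise ValueError(f"target side must be at least 2, got {side}")
    if img.shape == (side, side):
        return img.copy()
    out = Image.fromarray(img, mode="L").resize((side, side), Image.BILINEAR)
    return np.asarray(out, dtype=np.uint8)


def histogram(img: np.ndarray) -> Histogram:
    """Exact per-level counts m_k of an 8-bit image (sum equals the pixel count)."""
    img = _validate_gray(img)
    return Histogram(np.bincount(img.ravel(), minlength=256))
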