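"""Slice texture descriptors: local binary patterns and Shannon entropy.

A slice is summarised by two quantities computed over a (possibly masked)
region:

* a 256-bin, L1-normalised histogram of 8-neighbour local binary pattern
  (LBP) codes — the texture signature used to rank candidate slices, and
* the Shannon entropy (bits) of the 8-bit intensity histogram — a scalar
  disorder measure used to break ties between texture-equivalent candidates.

The LBP comparator is ``center >= neighbour -> bit 1``.  Codes are read
clockwise from the top-left neighbour, first neighbour in the most
significant bit.  Pixels without a full 8-neighbourhood (the one-pixel image
border) carry code 0 and never contribute to histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError

__all__ = [
    "NEIGHBOR_OFFSETS",
    "SliceDescriptor",
    "lbp_mask",
    "lbp_histogram",
    "lbp_error",
    "shannon_entropy",
    "entropy_error",
    "describe_slice",
]

#: 8-neighbourhood offsets (row, col), clockwise starting at the top-left.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass(frozen=True)
class SliceDescriptor:
    """Texture descriptor of one (masked) slice.

    Attributes
    ----------
    lbp_histogram:
        256 non-negative reals summing to 1.
    entropy:
        Shannon entropy of the region's intensity histogram, in bits
        (0 for a constant region, 8 for a uniform 256-level one).
    n_pixels:
        Number of interior pixels that contributed to the LBP histogram.
    region:
        Free-text description of the mask used (e.g. ``"lung"``, ``"full"``).
    """

    lbp_histogram: np.ndarray
    entropy: float
    n_pixels: int
    region: str = "full"

    def __post_init__(self) -> None:
        hist = np.asarray(self.lbp_histogram, dtype=float)
        if hist.shape != (256,):
            raise ValueError(f"LBP histogram must have 256 bins, got {hist.shape}")
        object.__setattr__(self, "lbp_histogram", hist)


def _as_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    return img


def lbp_mask(image, *, rotation: int = 0) -> np.ndarray:
    """Compute the 8-bit LBP code of every interior pixel.

    Bit ``b`` of the code is 1 iff ``center >= neighbour_b``.  ``rotation``
    rotates the starting neighbour (0 = top-left); any fixed rotation yields
    an equivalent comparison metric, the parameter exists to demonstrate
    that invariance.

    Returns an array of the same shape as ``image`` with dtype uint8; border
    pixels are 0 and must be excluded from histograms (``lbp_histogram``
    does this automatically).
    """
    img = _as_image(image)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3 for LBP, got {img.shape}")
    a = img.astype(np.int32)
    center = a[1:-1, 1:-1]
    offsets = NEIGHBOR_OFFSETS[rotation % 8:] + NEIGHBOR_OFFSETS[: rotation % 8]
    acc = np.zeros(center.shape, dtype=np.uint8)
    for bit, (dr, dc) in zip(range(7, -1, -1), offsets):
        nbr = a[1 + dr : a.shape[0] - 1 + dr, 1 + dc : a.shape[1] - 1 + dc]
        acc |= (center >= nbr).astype(np.uint8) << bit
    codes = np.zeros(img.shape, dtype=np.uint8)
    codes[1:-1, 1:-1] = acc
    return codes


def interior_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels that have a full 8-neighbourhood."""
    interior = np.zeros(shape, dtype=bool)
    interior[1:-1, 1:-1] = True
    return interior


def lbp_histogram(codes, mask=None) -> np.ndarray:
    """Normalised 256-bin histogram of LBP codes over interior (masked) pixels."""
    codes = _as_image(codes)
    sel = interior_mask(codes.shape)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != codes.shape:
            raise ValueError("mask shape does not match code grid")
        sel &= mask
    n = int(sel.sum())
    if n == 0:
        raise DegenerateInputError("no interior pixels under mask")
    counts = np.bincount(codes[sel].ravel(), minlength=256)
    return counts / n


def lbp_error(h1, h2) -> float:
    """Squared-error distance between two normalised LBP histograms.

    ``sum_b (h1[b] - h2[b])**2``; symmetric, zero iff the histograms agree.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != (256,) or h2.shape != (256,):
        raise ValueError("LBP histograms must have exactly 256 bins")
    d = h1 - h2
    return float(d @ d)


def shannon_entropy(image, mask=None) -> float:
    """Shannon entropy (bits) of the 8-bit intensity histogram under ``mask``.

    ``H = -sum_v p(v) log2 p(v)`` with the convention ``0 log 0 = 0``.
    Constant regions have entropy 0; a region using all 256 grey levels
    equally often has entropy 8.
    """
    img = _as_image(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape does not match image")
        vals = img[mask]
    else:
        vals = img.ravel()
    if vals.size == 0:
        raise DegenerateInputError("empty region for entropy")
    counts = np.bincount(vals.astype(np.uint8).ravel(), minlength=256)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def entropy_error(a: float, b: float) -> float:
    """Absolute difference of two entropies; the registration tie-breaker."""
    return abs(float(a) - float(b))


def describe_slice(image, mask=None, region: str = "full") -> SliceDescriptor:
    """Bundle the LBP histogram and entropy of one (masked) slice."""
    img = _as_image(image)
    codes = lbp_mask(img)
    hist = lbp_histogram(codes, mask)
    sel = interior_mask(img.shape)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    return SliceDescriptor(
        lbp_histogram=hist,
        entropy=shannon_entropy(img, mask),
        n_pixels=int(sel.sum()),
        region=region,
    )
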