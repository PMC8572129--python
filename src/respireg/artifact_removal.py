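"""Out-of-body artifact removal.

CT couch rails, cables and other objects outside the patient show up as
bright structures that confuse intensity-based lung segmentation.  The
removal strategy is:

1. quantize the slice into ``n_levels`` intensity classes by *minimum
   variance quantization* — the exact partition of the 256 grey levels into
   contiguous classes that minimises total within-class variance, found by
   dynamic programming on the intensity histogram;
2. take the brightest class (patient body and artifacts are bright, the
   background and the air-filled lungs are dark);
3. keep the connected component that overlaps the centre of the frame (the
   patient is centred in a CT scan; the couch and stray objects are not);
4. fill enclosed holes, so the dark lungs are folded back into the body
   mask.

Everything outside the resulting body mask is zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateInputError, SegmentationError

__all__ = [
    "QuantizationResult",
    "quantize_min_variance",
    "fill_holes",
    "extract_body_mask",
    "remove_artifacts",
]

# Complementary connectivity pairing: 8-connected foreground components,
# 4-connected background (holes). Avoids the topological paradox where a
# diagonal foreground "wall" fails to enclose its background.
_FOREGROUND_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class QuantizationResult:
    """Outcome of minimum variance quantization.

    Attributes
    ----------
    label_map:
        Per-pixel class index ``0 .. n_levels-1``, ordered by ascending
        class mean intensity (classes are contiguous intensity ranges, so
        the ordering is automatic).
    class_boundaries:
        ``n_levels - 1`` inclusive upper cut points: class ``c`` holds the
        intensities ``boundaries[c-1] < v <= boundaries[c]``.
    within_class_variance:
        Total within-class variance (mean over pixels of the squared
        deviation from the pixel's class mean) — the minimised objective.
    """

    label_map: np.ndarray
    class_boundaries: np.ndarray
    within_class_variance: float

    @property
    def n_levels(self) -> int:
        return len(self.class_boundaries) + 1


def _histogram_prefixes(counts: np.ndarray):
    v = np.arange(256, dtype=np.float64)
    w = np.concatenate([[0.0], np.cumsum(counts)])            # pixel count
    s = np.concatenate([[0.0], np.cumsum(counts * v)])        # sum of values
    q = np.concatenate([[0.0], np.cumsum(counts * v * v)])    # sum of squares
    return w, s, q


def _interval_sse(w, s, q):
    """256x256 matrix of within-class sums of squares for bin ranges [a, b].

    Entry (a, b) is the squared deviation of all pixels whose intensity lies
    in bins a..b inclusive from that range's mean; +inf for empty ranges and
    for a > b.
    """
    a = np.arange(256)[:, None]
    b = np.arange(256)[None, :]
    weight = w[b + 1] - w[a]
    total = s[b + 1] - s[a]
    sq = q[b + 1] - q[a]
    mean_sq = np.zeros_like(sq)
    np.divide(total * total, weight, out=mean_sq, where=weight > 0)
    sse = np.maximum(sq - mean_sq, 0.0)  # clamp negative rounding residue
    sse[(weight <= 0) | (a > b)] = np.inf
    return sse


def quantize_min_variance(image, n_levels: int) -> QuantizationResult:
    """Optimal contiguous quantization of an 8-bit image into ``n_levels`` classes.

    Dynamic programming over the 256-bin intensity histogram finds the exact
    minimum of the total within-class variance over all placements of the
    ``n_levels - 1`` cut points.  Ties are resolved toward the smallest cut
    points; the result is deterministic.

    Raises
    ------
    DegenerateInputError
        For a constant image, or when ``n_levels`` exceeds the number of
        distinct intensities.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    counts = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    distinct = int(np.count_nonzero(counts))
    if distinct < 2:
        raise DegenerateInputError("constant image cannot be quantized")
    if n_levels > distinct:
        raise DegenerateInputError(
            f"n_levels={n_levels} exceeds the {distinct} distinct intensities"
        )

    w, s, q = _histogram_prefixes(counts)
    sse = _interval_sse(w, s, q)

    # best[k][b]: minimal SSE of splitting bins 0..b into k+1 classes.
    best = sse[0].copy()
    # split[k][b]: first bin of the last class in the optimum for (k, b).
    splits = np.zeros((n_levels, 256), dtype=np.intp)
    for k in range(1, n_levels):
        # candidate last-class start a (1..255): best[a-1] + sse[a, b]
        cand = best[:-1, None] + sse[1:, :]  # axis 0: a-1 in 0..254
        arg = np.argmin(cand, axis=0)        # first (smallest a) on ties
        best = cand[arg, np.arange(256)]
        splits[k] = arg + 1

    total_sse = float(best[255])
    # Backtrack cut points (inclusive upper boundary of each class).
    cuts = []
    b = 255
    for k in range(n_levels - 1, 0, -1):
        a = int(splits[k][b])
        cuts.append(a - 1)
        b = a - 1
    boundaries = np.array(sorted(cuts), dtype=np.intp)

    lut = np.searchsorted(boundaries, np.arange(256), side="left")
    label_map = lut[img.astype(np.uint8)].astype(np.uint8)
    n = counts.sum()
    return QuantizationResult(
        label_map=label_map,
        class_boundaries=boundaries,
        within_class_variance=total_sse / n,
    )


def fill_holes(mask) -> np.ndarray:
    """Fill background regions not 4-connected to the image border.

    Foreground pixels are never removed; the operation is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    # scipy's default structuring element gives 4-connected background.
    return ndimage.binary_fill_holes(mask)


def extract_body_mask(image, n_levels: int = 3) -> np.ndarray:
    """Segment the patient body: brightest quantization class, centred component.

    The brightest class contains both the body and any out-of-body artifacts;
    the component with the largest overlap with the central ninth of the
    frame is kept (patients are centred; couches and stray objects are not).
    If nothing overlaps the centre the largest component is used instead.
    Holes (the dark lungs) are filled.
    """
    img = np.asarray(image)
    result = quantize_min_variance(img, n_levels)
    top = result.label_map == result.n_levels - 1
    labels, n_comp = ndimage.label(top, structure=_FOREGROUND_STRUCTURE)
    if n_comp == 0:
        raise SegmentationError("no pixels in the brightest quantization class")
    h, width = img.shape
    window = np.zeros_like(top)
    window[h // 3 : 2 * h // 3, width // 3 : 2 * width // 3] = True
    overlap = np.bincount(labels[window].ravel(), minlength=n_comp + 1)[1:]
    if overlap.max() > 0:
        keep = int(np.argmax(overlap)) + 1
    else:
        areas = np.bincount(labels.ravel(), minlength=n_comp + 1)[1:]
        keep = int(np.argmax(areas)) + 1
    body = fill_holes(labels == keep)
    if not body.any():
        raise SegmentationError("body mask came out empty")
    return body


def remove_artifacts(image, n_levels: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Zero out everything outside the body mask.

    Returns ``(masked_image, body_mask)``; pixels inside the body are
    unchanged.
    """
    img = np.asarray(image)
    body = extract_body_mask(img, n_levels=n_levels)
    masked = np.where(body, img, 0).astype(img.dtype)
    return masked, body
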