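"""Left/right lung segmentation of a single CT slice.

After artifact removal the slice holds a bright body on a zeroed background
with dark, air-filled lungs inside.  Segmentation proceeds:

1. Otsu's threshold (minimum within-class variance), computed over body
   pixels only so the zeroed background cannot bias it;
2. complement — dark lung pixels become foreground;
3. elementwise multiplication with the body mask, leaving lung candidates;
4. the body centroid column defines a centre line; on each side the largest
   candidate component is the lung, holes filled.

Slices where Otsu separates two classes whose means differ by less than
``min_class_separation`` grey levels carry no lung information (apex/base
slices, or slices without lungs at all) and come back flagged with an empty
combined mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .artifact_removal import fill_holes, remove_artifacts
from .exceptions import DegenerateInputError

__all__ = [
    "LungSegmentation",
    "EmptySideWarning",
    "otsu_threshold",
    "segment_lung_candidates",
    "split_left_right",
    "segment_slice",
]

_STRUCTURE8 = np.ones((3, 3), dtype=bool)

#: Minimum fraction of the body area a candidate component must cover to be
#: considered a lung (filters noise specks and vessels).
DEFAULT_MIN_AREA_FRAC = 0.005

#: Minimum Otsu class-mean gap (grey levels) for a slice to count as having
#: lung information. Air vs. soft tissue is a ~150-level contrast on 8-bit
#: CT renderings; a gap far below that means the threshold split texture,
#: not anatomy.
DEFAULT_MIN_CLASS_SEPARATION = 50.0


class EmptySideWarning(UserWarning):
    """One side of the centre line has no lung candidate component."""


@dataclass(frozen=True)
class LungSegmentation:
    """Per-slice segmentation output.

    ``left``/``right`` follow image coordinates (left = lower column
    indices), not patient anatomy.  ``flags`` is empty for a clean slice;
    non-empty flags mark slices to skip during registration.
    """

    left_mask: np.ndarray
    right_mask: np.ndarray
    combined_mask: np.ndarray
    body_mask: np.ndarray
    threshold: int
    slice_index: int = 0
    phase_label: str = ""
    flags: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return bool(self.combined_mask.any()) and not self.flags


def otsu_threshold(image, mask=None) -> int:
    """Otsu's threshold: minimise the weighted within-class variance.

    Scans every threshold ``t`` in 0..255 with pixels ``<= t`` as background
    and returns the smallest minimiser of
    ``sigma_w^2(t) = w0 * var0 + w1 * var1``.  An empty class contributes
    zero variance.  When ``mask`` is given only masked pixels enter the
    histogram.
    """
    img = np.asarray(image)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError("mask shape does not match image")
        vals = img[mask]
    else:
        vals = img.ravel()
    counts = np.bincount(vals.astype(np.uint8).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError("need at least two distinct intensities for Otsu")

    v = np.arange(256, dtype=np.float64)
    n = counts.sum()
    w0 = np.cumsum(counts)                    # pixels <= t
    s0 = np.cumsum(counts * v)
    q0 = np.cumsum(counts * v * v)
    w1 = n - w0
    s1 = s0[-1] - s0
    q1 = q0[-1] - q0
    m0 = np.zeros_like(q0)
    m1 = np.zeros_like(q1)
    np.divide(s0 * s0, w0, out=m0, where=w0 > 0)
    np.divide(s1 * s1, w1, out=m1, where=w1 > 0)
    sigma_w = (np.maximum(q0 - m0, 0.0) + np.maximum(q1 - m1, 0.0)) / n
    return int(np.argmin(sigma_w))  # argmin takes the smallest t on ties


def segment_lung_candidates(image, body_mask, *, return_threshold: bool = False):
    """Binary lung-candidate mask: Otsu inside the body, complemented.

    The complement of the Otsu foreground, multiplied by the body mask,
    marks every dark region inside the body — the lungs plus possible
    residue that :func:`split_left_right` removes.
    """
    img = np.asarray(image)
    body = np.asarray(body_mask, dtype=bool)
    if not body.any():
        raise DegenerateInputError("empty body mask")
    t = otsu_threshold(img, body)
    foreground = img > t
    candidates = ~foreground & body
    if return_threshold:
        return candidates, t
    return candidates


def split_left_right(
    candidates,
    body_mask,
    min_area_frac: float = DEFAULT_MIN_AREA_FRAC,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign candidate components to the left/right lung by the body centre line.

    The centre line is the body centroid column.  Components are assigned to
    the side their own centroid falls on (a component straddling the line is
    not split), components smaller than ``min_area_frac`` of the body area
    are discarded, and the largest component per side is kept with holes
    filled.  A side without any component comes back empty with an
    :class:`EmptySideWarning`.
    """
    cand = np.asarray(candidates, dtype=bool)
    body = np.asarray(body_mask, dtype=bool)
    if cand.shape != body.shape:
        raise ValueError("candidate and body masks must share a shape")
    if np.any(cand & ~body):
        raise ValueError("candidates must be a subset of the body mask")
    empty = np.zeros_like(cand)
    if not body.any():
        raise DegenerateInputError("empty body mask")
    center_col = float(np.nonzero(body)[1].mean())
    min_area = min_area_frac * body.sum()

    labels, n_comp = ndimage.label(cand, structure=_STRUCTURE8)
    sides: dict[str, tuple[int, int]] = {}  # side -> (area, label)
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        centroid_col = float(np.nonzero(comp)[1].mean())
        side = "left" if centroid_col < center_col else "right"
        if side not in sides or area > sides[side][0]:
            sides[side] = (area, lab)

    out = {}
    for side in ("left", "right"):
        if side in sides:
            out[side] = fill_holes(labels == sides[side][1])
        else:
            warnings.warn(f"no lung candidate on the {side} side", EmptySideWarning)
            out[side] = empty.copy()
    return out["left"], out["right"]


def segment_slice(
    image,
    *,
    n_levels: int = 3,
    min_area_frac: float = DEFAULT_MIN_AREA_FRAC,
    min_class_separation: float = DEFAULT_MIN_CLASS_SEPARATION,
    slice_index: int = 0,
    phase_label: str = "",
) -> LungSegmentation:
    """Full single-slice pipeline: artifact removal, thresholding, L/R split.

    Deterministic.  Slices without lung information (insufficient air/tissue
    contrast inside the body, or no sufficiently large dark component) are
    returned flagged with an empty combined mask rather than raising, so
    phase-level processing can record them as skipped.
    """
    img = np.asarray(image)
    masked, body = remove_artifacts(img, n_levels=n_levels)
    try:
        t = otsu_threshold(masked, body)
    except DegenerateInputError:
        # constant body region: no contrast, hence no lung information
        t, gap = 0, 0.0
    else:
        vals = masked[body]
        lo, hi = vals[vals <= t], vals[vals > t]
        gap = (float(hi.mean()) - float(lo.mean())) if lo.size and hi.size else 0.0
    empty = np.zeros_like(body)
    if gap < min_class_separation:
        return LungSegmentation(
            left_mask=empty,
            right_mask=empty.copy(),
            combined_mask=empty.copy(),
            body_mask=body,
            threshold=t,
            slice_index=slice_index,
            phase_label=phase_label,
            flags=("no lung information",),
        )

    candidates = segment_lung_candidates(masked, body)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptySideWarning)
        left, right = split_left_right(candidates, body, min_area_frac=min_area_frac)
    combined = left | right
    flags = []
    if not left.any():
        flags.append("no left lung")
    if not right.any():
        flags.append("no right lung")
    if not combined.any():
        flags = ["no lung information"]
    return LungSegmentation(
        left_mask=left,
        right_mask=right,
        combined_mask=combined,
        body_mask=body,
        threshold=t,
        slice_index=slice_index,
        phase_label=phase_label,
        flags=tuple(flags),
    )
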