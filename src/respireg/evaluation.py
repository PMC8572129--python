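"""Evaluation metrics: Dice overlap, coefficient of variation, ground truth.

* ``dice`` — Dice similarity coefficient, ``2|A ∩ B| / (|A| + |B|)`` as a
  percentage; the segmentation quality measure.
* ``cvar`` — coefficient of variation, ``std / mean * 100``; summarises the
  consistency of the per-slice registration errors within one phase.
* ``threshold_ground_truth`` — reference lung masks from a per-slice
  intensity threshold at the lung/body boundary, for datasets without
  expert segmentations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError
from .registration import PhaseRegistration
from .segmentation import EmptySideWarning, split_left_right

__all__ = ["EvaluationReport", "dice", "cvar", "threshold_ground_truth", "evaluate_run"]


def dice(seg, truth) -> float:
    """Dice similarity coefficient of two masks (or mask stacks), in percent."""
    a = np.asarray(seg, dtype=bool)
    b = np.asarray(truth, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise DegenerateInputError("both masks are empty (0/0)")
    inter = int((a & b).sum())
    return 2.0 * inter / (sa + sb) * 100.0


def cvar(values) -> float:
    """Coefficient of variation (sample std / mean) in percent."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise DegenerateInputError("need at least 2 values for CVar")
    mean = vals.mean()
    if mean == 0:
        raise DegenerateInputError("zero mean: CVar undefined")
    return float(np.std(vals, ddof=1) / mean * 100.0)


def threshold_ground_truth(image, threshold: int, body_mask) -> np.ndarray:
    """Reference combined-lung mask from a hand-picked boundary threshold.

    Pixels at or below ``threshold`` inside the body are lung candidates;
    component selection and hole filling follow the same rules as the
    segmentation pipeline.  An empty result is returned as-is (flagged by
    emptiness) for slices without lung content.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    img = np.asarray(image)
    body = np.asarray(body_mask, dtype=bool)
    candidates = (img <= threshold) & body
    if not candidates.any():
        return np.zeros_like(body)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptySideWarning)
        left, right = split_left_right(candidates, body)
    return left | right


@dataclass(frozen=True)
class EvaluationReport:
    """DSC per slice, CVar per phase, and summary statistics."""

    dsc_table: pd.DataFrame       # phase, slice, dsc_left, dsc_right, dsc_combined
    cvar_table: pd.DataFrame      # phase, cvar, n_slices
    summary: dict
    ground_truth: str = "phantom exact"


def _safe_dice(a, b):
    try:
        return dice(a, b)
    except DegenerateInputError:
        return np.nan


def evaluate_run(
    dataset,
    segmentations: Mapping[tuple[int, int], "object"],
    registrations: Mapping[str, PhaseRegistration] | None = None,
) -> EvaluationReport:
    """Aggregate DSC and CVar tables for a phantom run.

    ``segmentations`` maps ``(phase_index, slice_index)`` to the
    :class:`~respireg.segmentation.LungSegmentation` produced for that
    slice; DSC is computed against the phantom's exact masks.  ``registrations``
    maps target phase labels to :class:`PhaseRegistration`; per-phase CVar is
    taken over the per-slice combined error ``lbp_error + entropy_error``.
    A self-registration phase (all-zero errors) is reported as NaN.
    """
    if not segmentations:
        raise ValueError("no segmentations supplied")
    labels = dataset.volume.phase_labels
    dsc_rows = []
    for (p, k), seg in sorted(segmentations.items()):
        if not (0 <= p < dataset.volume.n_phases and 0 <= k < dataset.volume.n_slices):
            raise ValueError(f"segmentation index ({p}, {k}) outside the dataset")
        if not seg.combined_mask.any() and not dataset.lung_masks[p, k].any():
            continue  # nothing to evaluate on a lungless slice
        dsc_rows.append(
            {
                "phase": labels[p],
                "slice": k + 1,
                "dsc_left": _safe_dice(seg.left_mask, dataset.left_masks[p, k]),
                "dsc_right": _safe_dice(seg.right_mask, dataset.right_masks[p, k]),
                "dsc_combined": _safe_dice(seg.combined_mask, dataset.lung_masks[p, k]),
            }
        )
    dsc_table = pd.DataFrame(
        dsc_rows, columns=["phase", "slice", "dsc_left", "dsc_right", "dsc_combined"]
    )

    cvar_rows = []
    if registrations:
        for label, reg in registrations.items():
            errors = [r.lbp_error + r.entropy_error for r in reg.results]
            try:
                value = cvar(errors)
            except DegenerateInputError:
                value = np.nan  # self-registration or degenerate phase
            cvar_rows.append({"phase": label, "cvar": value, "n_slices": len(errors)})
    cvar_table = pd.DataFrame(cvar_rows, columns=["phase", "cvar", "n_slices"])

    summary = {
        "mean_dsc_combined": float(dsc_table["dsc_combined"].mean()) if len(dsc_table) else np.nan,
        "min_dsc_combined": float(dsc_table["dsc_combined"].min()) if len(dsc_table) else np.nan,
        "mean_cvar": float(cvar_table["cvar"].mean()) if len(cvar_table) else np.nan,
        "n_slices_evaluated": int(len(dsc_table)),
    }
    return EvaluationReport(dsc_table=dsc_table, cvar_table=cvar_table, summary=summary)
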