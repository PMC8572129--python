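"""Slice-to-phase registration by windowed LBP search with entropy tie-break.

For a target slice ``i`` of one phase the matching slice in the source
phase is sought among the candidates ``i - margin .. i + margin`` (the
anatomy never moves further than a few slices within one breath).  The
candidate with the minimum LBP histogram squared error wins; when several
candidates are within a relative tolerance of the minimum — texture alone
cannot separate them — the one with the smallest entropy error is chosen.
Residual ties fall back to the candidate nearest the target index, then the
lower index, so results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .descriptors import SliceDescriptor, describe_slice, entropy_error, lbp_error
from .exceptions import RegistrationError
from .segmentation import LungSegmentation, segment_slice
from .volume_io import Volume4D

__all__ = [
    "CandidateScore",
    "RegistrationResult",
    "PhaseRegistration",
    "candidate_window",
    "register_slice",
    "register_phase",
    "phase_descriptors",
]

DEFAULT_MARGIN = 5
DEFAULT_SLICE_RANGE = (30, 70)  # 1-based, inclusive
DEFAULT_TIE_REL_TOL = 0.01
_ZERO_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CandidateScore:
    slice_index: int
    lbp_error: float
    entropy_error: float


@dataclass(frozen=True)
class RegistrationResult:
    """Match of one target slice against a source phase."""

    target_phase: str
    target_slice: int
    matched_slice: int
    lbp_error: float
    entropy_error: float
    candidates: tuple[CandidateScore, ...]
    tie_broken: bool = False


@dataclass(frozen=True)
class PhaseRegistration:
    """All per-slice matches of one target phase, plus the skipped slices."""

    target_phase: str
    source_phase: str
    results: tuple[RegistrationResult, ...]
    skipped: tuple[tuple[int, str], ...]
    slice_range: tuple[int, int]
    margin: int

    def to_frame(self):
        """Registration table (1-based slice numbers) as a DataFrame."""
        import pandas as pd

        rows = [
            {
                "phase": r.target_phase,
                "target_slice": r.target_slice + 1,
                "matched_slice": r.matched_slice + 1,
                "lbp_error": r.lbp_error,
                "entropy_error": r.entropy_error,
                "tie_broken": r.tie_broken,
                "skipped_reason": "",
            }
            for r in self.results
        ] + [
            {
                "phase": self.target_phase,
                "target_slice": k + 1,
                "matched_slice": pd.NA,
                "lbp_error": pd.NA,
                "entropy_error": pd.NA,
                "tie_broken": pd.NA,
                "skipped_reason": reason,
            }
            for k, reason in self.skipped
        ]
        return pd.DataFrame(rows).sort_values("target_slice", ignore_index=True)


def candidate_window(target_slice: int, margin: int, n_slices: int) -> range:
    """Inclusive candidate range ``[target - margin, target + margin]``, clipped."""
    if not 0 <= target_slice < n_slices:
        raise IndexError(f"target_slice {target_slice} out of range [0, {n_slices})")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    return range(max(0, target_slice - margin), min(n_slices - 1, target_slice + margin) + 1)


def register_slice(
    target_descriptor: SliceDescriptor,
    source_descriptors: Sequence[Optional[SliceDescriptor]],
    target_slice: int,
    margin: int = DEFAULT_MARGIN,
    tie_rel_tol: float = DEFAULT_TIE_REL_TOL,
    target_phase: str = "",
) -> RegistrationResult:
    """Match one target slice against the windowed source candidates.

    ``source_descriptors`` is indexed by source slice; ``None`` marks slices
    without lung information, which are excluded from the search.
    """
    n_slices = len(source_descriptors)
    window = candidate_window(target_slice, margin, n_slices)
    scores = []
    for i in window:
        desc = source_descriptors[i]
        if desc is None:
            continue
        scores.append(
            CandidateScore(
                slice_index=i,
                lbp_error=lbp_error(target_descriptor.lbp_histogram, desc.lbp_histogram),
                entropy_error=entropy_error(target_descriptor.entropy, desc.entropy),
            )
        )
    if not scores:
        raise RegistrationError(
            f"no usable source slice in window {window.start}..{window.stop - 1}"
        )

    m = min(s.lbp_error for s in scores)
    bound = m * (1.0 + tie_rel_tol) if m > 0 else _ZERO_TIE_TOL
    ties = [s for s in scores if s.lbp_error <= bound]
    tie_broken = len(ties) > 1
    winner = min(
        ties,
        key=lambda s: (s.entropy_error, abs(s.slice_index - target_slice), s.slice_index),
    )
    return RegistrationResult(
        target_phase=target_phase,
        target_slice=target_slice,
        matched_slice=winner.slice_index,
        lbp_error=winner.lbp_error,
        entropy_error=winner.entropy_error,
        candidates=tuple(scores),
        tie_broken=tie_broken,
    )


def _segment(volume: Volume4D, phase: int, k: int, **kwargs) -> LungSegmentation:
    return segment_slice(
        volume.data[phase, k],
        slice_index=k,
        phase_label=volume.phase_labels[phase],
        **kwargs,
    )


def phase_descriptors(
    volume: Volume4D,
    phase: int | str,
    slice_indices: Sequence[int],
    **segment_kwargs,
) -> list[Optional[SliceDescriptor]]:
    """Lung-masked descriptors for the given slices of one phase.

    Returns a list of length ``volume.n_slices`` with ``None`` outside
    ``slice_indices`` and for slices whose segmentation carries no usable
    lung mask.
    """
    p = volume.phase_index(phase) if isinstance(phase, str) else phase
    out: list[Optional[SliceDescriptor]] = [None] * volume.n_slices
    for k in slice_indices:
        seg = _segment(volume, p, k, **segment_kwargs)
        if not seg.usable:
            continue
        out[k] = describe_slice(volume.data[p, k], seg.combined_mask, region="lung")
    return out


def register_phase(
    volume: Volume4D,
    target_phase: int | str,
    source_phase: int | str = "T00",
    slice_range: tuple[int, int] = DEFAULT_SLICE_RANGE,
    margin: int = DEFAULT_MARGIN,
    tie_rel_tol: float = DEFAULT_TIE_REL_TOL,
    source_descriptors: Optional[Sequence[Optional[SliceDescriptor]]] = None,
    **segment_kwargs,
) -> PhaseRegistration:
    """Register every usable slice of ``target_phase`` against ``source_phase``.

    ``slice_range`` uses the conventional 1-based, inclusive slice numbering
    (the default (30, 70) covers the mid-lung slices that carry clear
    segmentation information).  Precomputed ``source_descriptors`` may be
    passed to amortise segmentation across phases.
    """
    tp = volume.phase_index(target_phase) if isinstance(target_phase, str) else target_phase
    sp = volume.phase_index(source_phase) if isinstance(source_phase, str) else source_phase
    lo1, hi1 = slice_range
    if lo1 > hi1:
        raise ValueError(f"slice_range {slice_range} must satisfy lo <= hi")
    if lo1 < 1 or hi1 > volume.n_slices:
        raise ValueError(
            f"slice_range {slice_range} outside 1..{volume.n_slices}"
        )
    lo, hi = lo1 - 1, hi1 - 1  # to 0-based

    if source_descriptors is None:
        src_slices = range(max(0, lo - margin), min(volume.n_slices - 1, hi + margin) + 1)
        source_descriptors = phase_descriptors(volume, sp, src_slices, **segment_kwargs)

    results: list[RegistrationResult] = []
    skipped: list[tuple[int, str]] = []
    for k in range(lo, hi + 1):
        seg = _segment(volume, tp, k, **segment_kwargs)
        if not seg.usable:
            reason = "; ".join(seg.flags) or "no lung information"
            skipped.append((k, reason))
            continue
        desc = describe_slice(volume.data[tp, k], seg.combined_mask, region="lung")
        try:
            results.append(
                register_slice(
                    desc,
                    source_descriptors,
                    k,
                    margin=margin,
                    tie_rel_tol=tie_rel_tol,
                    target_phase=volume.phase_labels[tp],
                )
            )
        except RegistrationError as exc:
            skipped.append((k, str(exc)))
    if not results:
        raise RegistrationError(
            f"no usable slice in range {slice_range} of phase "
            f"{volume.phase_labels[tp]}"
        )
    return PhaseRegistration(
        target_phase=volume.phase_labels[tp],
        source_phase=volume.phase_labels[sp],
        results=tuple(results),
        skipped=tuple(skipped),
        slice_range=slice_range,
        margin=margin,
    )
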