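"""Respiratory-signal modeling from per-phase registration errors.

Registering each phase to the end-inspiration reference (T00) yields, per
slice, an LBP error and an entropy error.  The per-phase scalar

    signal(p) = std(lbp_errors) + std(entropy_errors)

(sample standard deviations over the usable mid-lung slices) rises while
the lung moves away from the reference state and falls as it returns, so
its profile over T10..T90 traces the breathing cycle: the phases before the
peak are inhalation, the peak marks the start of exhalation, and the phases
after it are exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError
from .registration import (
    DEFAULT_MARGIN,
    DEFAULT_SLICE_RANGE,
    DEFAULT_TIE_REL_TOL,
    PhaseRegistration,
    RegistrationResult,
    phase_descriptors,
    register_phase,
)
from .volume_io import Volume4D

__all__ = [
    "RespiratorySignal",
    "phase_signal_value",
    "classify_phases",
    "respiratory_signal",
    "save_signal_plot",
]

START_INHALATION = "start inhalation"
INHALATION = "inhalation"
START_EXHALATION = "start exhalation"
EXHALATION = "exhalation"
FINISH = "finish"


@dataclass(frozen=True)
class RespiratorySignal:
    """Per-phase respiratory signal with breathing-stage labels."""

    phase_labels: tuple[str, ...]
    values: np.ndarray
    labels: Optional[tuple[str, ...]]
    source_phase: str
    slice_range: tuple[int, int]
    registrations: tuple[PhaseRegistration, ...] = ()

    @property
    def peak_phase(self) -> str:
        return self.phase_labels[int(np.argmax(self.values))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": list(self.phase_labels),
                "value": np.asarray(self.values, dtype=float),
                "label": list(self.labels) if self.labels is not None else "",
            }
        )


def phase_signal_value(results: Sequence[RegistrationResult]) -> float:
    """Sum of the sample standard deviations of LBP and entropy errors."""
    if len(results) < 2:
        raise DegenerateInputError(
            f"need at least 2 registered slices, got {len(results)}"
        )
    lbp = np.array([r.lbp_error for r in results], dtype=float)
    ent = np.array([r.entropy_error for r in results], dtype=float)
    return float(np.std(lbp, ddof=1) + np.std(ent, ddof=1))


def classify_phases(values: Sequence[float]) -> list[str]:
    """Label each phase of the signal by its breathing stage.

    The peak (earliest argmax on ties) is the start of exhalation; every
    phase before it is inhalation, the first of those the start of
    inhalation; every phase after the peak is exhalation, the last of those
    the finish.  Degenerate edge cases follow from the rule: a strictly
    increasing signal ends on "start exhalation" with no exhalation phases,
    and a peak in the first phase leaves no inhalation phases.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two phases to classify")
    if np.ptp(vals) == 0:
        raise DegenerateInputError("all phase values equal: no discernible motion")
    peak = int(np.argmax(vals))
    labels = []
    for i in range(vals.size):
        if i < peak:
            labels.append(START_INHALATION if i == 0 else INHALATION)
        elif i == peak:
            labels.append(START_EXHALATION)
        else:
            labels.append(FINISH if i == vals.size - 1 else EXHALATION)
    return labels


def _moving_average3(values: np.ndarray) -> np.ndarray:
    padded = np.concatenate([values[:1], values, values[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def respiratory_signal(
    volume: Volume4D,
    source_phase: int | str = "T00",
    slice_range: tuple[int, int] = DEFAULT_SLICE_RANGE,
    margin: int = DEFAULT_MARGIN,
    tie_rel_tol: float = DEFAULT_TIE_REL_TOL,
    classify: bool = True,
    smooth: bool = False,
    **segment_kwargs,
) -> RespiratorySignal:
    """Register every non-source phase to ``source_phase`` and build the signal.

    ``smooth`` applies a 3-point moving average before classification (the
    reported values stay raw).  With ``classify=False`` no stage labels are
    produced — useful for motion-free datasets where classification is
    undefined.
    """
    sp = volume.phase_index(source_phase) if isinstance(source_phase, str) else source_phase
    if volume.n_phases < 2:
        raise ValueError("need at least two phases")

    lo1, hi1 = slice_range
    src_slices = range(
        max(0, lo1 - 1 - margin), min(volume.n_slices - 1, hi1 - 1 + margin) + 1
    )
    source_descriptors = phase_descriptors(volume, sp, src_slices, **segment_kwargs)

    labels_out, values, registrations = [], [], []
    for p in range(volume.n_phases):
        if p == sp:
            continue
        reg = register_phase(
            volume,
            p,
            source_phase=sp,
            slice_range=slice_range,
            margin=margin,
            tie_rel_tol=tie_rel_tol,
            source_descriptors=source_descriptors,
            **segment_kwargs,
        )
        labels_out.append(volume.phase_labels[p])
        values.append(phase_signal_value(reg.results))
        registrations.append(reg)

    values = np.asarray(values, dtype=float)
    stage_labels = None
    if classify:
        basis = _moving_average3(values) if smooth else values
        stage_labels = tuple(classify_phases(basis))
    return RespiratorySignal(
        phase_labels=tuple(labels_out),
        values=values,
        labels=stage_labels,
        source_phase=volume.phase_labels[sp],
        slice_range=slice_range,
        registrations=tuple(registrations),
    )


def save_signal_plot(signal: RespiratorySignal, path) -> None:
    """Bar/line plot of the signal (value per phase), written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(signal.phase_labels))
    ax.bar(x, signal.values, color="#7aa6c2", label="signal value")
    ax.plot(x, signal.values, "o-", color="#1f4e79")
    ax.set_xticks(x, signal.phase_labels)
    ax.set_xlabel(f"phase (registered to {signal.source_phase})")
    ax.set_ylabel("sum of std of LBP and entropy errors")
    ax.set_title("Respiratory signal")
    if signal.labels is not None:
        for xi, lab in zip(x, signal.labels):
            ax.annotate(
                lab, (xi, signal.values[xi]), rotation=90,
                textcoords="offset points", xytext=(0, 4),
                ha="center", va="bottom", fontsize=7,
            )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
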