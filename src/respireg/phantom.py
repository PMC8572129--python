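"""Synthetic 4DCT breathing phantom with exact ground truth.

The phantom emulates the structure of a thoracic 4DCT study: a bright
elliptical body on a dark background, two dark lung regions whose texture is
distinct on every slice, optional out-of-body artifacts (a couch bar below
the body and a few bright blobs), and a cyclic axial deformation across the
respiratory phases.

Breathing model
---------------
Phase ``p`` of ``n`` displaces lung content axially by

    s(p) = amplitude * sin(pi * p / n)        [slices]

so phase 0 (end inspiration) is the rest state and displacement peaks at
``p = n/2`` (end expiration for the default ten phases, i.e. T50).  The
displacement is depth-weighted by a linear ramp ``w(k)`` rising from 0 at
the lung apex to 1 at the lung base — the diaphragm dominates respiratory
motion.  Slice ``k`` of phase ``p`` therefore shows the lung texture of the
phase-0 slice nearest to ``k + s(p) * w(k)``, and the lung compresses
in-plane by the factor ``1 - lung_shrink_per_slice * s(p) * w(k)``: the
semi-axes shrink and the texture loses aeration (local averaging plus
contrast reduction) in proportion to the compression.  Registration
residuals therefore grow continuously with the local displacement, which
is what makes the per-phase error spread a usable breathing signal.

Every displacement actually applied is recorded, so the generator doubles
as the oracle for registration-recovery tests: the ground-truth match of
``(phase p, slice k)`` is ``round(k + s(p) * w(k))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError
from .volume_io import Volume4D, default_phase_labels, write_dataset

__all__ = [
    "PhantomConfig",
    "PhantomDataset",
    "breathing_displacement",
    "generate_phantom",
    "ground_truth_match",
]

# Geometry of the default phantom as fractions of the frame, mirroring the
# proportions of a thoracic CT slice.
_BODY_SEMI_FRAC = (0.305, 0.390)    # (row, col) semi-axes of the body ellipse
_LUNG_SEMI_FRAC = (0.148, 0.102)    # per-lung semi-axes at full size
_LUNG_ROW_FRAC = 0.484              # lung centre row
_LUNG_COL_OFFSET_FRAC = 0.184       # lung centre offset from the midline
_LUNG_APEX_FRAC = 0.08              # first slice with lungs
_LUNG_BASE_FRAC = 0.92              # last slice with lungs
_MIN_LUNG_PROFILE = 0.25            # below this z-profile no lung is drawn


def breathing_displacement(phase_index: int, n_phases: int, amplitude: float) -> float:
    """Axial lung displacement (slices) of phase ``phase_index``.

    Half-sine over the cycle: zero at phase 0, maximal at ``n_phases / 2``.
    """
    if not 0 <= phase_index < n_phases:
        raise IndexError(f"phase_index {phase_index} out of range [0, {n_phases})")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    return amplitude * math.sin(math.pi * phase_index / n_phases)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic breathing phantom.

    Defaults mirror the geometry of a public thoracic 4DCT study: 256x256
    frames, 92 slices at 2.5 mm spacing, ten phases T00..T90, and a peak
    diaphragm excursion of 4 slices (10 mm).
    """

    image_size: int = 256
    n_slices: int = 92
    n_phases: int = 10
    slice_spacing_mm: float = 2.5
    amplitude_slices: float = 4.0
    body_semi_axes: tuple[int, int] | None = None   # (row, col) pixels
    lung_semi_axes: tuple[int, int] | None = None   # (row, col) pixels
    texture_scale: float = 1.0
    artifact_enabled: bool = True
    noise_sd: float = 0.0
    seed: int = 0
    #: Linear lung shrink per slice of displacement (~6% at the default
    #: 4-slice peak, matching tidal lung-volume change).
    lung_shrink_per_slice: float = 0.015

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigError("image_size must be >= 32")
        if self.n_slices < 3:
            raise ConfigError("n_slices must be >= 3")
        if self.n_phases < 2:
            raise ConfigError("n_phases must be >= 2")
        if self.amplitude_slices < 0:
            raise ConfigError("amplitude_slices must be >= 0")
        if self.amplitude_slices >= self.n_slices / 4:
            raise ConfigError(
                f"amplitude_slices={self.amplitude_slices} too large for "
                f"{self.n_slices} slices (must be < n_slices/4)"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.texture_scale <= 0:
            raise ConfigError("texture_scale must be > 0")

    # -- derived geometry ---------------------------------------------------

    @property
    def body_axes(self) -> tuple[int, int]:
        if self.body_semi_axes is not None:
            return self.body_semi_axes
        s = self.image_size
        return (round(_BODY_SEMI_FRAC[0] * s), round(_BODY_SEMI_FRAC[1] * s))

    @property
    def lung_axes(self) -> tuple[int, int]:
        if self.lung_semi_axes is not None:
            return self.lung_semi_axes
        s = self.image_size
        return (round(_LUNG_SEMI_FRAC[0] * s), round(_LUNG_SEMI_FRAC[1] * s))

    @property
    def lung_apex(self) -> int:
        return round(_LUNG_APEX_FRAC * self.n_slices)

    @property
    def lung_base(self) -> int:
        return min(self.n_slices - 1, round(_LUNG_BASE_FRAC * self.n_slices))

    def depth_weight(self, slice_index) -> np.ndarray | float:
        """Displacement weight w(k): 0 at the lung apex, 1 at the base."""
        k = np.asarray(slice_index, dtype=float)
        w = (k - self.lung_apex) / max(self.lung_base - self.lung_apex, 1)
        return np.clip(w, 0.0, 1.0)

    def lung_profile(self, slice_index: int) -> float:
        """Axial size profile of the lungs: trapezoid along z.

        Full size over the mid-lung span, tapering to zero over the outer
        15% near apex and base.  The flat mid section keeps the rest-state
        lung cross-section constant over the slices used for registration,
        so inter-slice differences there are purely breathing-induced.
        """
        span = self.lung_base - self.lung_apex
        if span <= 0 or not self.lung_apex <= slice_index <= self.lung_base:
            return 0.0
        taper = max(1.0, 0.15 * span)
        rise = (slice_index - self.lung_apex) / taper
        fall = (self.lung_base - slice_index) / taper
        return min(1.0, rise, fall)


@dataclass(frozen=True)
class PhantomDataset:
    """A phantom volume bundled with its exact ground truth.

    ``correspondence[p, k]`` is the real-valued phase-0 slice position
    ``k + s(p) * w(k)`` whose lung content slice ``k`` of phase ``p`` shows;
    row 0 is the identity.  ``left_masks``/``right_masks`` have shape
    ``(n_phases, n_slices, H, W)``; ``body_mask`` is shared by all slices.
    """

    volume: Volume4D
    left_masks: np.ndarray
    right_masks: np.ndarray
    body_mask: np.ndarray
    correspondence: np.ndarray
    config: PhantomConfig

    @property
    def lung_masks(self) -> np.ndarray:
        """Combined (left | right) lung masks."""
        return self.left_masks | self.right_masks

    def save(self, root, layout: str = "png") -> dict:
        """Write the volume plus ground truth (mask PNGs, correspondence CSV)."""
        import imageio.v3 as iio
        import pandas as pd

        root = Path(root)
        manifest = write_dataset(self.volume, root / "volume", layout=layout)
        mask_root = root / "masks"
        for p, label in enumerate(self.volume.phase_labels):
            d = mask_root / label
            d.mkdir(parents=True, exist_ok=True)
            for k in range(self.config.n_slices):
                combined = (
                    self.left_masks[p, k].astype(np.uint8)
                    + 2 * self.right_masks[p, k].astype(np.uint8)
                )
                iio.imwrite(d / f"{k + 1:04d}.png", (combined * 100).astype(np.uint8))
        iio.imwrite(root / "body_mask.png", self.body_mask.astype(np.uint8) * 255)
        rows = [
            {
                "phase": self.volume.phase_labels[p],
                "slice": k + 1,  # slices are reported 1-based
                "source_slice_real": self.correspondence[p, k] + 1,
            }
            for p in range(self.config.n_phases)
            for k in range(self.config.n_slices)
        ]
        pd.DataFrame(rows).to_csv(root / "correspondence.csv", index=False)
        return manifest


def _ellipse(h: int, w: int, center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    if semi[0] <= 0 or semi[1] <= 0:
        return np.zeros((h, w), dtype=bool)
    rr, cc = np.ogrid[:h, :w]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _rng(config: PhantomConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *tags])


def _lung_textures(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice full-frame lung texture fields with distinct statistics.

    Each slice draws its own blob pattern (smoothed thresholded noise), grey
    levels and fill fraction from a slice-local RNG, so LBP histograms of
    different slices differ by far more than sampling noise — the property
    the registration method relies on.  Returns the fields and their blurred
    copies (used by :func:`_compress_texture`).
    """
    h = w = config.image_size
    fields = np.empty((config.n_slices, h, w), dtype=np.float32)
    blurred = np.empty_like(fields)
    for k in range(config.n_slices):
        rng = _rng(config, 11, k)
        sigma = rng.uniform(1.0, 2.5)
        base = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
        q = rng.uniform(0.35, 0.65)
        blobs = base > np.quantile(base, q)
        lo = rng.uniform(22.0, 30.0)
        hi = lo + rng.uniform(22.0, 40.0) * config.texture_scale
        jitter = rng.uniform(0.0, 10.0 * config.texture_scale, size=(h, w))
        fields[k] = lo + blobs * (hi - lo) + jitter
        blurred[k] = ndimage.gaussian_filter(fields[k], 1.5)
    return fields, blurred


#: Aeration-loss gain: texture blend/contrast weight per unit of linear
#: compression (a lung compressed by 5% loses ~15% of its texture contrast).
_AERATION_GAIN = 3.0


def _compress_texture(field: np.ndarray, blurred: np.ndarray, compression: float) -> np.ndarray:
    """In-plane appearance of a lung compressed by the linear ``compression``.

    A compressed lung is less aerated: its speckle texture averages out
    locally (blend toward a blurred copy of itself) and the air/tissue
    contrast falls (spread scaled toward the mean).  Both effects vary
    continuously with ``compression``, so registration residuals track the
    local breathing displacement — the property the respiratory signal
    relies on.
    """
    if compression <= 0:
        return field
    a = min(1.0, _AERATION_GAIN * compression)
    mean = float(field.mean())
    blended = (1.0 - a) * field + a * blurred
    return mean + (blended - mean) * (1.0 - a)


def _body_field(config: PhantomConfig) -> np.ndarray:
    h = w = config.image_size
    rng = _rng(config, 12)
    slow = ndimage.gaussian_filter(rng.standard_normal((h, w)), 8.0)
    mx = float(np.abs(slow).max())
    slow = slow / mx * 6.0 if mx > 0 else slow
    return 188.0 + slow + rng.uniform(0.0, 6.0, size=(h, w))


def _artifact_overlay(config: PhantomConfig, body: np.ndarray) -> np.ndarray:
    """Bright couch bar below the body plus 1-3 bright blobs outside it."""
    h = w = config.image_size
    overlay = np.zeros((h, w), dtype=np.float32)
    cy = cx = (config.image_size - 1) / 2.0
    b_row, _ = config.body_axes
    rng = _rng(config, 13)

    r0 = int(min(h - 2, cy + b_row + max(3, h // 40)))
    r1 = int(min(h, r0 + max(4, h // 24)))
    c0, c1 = int(0.30 * w), int(0.70 * w)
    overlay[r0:r1, c0:c1] = 235.0

    n_blobs = int(rng.integers(1, 4))
    placed = 0
    attempts = 0
    margin = max(4, w // 32)
    while placed < n_blobs and attempts < 200:
        attempts += 1
        r = float(rng.uniform(margin, h - margin))
        c = float(rng.uniform(margin, w - margin))
        radius = float(rng.uniform(max(3, w / 60), max(4, w / 24)))
        blob = _ellipse(h, w, (r, c), (radius, radius))
        # keep artifacts strictly outside the (slightly dilated) body
        if np.any(blob & ndimage.binary_dilation(body, iterations=3)):
            continue
        if np.any(blob & (overlay > 0)):
            continue
        overlay[blob] = float(rng.uniform(215.0, 250.0))
        placed += 1
    return overlay


def generate_phantom(config: PhantomConfig | None = None) -> PhantomDataset:
    """Render the full 4-D phantom with ground-truth masks and correspondences.

    Deterministic given ``config.seed``: equal seeds produce byte-identical
    datasets; different seeds change the textures but not the masks'
    geometry or the correspondences.
    """
    config = config or PhantomConfig()
    h = w = config.image_size
    n_p, n_s = config.n_phases, config.n_slices
    cy = cx = (config.image_size - 1) / 2.0

    body = _ellipse(h, w, (cy, cx), config.body_axes)
    body_field = _body_field(config)
    textures, blurred = _lung_textures(config)

    static = np.zeros((h, w), dtype=np.float32)
    static[body] = body_field[body]
    if config.artifact_enabled:
        overlay = _artifact_overlay(config, body)
        static = np.where(overlay > 0, overlay, static)

    lung_row = _LUNG_ROW_FRAC * config.image_size
    lung_col_off = _LUNG_COL_OFFSET_FRAC * config.image_size
    lung_axes = config.lung_axes

    volume = np.empty((n_p, n_s, h, w), dtype=np.uint8)
    left_masks = np.zeros((n_p, n_s, h, w), dtype=bool)
    right_masks = np.zeros((n_p, n_s, h, w), dtype=bool)
    correspondence = np.empty((n_p, n_s), dtype=np.float64)

    for p in range(n_p):
        s = breathing_displacement(p, n_p, config.amplitude_slices)
        for k in range(n_s):
            wk = float(config.depth_weight(k))
            src_real = k + s * wk
            correspondence[p, k] = src_real
            frame = static.copy()

            prof = config.lung_profile(k)
            if prof > _MIN_LUNG_PROFILE:
                compression = config.lung_shrink_per_slice * s * wk
                shrink = 1.0 - compression
                semi = (lung_axes[0] * prof * shrink, lung_axes[1] * prof * shrink)
                left = _ellipse(h, w, (lung_row, cx - lung_col_off), semi)
                right = _ellipse(h, w, (lung_row, cx + lung_col_off), semi)
                j = int(np.clip(round(src_real), 0, n_s - 1))
                tex = _compress_texture(textures[j], blurred[j], compression)
                lungs = left | right
                frame[lungs] = tex[lungs]
                left_masks[p, k] = left
                right_masks[p, k] = right

            if config.noise_sd > 0:
                frame = frame + _rng(config, 14, p, k).normal(
                    0.0, config.noise_sd, size=(h, w)
                ).astype(np.float32)
            volume[p, k] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    vol = Volume4D(
        data=volume,
        phase_labels=default_phase_labels(n_p),
        slice_spacing_mm=config.slice_spacing_mm,
        provenance="phantom",
    )
    return PhantomDataset(
        volume=vol,
        left_masks=left_masks,
        right_masks=right_masks,
        body_mask=body,
        correspondence=correspondence,
        config=config,
    )


def ground_truth_match(dataset: PhantomDataset, phase: int, slice_index: int) -> int:
    """Nearest-integer phase-0 slice corresponding to ``(phase, slice_index)``.

    The oracle for registration-recovery tests.
    """
    n_p, n_s = dataset.correspondence.shape
    if not 0 <= phase < n_p:
        raise IndexError(f"phase {phase} out of range [0, {n_p})")
    if not 0 <= slice_index < n_s:
        raise IndexError(f"slice {slice_index} out of range [0, {n_s})")
    return int(np.clip(round(dataset.correspondence[phase, slice_index]), 0, n_s - 1))
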