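# Methods

This note documents the models, parameters and numerical choices behind
`respireg`, and what the synthetic phantom does and does not establish about
real data.

## Pipeline overview

Every stage operates on single 8-bit axial slices of a 4-D stack
(`phase × slice × row × col`); nothing is volumetric. The stages compose as

1. **artifact removal** — minimum variance quantization, centred-component
   selection, hole filling → body mask;
2. **lung segmentation** — Otsu threshold inside the body, complement,
   multiply by the body mask, left/right split at the body centroid column;
3. **descriptors** — 256-bin LBP histogram and Shannon entropy over the
   combined lung mask;
4. **registration** — windowed minimum-LBP-error search with entropy
   tie-break, one match per mid-lung slice;
5. **signal** — per-phase spread of the registration errors, classified
   into breathing stages around the argmax.

## Models and conventions

**Minimum variance quantization.** The 256-bin intensity histogram is
partitioned into `K` contiguous classes minimising total within-class
variance. A dynamic program over (class count, last bin) finds the exact
optimum in `O(K · 256²)`; ties resolve toward the smallest cut points.
Quantizing the grayscale intensities directly is equivalent to quantizing
any monotone colour-palette rendering of them, so no palette step is needed.
With `K = 2` the partition coincides with Otsu's (both minimise the same
objective), which the suite asserts.

**Otsu threshold.** Exhaustive scan of `t ∈ [0, 255]` minimising
`σ_w²(t) = ω₀σ₀² + ω₁σ₁²` with pixels `≤ t` as background; the smallest
minimiser wins (determinism under exact ties, e.g. two-valued images). The
threshold is computed over body pixels only — after artifact removal the
background is uniformly zero and would otherwise bias the scan.

**Body mask.** Of the brightest quantization class, the connected component
with the largest overlap with the central ninth of the frame is kept
(patients are centred; couches and stray bright objects are not), falling
back to the largest component when nothing overlaps. Foreground components
use 8-connectivity, holes 4-connectivity — the standard complementary
pairing that avoids topological paradoxes.

**Left/right split.** Candidate components are assigned to the side of the
body-centroid column their own centroid falls on (straddling components are
not cut), the largest per side is kept and hole-filled. "Left" and "right"
are image coordinates, not patient anatomy. Components below 0.5 % of the
body area are discarded as specks.

**No-lung-information guard.** A slice counts as unusable when the Otsu
class means inside the body differ by fewer than 50 grey levels: air against
soft tissue is a ~150-level contrast on 8-bit CT renderings, so a far
smaller gap means the threshold split tissue texture, not anatomy. Apex and
base slices (and slices without lungs entirely) are thereby flagged and
skipped, rather than contributing garbage matches; this implements the
usual "slices outside 30–70 carry no clear lung information" rule as an
explicit, testable criterion.

**LBP.** Bit *b* = 1 iff `center ≥ neighbour_b` — note the `≥`, which
inverts the more common strict-less convention; constant regions therefore
code 255, not 0. Neighbours are read clockwise from the top-left, first
neighbour in the most significant bit. Any fixed rotation of that order
yields equivalent comparisons (asserted end-to-end in the suite). Border
pixels lack a full neighbourhood and are excluded from histograms rather
than padded. The per-bin squared errors are summed into a scalar because
registration needs a total order on candidates.

**Entropy.** Base-2 over the 256-bin intensity histogram (`0 log 0 = 0`),
so values live in [0, 8] bits. The base is a pure rescale and never changes
a comparison.

**Descriptor region.** Descriptors are computed over the combined lung mask
of the segmented slice (segmentation precedes registration); an unmasked
mode exists for diagnostics. The lung mask is the defensible choice: body
and background texture are static across phases and would dilute the
breathing-induced differences.

**Registration.** Window `[i − m, i + m]` clipped to the volume, margin
`m = 5` by default — within one breath, anatomy does not travel further
across slices. The tie set holds every candidate within a relative 1 % of
the minimum LBP error (absolute `1e-12` when the minimum is zero): floating
minima are never exactly equal, and 1 % captures "visually indistinguishable"
minima. Within the tie set the smallest entropy error wins; residual ties
fall to the candidate nearest the target index, then the lower index, so
results are fully deterministic. Slice ranges in the public API are 1-based
and inclusive (the field's reporting convention); in-memory indices are
0-based.

**Signal.** `signal(p) = std(E_LBP) + std(E_H)` with sample (n−1) standard
deviations — the conventional spread estimator for a sample of slices. The
two spreads are summed (rather than taking the spread of summed errors)
because the two error scales are incommensurate and summing the stds keeps
each metric's contribution visible. Classification is rule-based on the
argmax (earliest on ties): phases before it are inhalation (the first
"start inhalation"), the peak is "start exhalation", phases after are
exhalation (the last "finish"). Degenerate shapes follow from the rule — a
strictly increasing signal ends on "start exhalation" with no exhalation
phases. A flat signal (no discernible motion) is a classification error by
design; `respiratory_signal(..., classify=False)` returns the values
without labels for such data. An optional 3-point moving average can smooth
the values before classification; it is off by default because the default
phantom and typical ten-phase data need no smoothing.

**Evaluation.** Dice is computed per slice for left, right and combined
masks. CVar is taken over the per-slice combined error
`E_LBP + E_H` within one phase — the only per-slice scalar the pipeline
produces per registration; note this is an *interpretation*, since "all
registration results" admits several readings, and CVar magnitudes are
therefore comparable within this package but not across implementations.
Self-registration yields all-zero errors and a zero mean; its CVar is
reported as not applicable rather than raising.

## The synthetic phantom

### What it emulates

The phantom mirrors the structure of a public thoracic 4DCT study: 256 × 256
frames, 92 slices at 2.5 mm spacing, ten phases T00 … T90 with T00 at end
inspiration. Each slice shows a bright elliptical body (grey ≈ 188 ± slow
spatial variation) on a zero background, a bright couch bar below the body
plus 1–3 bright blobs outside it, and two dark lungs (grey ≈ 22 … 70).

* **Texture.** Every slice draws its own lung texture: smoothed thresholded
  noise ("blobs") with slice-local fill fraction, correlation length and
  grey levels, plus continuous jitter. Different slices therefore differ in
  texture *statistics*, not merely realisation — LBP histograms of
  neighbouring slices are separated by far more than sampling noise, which
  is the property windowed texture matching needs.
* **Breathing.** Phase `p` displaces lung content axially by
  `s(p) = A sin(π p / n)` slices (default `A = 4`, zero at T00, peak at
  T50), depth-weighted by a linear ramp `w(k)` from 0 at the lung apex to 1
  at the base — the diaphragm dominates respiratory motion. Slice `k` of
  phase `p` shows the lung texture of the phase-0 slice nearest to
  `k + s(p)·w(k)` (nearest-neighbour axial resampling: the method operates
  at whole-slice granularity, and ground truth is defined on the nearest
  integer slice).
* **Compression.** The same depth-weighted displacement compresses the lung
  in-plane by `1 − c · s(p) · w(k)` with `c = 0.015` per slice (~6 % linear
  at the default peak, consistent with tidal lung-volume change): the mask
  semi-axes shrink, and the texture loses aeration — it blends toward a
  blurred copy of itself and its contrast falls, both with gain 3× the
  linear compression. Aeration loss was chosen over geometric zooming
  because order-0/order-1 zooms change descriptors in steps (duplicated
  pixel rows, instant interpolation blur) rather than continuously with the
  displacement; the blend/contrast model makes the registration residual a
  smooth, monotone function of the local displacement, which is exactly the
  property that turns the per-phase error spread into a breathing signal.
* **Ground truth.** Every mask and every real-valued source position
  `k + s(p)·w(k)` is recorded exactly as applied; `ground_truth_match`
  rounds it and serves as the oracle for recovery tests.
* **Axial lung extent.** Lungs span slices 8 … 85 (8 %–92 % of the stack)
  with a trapezoidal size profile: full size over the mid-lung span,
  tapering over the outer 15 %. The flat mid section keeps the rest-state
  cross-section constant over the slices used for registration, so
  inter-slice differences there are purely breathing-induced. Slices whose
  profile falls below 0.25 carry no lungs and exercise the
  no-lung-information path.

### Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| `image_size` | 256 px | frame size of the emulated study |
| `n_slices` | 92 | slice count of the emulated study (2.5 mm spacing) |
| `n_phases` | 10 | ten respiratory bins T00 … T90 |
| `amplitude_slices` | 4.0 | 10 mm peak diaphragm excursion — typical tidal breathing |
| `lung_shrink_per_slice` | 0.015 | ~6 % linear (~12 % area) at peak, matching tidal volume change |
| `texture_scale` | 1.0 | blob contrast 22–40 grey levels over a 10-level jitter floor |
| `noise_sd` | 0.0 | the phantom is a clean geometric/texture phantom whose purpose is exact ground truth; acquisition noise is an explicit robustness knob, not part of the default conditions |
| `seed` | 0 | all randomness flows from one integer; equal seeds ⇒ byte-identical datasets |

### What passing tests do and do not show

The phantom establishes *internal correctness*: the optimisers match
exhaustive oracles, segmentation recovers masks it can in principle recover
exactly, registration recovers recorded correspondences, and the signal's
shape follows the injected breathing model. It does **not** establish
performance on clinical CT: real lungs contain vessels and airways that
violate the two-dark-components model, texture differences between adjacent
slices are weaker and noise-correlated, intensities are Hounsfield-calibrated
rather than 8-bit min-max renderings, and real breathing is neither a pure
half-sine nor depth-linear. Dice values near 100 % on the phantom say the
pipeline is implemented correctly, not that clinical Dice would match.

## Numerical choices and degenerate inputs

* Ties: Otsu → smallest threshold; quantizer → smallest cuts; registration →
  entropy, then proximity, then lower index; classification → earliest peak.
* Constant images/regions are rejected (`DegenerateInputError`) wherever an
  objective is undefined: quantization and Otsu on constant input, entropy
  and histograms over empty masks, CVar with zero mean or fewer than two
  values, Dice of two empty masks, signal values from fewer than two slices.
* 16-bit input volumes are rescaled to 0–255 with the *dataset-global*
  min–max (per-slice scaling would distort inter-slice entropy
  comparisons); the applied rescale is recorded in the volume's provenance.
* `float64` accumulators throughout the histogram prefix sums; interval
  sums of squares are clamped at zero to absorb rounding residue.

## Known limitations

* Whole-slice matching only: no in-plane deformation field, no landmark
  target-registration error; the signal summarises axial motion.
* The signal-peak recovery guarantee degrades for small breathing
  amplitudes: below ~3 slices of peak displacement the half-sine's
  shoulder-to-peak displacement gap (1.9 vs 2.0 slices at amplitude 2)
  falls under the sample-std estimation noise of a 41-slice spread, and the
  argmax can land one phase off for some seeds. The suite therefore asserts
  peak recovery across seeds at the default amplitude.
* Symmetric phases of the noise-free default phantom (`T40`/`T60`, …) have
  *identical* signal values by construction; the classifier's earliest-peak
  tie rule keeps labels deterministic.
* Vessels, airways and the trachea are out of scope for segmentation; slices
  where a lung component touches the centre line are assigned whole by
  centroid, never split.
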