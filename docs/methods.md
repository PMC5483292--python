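# Methods

`thermoface` implements a complete severity-analysis protocol for infrared
thermal facial image (ITFI) sequences: emotion-evoked facial skin-temperature
responses are extracted from a stimulation-locked acquisition, aligned for
head motion, summarised per facial region, and compared between two clinical
severity groups ("moderately ill" vs "markedly ill") with multivariate
statistics and a kernel-SVM classifier. Because no patient thermal data are
publicly deposited for this paradigm, the package ships a synthetic phantom
cohort generator with full ground truth, and every claim the pipeline makes
is validated against that ground truth.

## Acquisition model and stimulus schedule

Frames are 320 × 240 matrices of skin/ambient temperature in °C sampled at
2 fps. The default stimulation protocol is a 225 s film: nine 15 s picture
segments (five pictures × 3 s) interleaved with nine 10 s rest breaks. Each
segment evokes one of three dimensional-emotion categories — HVLA (high
valence / low arousal), LVLA (low valence / low arousal), LVHA (low valence /
high arousal) — and each category appears in exactly three segments. A full
run therefore yields 450 frames per subject and per ROI series.

The published protocol does not state the order of the nine segments; the
default is the repeating cycle HVLA → LVLA → LVHA (three cycles), each
segment followed by a break. Order is configurable through the schedule file
and immaterial to the statistics as long as windowing follows the schedule.

**Response windows.** Forty-eight features per emotion are extracted, yet an
emotion covers 3 × 15 s × 2 fps = 90 frames. The only uniform per-segment
window reproducing 48 is 16 frames (8 s) per segment × 3 segments, so the
default `WindowPolicy` takes the first 16 frames of each matching segment.
The same policy applied to the first three rest breaks yields the
"no stimulus" block, making it PCA-reducible to 9 components like the
emotion blocks. Offset, length and segment count are configurable; nothing
downstream depends on the specific choice beyond the feature count.

## Synthetic phantom

The phantom is deliberately schematic rather than photorealistic — it
reproduces the *statistical* structure the analysis assumes, with closed-form
ground truth:

- **Geometry.** Ambient background (27 °C, within the protocol's 26–28 °C
  room-temperature band), an elliptical face at 33.5 °C, rectangular ROI
  plateaus (forehead 34.3, nose 33.0, mouth 33.8, cheeks 33.6 °C) and two
  cool eye disks at 29.8 °C. The eye disks are high-contrast on purpose: the
  binocular pre-alignment stage needs them. The left disk is drawn slightly
  larger (9 px vs 8 px radius), a mild asymmetry that also gives the
  mirror-detection heuristic a cue.
- **Kinetics.** During a segment of its matching emotion, each ROI's
  temperature relaxes exponentially (first-order, time constant τ = 5 s)
  toward baseline + amplitude; during breaks and non-matching segments it
  decays back toward baseline. The piecewise solution is evaluated exactly at
  frame times, so extracted ROI means can be checked against the analytic
  trajectory to 1e-9 °C.
- **Amplitudes.** No effect sizes in °C are published for this paradigm, so
  the group-mean amplitudes are free parameters chosen once as plausible
  emotion-evoked responses (a few tenths of a °C) mirroring the qualitative
  group-difference pattern of interest: forehead responses differ for every
  emotion (most under LVHA), nose cooling differs for every emotion, the
  right cheek differs under HVLA only. Per-subject amplitudes scatter around
  the group mean with sd 0.08 °C.
- **Nuisance terms.** Per-frame head jitter (translation sd 2 px, rotation
  sd 1°, scale sd 0.5%), i.i.d. Gaussian sensor noise (sd 0.05 °C per
  pixel), linear drift (0.1 °C/min), and a within-subject AR(1)
  "physiological" fluctuation per ROI (stationary sd 0.05 °C, lag-1
  correlation 0.9, i.e. a ~5 s correlation time). The AR(1) term models slow
  vasomotor wandering of skin temperature. It is not cosmetic: ROI averaging
  shrinks pixel sensor noise below 0.001 °C, and without any within-subject
  variability every decayed copy of a subject's response (carry-over into
  breaks and baselines) would be exactly as detectable as the directly
  stimulated cell, which no real recording behaves like.

Two sampling paths share the trajectory model. `generate_subject` rasterises
full frames (used to exercise registration); `generate_cohort_series` emits
ROI-mean series directly with sensor noise scaled by 1/√(ROI pixel count),
which is how hundreds of cohorts are simulated for calibration studies. A
closed-form test proves the two paths agree on noiseless input.

Cohort defaults are 18 moderately and 17 markedly ill subjects (N = 35).

## Registration

A fixed reference is built from the first frame: eye regions are pixels
colder than the face-mask median by ≥ 2 °C (face mask = pixels above a
28.5 °C background threshold), the two largest connected components are the
eyes, and their intensity-weighted centroids give sub-pixel centers. The
frame is flipped horizontally if the heavier eye blob sits on the right
(mirrored acquisition — a heuristic, since nothing else in a two-eye
geometry breaks the symmetry) and translated so the binocular midpoint sits
at the canonical position (image center column, 5/12 of the height).

Every frame is then aligned to the reference by a real-coded genetic
algorithm maximising the negative mean absolute temperature difference over
the face mask. Stage 1 searches translation ± 15 px and rotation ± 10° with
scales fixed; stage 2 refines all six affine parameters (translation ± 3 px,
rotation ± 2°, scales 1 ± 0.05, shear ± 0.05) around the stage-1 optimum.
GA operators: population 50, 60 generations per stage, tournament selection
(k = 3), uniform crossover (rate 0.8), Gaussian mutation (rate 0.1, sd =
10 % of the bound width), elitism 2 — all configurable, deterministic given
the seed; elitism makes the best-fitness trace non-decreasing. Sequence
registration warm-starts each frame's stage 2 at the previous frame's
solution. Warps use bilinear interpolation about the image center with a
constant background fill; identity parameters return the input bit-exactly.

Measured on half-scale phantoms (160 × 120) with the default GA budget —
the problem size used throughout the validation suites — planted jitter at
the default scales is recovered with median error ≈ 0.15 px / 0.18°, and the
mean overlap error falls from ≈ 0.34 to ≈ 0.05 °C.

## Features and statistics

ROI rectangles are placed relative to the binocular midpoint and scaled by
the inter-ocular distance *d* (forehead 1.6d × 0.6d above the eyes, nose
0.5d × 0.6d, mouth 0.9d × 0.4d, cheeks 0.6d × 0.6d lateral) — an invented
but stored-and-overridable layout, since no ROI geometry is published. Per
frame, the ROI value is the arithmetic mean over the half-open rectangle.

Features are temperature *changes*: each 16-frame window minus the mean of
the final 3 s of the rest break immediately preceding its segment (the first
event falls back to the sequence's opening 3 s). This per-segment baseline
removes drift and makes features invariant to constant offsets; global and
raw alternatives are selectable.

Each of the 20 blocks (5 ROIs × {HVLA, LVLA, LVHA, no-stimulus}) is a 35 × 48
matrix. PCA (column-centered, unscaled — all features share °C) fitted
across subjects per block reduces it to 35 × 9 scores; component signs follow
a largest-loading-positive convention. Fitting per block across subjects is
the only scoping under which 48 → 9 yields a 35 × 9 MANOVA input per cell.

The group comparison is a one-way MANOVA per cell using Wilks' Λ =
det(E)/det(E+H). For two groups the exact transform
F = ((1−Λ)/Λ)·(N−k−1)/k on (k, N−k−1) df is used — equivalent to Hotelling's
T², and verified against an independently coded T² oracle to 1e-10 (and
against `statsmodels`' MANOVA). With N = 35, k = 9 the df are (9, 25).
Raw p-values are reported with star thresholds 0.05/0.01/0.001; no
multiple-testing correction by default (a Bonferroni flag would be a one-line
extension). A singular within-group SSCP (k too large for N) raises a
diagnostic error; the pipeline records such cells rather than crashing.

## Classification

Four SVM presets mirror the common classifier-app kernels: linear,
quadratic (poly degree 2, coef0 = 1), cubic (poly degree 3) and "medium
Gaussian" (RBF with length-scale √k, γ = 1/k), all with unit box constraint.
Evaluation is stratified 5-fold cross-validation (the fold count is a
convention choice; the published protocol names none) with features
standardized by training-fold statistics only; accuracy is the percentage of
correctly classified held-out subjects, hence always a multiple of 100/35 on
the default cohort. The component sweep re-fits PCA per k ∈ {8,…,12} on the
full block before CV by default, mirroring the sequential
reduce-then-classify description; `leakage_safe=True` re-fits PCA inside
each training fold and is the methodologically preferred option.

## Validation summary (all recomputed by the test suite / acceptance script)

- Protocol contracts: 225 s, 9 breaks, 3 × 15 s segments per emotion, 450
  frames per series, 48 features per emotion, 9 components, df (9, 25).
- Registration: median planted-transform recovery ≤ 0.5 px / 0.5° over 20
  frames; mean overlap error strictly reduced.
- Statistics: Wilks F ≡ Hotelling F to 1e-10; univariate case ≡ squared
  pooled t; under the null phantom the fraction of cells with p < 0.05 over
  200 cohorts is ≈ 0.05.
- Signal: a gap planted only in forehead-LVHA makes that cell the smallest-p
  cell in the majority of 50 cohorts (the runner-up is forehead-rest, which
  genuinely carries the decaying response into the following break), and SVM
  accuracy at k = 9 exceeds the permuted-label null by well over 20 points.
- Determinism: identical config + seed ⇒ byte-identical result CSVs.

## Limitations

- The phantom is geometric, not photorealistic: no perfusion physics, no
  camera non-uniformity, no facial expression deformation (registration is
  purely affine by design).
- Mirror detection relies on eye-blob mass asymmetry; on a perfectly
  symmetric face it is undecidable.
- Synthetic effect sizes are free parameters; passing the planted-signal
  suites demonstrates that the pipeline recovers structure of the assumed
  kind and magnitude, not that real cohorts carry such effects.
- The ROI layout and the 8 s response window are reconstructions; deployments
  on real data should treat both as tunable and store them alongside results
  (the ROI JSON and schedule/policy files exist for exactly that).
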