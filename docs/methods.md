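# Methods

## The measurement model

The optical redox ratio RR = NADH/FAD is computed pixel-wise (voxel-wise in
3D) from two autofluorescence channels acquired with a 14-bit camera
(digital numbers in [0, 16383]).  Raw intensities are meaningless across
days because the excitation lamp drifts; two calibrations restore
comparability:

* **Cuvette normalization (in vivo).**  Each tissue frame is divided by the
  mean intensity of a reference-fluorophore cuvette frame acquired the same
  day in the same channel.  Since the drift factor multiplies tissue and
  cuvette alike, the calibrated frame (cI)/(cM) = I/M is drift-free — an
  exact identity, tested as such.  The cuvette mean uses all pixels of the
  cuvette frame: the reference solution is homogeneous and a full-frame
  mean is the least arbitrary region choice.
* **Flat-field correction (cryo).**  Each slice is divided by
  flat/mean(flat).  The normalized divisor preserves the stack's intensity
  scale; note it preserves the stack *mean* exactly only when intensity is
  proportional to the illumination field (true of the synthetic
  construction) or the flat is constant — for arbitrary stacks the
  preservation is first-order.  Background voxels below
  `threshold_fraction × (99.5th percentile)` are then zeroed and excluded
  from every downstream statistic; the percentile anchor (not the max)
  resists hot pixels, and correction precedes zeroing so the illumination
  pattern cannot distort the cutoff (order is configurable).

Wound pixels come from Otsu thresholding a 3×3-median-smoothed white-light
frame (the wound bed is darker than shaved skin), keeping the largest
8-connected component, filling holes and applying one radius-1 opening.
This automates a traditionally visual delineation step for reproducibility;
manual masks (PNG/TIFF, nonzero = wound) are accepted everywhere.  Ties
between equal-size components go to the one nearest frame centre (wounds
are centred by protocol).  For biopsies the wound mask is simply all
non-background voxels: excised samples contain only wound tissue.

**Division by zero.**  The ratio is undefined where calibrated FAD falls
below a floor (default 1% of the masked median FAD).  The surface/volumetric
means divide by the count of *valid* pixels, not the mask count: an
undefined ratio cannot contribute zero without biasing the mean downward.
Both counts are reported so either convention can be reproduced.  Saturated
pixels are retained; a frame with >1% saturated pixels triggers a warning.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size | 40 | µm | instrument geometry; constant, so it cancels in N(t)/N(0) |
| wound radius, day 0 | 5.0 | mm | 10 mm circular full-thickness wound |
| `fad_floor` | 1% of masked median FAD | – | excludes unstable ratios, logged as excluded fraction |
| `threshold_fraction` | 0.10 | – | cryo background cutoff vs 99.5th percentile |
| histogram | 100 bins on [0, 4] | – | visible support of wound RR distributions |
| `noise_gain`, `read_noise_sd` | 4, 10 | DN | standard CCD Poisson–Gaussian model |
| `lamp_drift_sigma` | 0.15 | – | lognormal per-day per-channel drift |
| `subject_sd` | 0.03 | RR | between-mouse spread of redox state |

## The synthetic cohort

The generator emulates the stated experiment: n = 6/group imaged on days
0/2/4/6; biopsies cryo-imaged at the endpoints (n = 4/group at day 0 from
separate animals, n = 6/group at day 6 from the imaged animals).  Wounds are
filled disks with integer-pixel centre jitter (±3 px), so the true pixel
count is the exact lattice count of the scheduled radius — 49,077 pixels
for the full-scale 125 px day-0 disk (the exhaustive count, slightly below
π·125² ≈ 49,087).  Frames smaller than ~512² cannot hold the full-scale
disk; geometry is then shrunk by powers of two and the scale recorded in
the truth sidecar (256² frames run at half scale).

Planted trajectories: both groups start at surface RR 1.2; controls stay at
1.2 while diabetic wounds decline to 0.468 by day 6 (a 61% drop).  Control
wounds close (radius 5.0 → 2.2 mm); diabetic wounds do not.  Volumetric RR
is equal across groups at day 0 and 66% lower in diabetics at day 6
(0.408 vs 1.2).

**RR–area coupling.**  Each subject-day's true surface RR is
`μ(group, day) + b·(A − 1) + u_subject + ε`, with u ~ N(0, 0.03²).  The
noise sd is tied to the slope by σ² = b²·Var(A)·(1 − R²)/R² at the target
pooled R² of 0.72, and b (≈ −1.15) is solved at runtime so that the
*expected pooled regression* of RR on normalized area hits that target —
the planted group trajectories are themselves correlated with area, so the
closed form alone would not.  A side effect of the b·(A − 1) form is that
control RR rises as control wounds close; this keeps the diabetic anchors
(day-0 equality, the 61% drop) exactly intact, and control trajectories are
not otherwise pinned by data.

**Exact planting.**  By default, subject effects are centred within group
and ε within each (group, day) cell, so cohort group means equal the
configured trajectories exactly while within-cell spread is preserved for
the ANOVA error terms.  With `center_effects=False` draws are i.i.d. — the
regime used for statistical calibration studies.  Cells are redrawn in the
rare event a planted RR would be non-positive.

**What a green test does not establish.**  The phantom world omits spectral
bleed-through, keratin autofluorescence (which overlaps the FAD band), fur
and specular artifacts, wound-margin ambiguity, inter-day registration
error, and spatial heterogeneity of the wound bed (the planted RR is
uniform within the wound).  Recovery of the planted effects therefore
validates the arithmetic and calibration chain, not robustness to biology
the generator does not model.  Flat-field frames are emitted noise-free
(labs average many flat exposures); tissue slices carry the full noise
model.

## Statistics

The group × day repeated-measures ANOVA is computed from explicit sums of
squares (between-subjects split into group and subjects-within-group;
within-subjects into day, group × day and the day × subjects error), so the
decomposition identity ΣSS = SS_total is testable to 1e-9 on any input.
Greenhouse–Geisser epsilon (from the pooled within-group covariance of the
day measures) is reported with corrected p-values alongside, but the
uncorrected p is the headline, matching common practice.  Tukey HSD
contrasts per day use the studentized-range distribution with the per-day
pooled MSE; SE in summaries is SD/√n; no multiple-testing adjustment is
applied across the three markers (recorded in output metadata).  Degenerate
inputs are explicit: all-identical responses yield a no-variance result
(F undefined), a zero-error planted effect yields F = ∞, p = 0.

Calibration of the interaction test (200 replicate cohorts, i.i.d. draws):
empirical type-I error 0.06 with fully equalized groups (both trajectory
*and* healing schedule — equalizing only the RR map leaves the area-coupling
term group-specific, a real interaction, not a null) and power 1.0 with the
planted effect.

## Numerical choices and limitations

* All grids are 0-based, row-major, pixel/voxel-centred; disk membership is
  centre-distance ≤ radius.
* Determinism: every random stream derives from `(seed, stream-tag, …)`
  tuples via numpy's SeedSequence machinery; a fixed seed reproduces the
  dataset bit-for-bit and the metrics CSV byte-for-byte.
* Measured means carry a small (+0.4% at default noise) Jensen bias from
  dividing noisy channels; this is far inside the 2% recovery tolerance and
  is not corrected.
* The pipeline quantifies whole-wound means only; regional sub-structure
  (epithelial tongue, granulation tissue) is out of scope.
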