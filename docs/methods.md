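# Methods

This note documents the models, conventions and numerical choices behind
`wormfeatures`, in particular the places where a convention had to be
fixed because the underlying quantities admit more than one reasonable
definition.

## Input model

A trajectory is a per-frame skeleton of P ordered midline points
(micrometres; point 0 is the head tip, point P−1 the tail tip; default
P = 49), an optional width profile, strictly increasing timestamps, a frame
rate, and a ventral-side annotation (`left`, `right`, or `unknown`).
Frames where tracking failed carry NaN coordinates and a `frame_valid`
mask; readers never interpolate them — every downstream feature is NaN on
invalid frames. Missing widths make width-derived features NaN rather than
raising, so the NaN-tolerant cleaning stage can deal with them.

## Body segments

The P points are partitioned into five contiguous fifths — head, neck,
midbody, hips, tail. When P is not divisible by five, the midbody takes
the smallest share so the partition stays symmetric (for P = 49:
10/10/9/10/10, midbody = points 20–28). `head_base` is the boundary point
between head and neck (index 10), `tail_base` between hips and tail
(index 39). These index conventions are this package's; any fixed,
documented partition works as long as it is used consistently.

## Core features

- **Length** is the skeleton arc length (sum of consecutive point
  distances). **Area** integrates the width profile along the midline.
- **Axes / quirkiness** come from the second moments of the skeleton
  points. Axis lengths use the solid-ellipse convention (full axis =
  4·√eigenvalue of the point covariance), so a straight worm of length L
  has major axis ≈ L·(4/√12) ≈ 1.15 L; quirkiness √(1 − minor²/major²) is
  scale-free and unaffected by the convention. Quirkiness is 0 for a
  circle and 1 for a line; the closed form is exact on ellipse-sampled
  points.
- **Curvature** is dφ/ds of the tangent angle with respect to arc length.
  Coordinates are pre-smoothed with a Savitzky–Golay filter whose window
  spans about 1/12 of the body (5 points at P = 49, polynomial order 3);
  tangent angles come from arc-length gradients of the smoothed
  coordinates. On a circular arc of radius R the interior segments (neck,
  midbody, hips) recover 1/R to better than 0.1%; the head and tail
  segments are boundary-affected (up to ~7% at P = 49) — an inherent
  property of end-point derivative estimation, shared by any tracker-side
  implementation. Segment curvature is the mean over the segment's points
  (the value at the segment midpoint would be an equally defensible
  choice).
- **Velocities** are central differences of anchor positions over a
  window (default 0.5 s, rounded to frames). Speed is signed by the
  alignment of the displacement with the tail-to-head body axis (positive
  = head-ward). Angular velocity differentiates the unwrapped orientation
  of the segment's mean tangent. Relative velocities are the rate of
  change of the distance (radial, positive = receding) and of the bearing
  angle (angular) of a moving anchor about a reference anchor; the 12
  (reference, moving) pairs of the default inventory relate the tips and
  bases of the worm to nearby segments and to the whole-body centroid.
  Central differencing attenuates oscillatory signals by sinc(ω·w/2);
  with the 0.5 s default this is <3% below 0.5 Hz.
- **Motion state** thresholds the smoothed signed midbody speed: forward
  above 0.05 body lengths/s, backward below −0.05, paused below
  0.01 BL/s in magnitude, with the band in between acting as hysteresis
  (the previous state persists). Bouts shorter than 0.5 s are merged into
  their neighbours. Body-length units make the thresholds size-invariant;
  all three values are configurable.
- **Eigenworm amplitudes** project the mean-subtracted tangent-angle
  profile onto a K×(P−1) orthonormal basis (default K = 7). The shipped
  default basis is synthetic — orthonormalized, mean-free sinusoids of
  increasing spatial frequency — standing in for an experimentally derived
  postural basis, which can be supplied as a CSV of tangent-angle loadings
  instead. Amplitudes, not the basis, are the feature.
- **Path features** describe the centroid track: path curvature of the
  smoothed (1 s window) centroid trajectory, NaN wherever the centroid
  moves slower than 2 µm/s (the tangent is undefined for a stationary
  worm); coverage (area of distinct 50 µm grid cells visited by a segment
  centroid) and dispersion (radius of gyration of the centroid) over
  non-overlapping 10 s windows. Coverage and dispersion are slow windowed
  quantities: they are held step-wise constant across their window so they
  can be summarized by percentiles like every other series, and they are
  not differentiated or subdivided by motion state, where those operations
  have no meaning at window scale. Path definitions are package
  conventions; the cell size and windows are configurable.

## Fingerprint expansion

Feature names follow the grammar

```
[d_] base [_segment] [_norm] [_w_state] [_abs] _summary
```

with `summary` ∈ {10th, 50th, 90th} for time-series features and
{fraction, frequency} for motion-mode events. The structured form and the
string form round-trip exactly. `_norm` divides by the per-frame body
length (widths, axes, area, speeds, radial velocities) or multiplies by it
(curvatures), making the value dimensionless or size-invariant.

Undefined quantities stay NaN rather than being zero-filled: a worm that
never pauses has NaN paused-state features; a worm with unknown ventral
side has NaN *signed* percentiles for dorsoventrally signed bases
(curvature, angular velocities, eigen amplitudes, path curvature) while
their `_abs` versions, and direction-signed speeds, remain defined. For
signed features the derivative is taken on the signed series first, then
`_abs`, then the percentile.

The default inventory enumerates 4083 unique names from 16 base features:
20 unsigned fully expanded channels (2 derivative variants × 4 state
variants × 3 percentiles = 24 values each), 74 signed fully expanded
channels (48 values each: percentiles of both the signed and the absolute
series), path curvature raw and normalized (12 each: no state split),
seven percentile-only path channels (3 each) and six motion-mode event
statistics. `frequency` counts entries into a state per second of defined
time, which makes it frame-rate independent. The inventory is shipped as
JSON data (`wormfeatures/data/feature_inventory.json`) and can be pruned
or extended; `tierpsy_8`/`tierpsy_16` are explicit published name lists,
`tierpsy_2k` is the programmatic restriction that drops eigen amplitudes,
drops length normalization except for widths, and keeps only absolute
values of dorsoventrally signed features (1929 names — just under half the
full set). The membership of the 256-feature preset is published as
supplementary data elsewhere and is therefore user-suppliable rather than
shipped.

## Feature selection

Cleaning drops features that are NaN in more than 2.5% of worms and
imputes remaining NaNs with the feature's population mean, computed over
all worms before splitting (a train-only variant would avoid a small
leakage; population-mean imputation is the reference behaviour and the
leakage does not involve labels). z-normalization uses the population
standard deviation; constant features become zeros with a warning.

Splits are 80/20 within each strain; the train share is
clamp(round(0.8 n), 1, n−1) so both sides are non-empty for n ≥ 2.
Classification is multinomial logistic regression trained by minibatch SGD
on the categorical cross-entropy (learning rate 0.05 with 1/(1+0.01·epoch)
decay, 60 epochs, batch 32, L2 10⁻⁴, seeded shuffling; all recorded in the
result). Importance of a feature is the increase in the *data* loss when
its column is ablated — set to zero, i.e. to the normalized mean — in the
fitted model, without refitting; this is computed vectorized by
subtracting each column's contribution from the decision scores and equals
explicit per-feature recomputation to 10⁻¹⁰. Elimination drops the least
important features to the largest power of two strictly below the current
size (a size already a power of two halves), down to one feature, with
ties broken by feature name for determinism. The whole procedure repeats
(default 10×) over fresh per-strain splits — our reading of "different
random subsets of worms" — and reports per-size test accuracies.

## Pulse analysis

Frames are assigned to pulse-relative time bins (defaults: −5..0, 0..5,
5..15 s around short pulses; −30..0, 0..10, 10..90, 90..120 s around long
pulses) and pooled across pulses of the same class and worms of the same
condition. Histograms use 25 bins spanning the pooled 1st–99th percentile
range of the two groups being compared, with out-of-range values clamped
into the end bins; the grid is shared between the groups and, for strain
distance matrices, across strains. Binning and layout are configurable —
the analysis needs only "multiple time bins", not these particular ones.

The test statistic is the base-2 Jensen–Shannon divergence between the
pooled treatment and control histograms. The permutation test reshuffles
*worms* between the two condition labels (default 1000 permutations,
add-one estimator p = (1+#{perm ≥ obs})/(1+N) so p > 0); frames within a
worm are correlated (worms differ in baseline), so permuting frames would
be anticonservative — the test suite demonstrates a ~7× type-I-error
inflation for frame-level shuffling on worm-random-effect data, while the
worm-level test's null p-values are uniform. With fewer than 20 distinct
assignments the null is enumerated exactly (with a warning).
Benjamini–Hochberg step-up q-values are computed within strain across all
(feature, bin) comparisons and rejected at FDR 0.05. Between-strain
distances take the median JSD across (feature, bin) histogram pairs;
cluster maps use average-linkage hierarchical clustering with scipy's
deterministic tie-breaking.

Note the granularity interaction between the permutation count and BH: the
smallest attainable p-value is 1/(N+1), and with m comparisons a true
effect needs m/(k·(N+1)) ≤ 0.05 to survive correction at rank k — N = 1000
suffices for the analyses here, but small N silently costs power, not
validity.

## Synthetic data

The worm model is a travelling sine wave in the tangent angle,
θ(s, t) = A·sin(2π(s/λ − phase(t))), integrated to coordinates, anchored
at its shape centroid and advected along the body axis at a scheduled
signed speed (defaults: length 1000 µm, maximum width 80 µm with a
tapered profile, amplitude 0.6 rad, wave frequency 0.5 Hz, wavelength one
body length, speed 300 µm/s, 25 fps). During scheduled pauses the
centroid freezes and the wave phase advances at 10% rate (a paused worm
holds its posture apart from residual slow movement). Gaussian coordinate
noise is optional. This exercises every feature operator with analytic
expectations — exact length, zero curvature at zero amplitude, recoverable
motion-state fractions (±0.03 after window edges and bout smoothing) — but
it is not a biomechanical simulation: there are no omega turns, no
self-occlusion, no substrate interaction, and anchor speeds during
locomotion include an undulation component above the scheduled advection
speed. Passing tests therefore certify the *operators*, not realism of
locomotor dynamics.

Feature tables are class-conditional Gaussians: informative columns get
per-strain mean offsets drawn N(0, effect²) (default effect 2 sd, 5
informative of 125 columns, 4 strains × 50 worms), noise columns are
standard normal, and NaNs can be injected per column. Pulse experiments
draw per-worm random intercepts (sd 0.5) plus unit frame noise and add a
stimulus-locked mean shift on chosen features in the treatment arm only —
the random intercepts are what make frame-level permutation demonstrably
invalid.

## Problem sizes in the shipped tests

The test suite and acceptance script run at desk scale by design:
synthetic tables of 125–3000 features and 120–200 worms, pulse experiments
of 12–30 features and 15 worms per arm, permutation tests at 200–1000
permutations, and 500-simulation calibration runs. These sizes were chosen
as the smallest at which the statistical assertions (planted-feature
recovery, p-value uniformity, FDR control, power) are stable across seeds.

## Known limitations

- Head/tail orientation and ventral-side annotation are trusted from the
  tracker; no re-disambiguation is attempted.
- Curvature at the head and tail segments carries boundary bias (see
  above); comparisons across worms are unaffected since the bias is
  systematic.
- The eigenworm default basis is synthetic; absolute amplitude values are
  only comparable across analyses that use the same basis.
- Percentile summaries discard temporal ordering within a state; the pulse
  module exists precisely for effects that are localized in time.
- The permuted statistic is the JSD of re-pooled histograms on a fixed
  grid; re-deriving the grid per permutation would be marginally more
  faithful and substantially slower, and does not change calibration in
  the regimes tested.
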