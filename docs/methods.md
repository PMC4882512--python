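# Methods

## The measurement this package models

Organelle transport along thin neurites is saltatory: bursts of
motor-driven, microtubule-dependent movement separated by pauses. The
canonical readout is time-lapse imaging of fluorescently labelled
peroxisomes in axon-like processes (z-stacks every 2 s for 4 min), maximum
projection of each stack, spot detection, frame-to-frame tracking, and
per-track statistics. Tracks that do not span the entire observation period
are discarded before any motion metric is computed; this completeness filter
is part of the measurement definition, not an implementation detail, and it
is applied identically here.

Per-track metrics. Instantaneous speed is the Euclidean displacement of the
projected 2-D centroid between consecutive frames divided by the frame
interval (2 s). Mean speed is the arithmetic mean of that series, which
equals path length / total time. A saltatory event is a maximal contiguous
run of instantaneous speeds strictly above 0.1 μm/s; event duration is the
run length times the frame interval. A fast mover is a track whose mean
speed strictly exceeds 0.14 μm/s — operationally, the 90th percentile of a
control speed population; `calibrate_fast_threshold` recomputes it from
data. "Exceeding" is read as a strict inequality for both thresholds, so
boundary values are excluded. Direction is classified from the net axial
displacement relative to the soma with a guard band ε = 0.2 μm (net
displacements within ±ε are "stationary"); the guard exists because
localisation noise makes exact zero-displacement classification meaningless.
Organelle density uses a half-open axial window, by default [20, 140) μm
from the soma (a [20, 120) variant is selectable), so boundary spots are
never double-counted.

## Generative model (synthetic_data)

The simulator produces ground-truth tracks with the statistical structure
the analysis assumes, so every downstream stage can be validated without
real data. Geometry is a straight 1-D process: the axial coordinate s runs
from the soma (s = 0) distally, and equals the image x coordinate; the
transverse coordinate y is confined to the process width (default 1 μm,
processes being 0.5–1 μm wide and 150–300 μm long; default length 240 μm).

Three motion classes, drawn per track:

- **fast** (saltatory): alternating runs and pauses with exponential
  durations (defaults: mean run 6 s, mean pause 9 s). Each run moves at a
  constant speed drawn per run from a normal (default 0.55 ± 0.22 μm/s,
  floored at 0.10 μm/s) in the track's direction. Direction is drawn once
  per track — anterograde with probability `p_anterograde` — and every run
  inherits it, so the track-level anterograde fraction equals
  `p_anterograde`, matching how directionality is scored (per organelle,
  not per excursion). Displacement per frame integrates the run/pause
  segments exactly over each 2 s interval.
- **slow** (Brownian-like): zero-mean Gaussian axial steps. The per-frame
  step SD is itself heterogeneous across organelles — base 0.09 μm/frame
  times a lognormal multiplier (σ = 0.48, truncated at +3σ). Without this
  heterogeneity the population speed histogram is visibly bimodal with an
  empty band between the slow and fast classes, which real speed
  distributions do not show and which makes upper percentiles unstable.
- **immobile**: localisation noise only.

All tracks get isotropic localisation noise (SD 0.02 μm) and transverse
jitter reflected into the process width. Positions are clipped to
[0, process_length]; fast tracks start inside a window that leaves room for
their expected excursion, so clipping is a safety net rather than a regular
event. Randomness derives from one master seed with a per-track substream
(`SeedSequence(seed, track_index)`), so enlarging a simulation never
perturbs existing tracks.

Calibration. The class fractions and direction biases are the measured
condition values (control 10% fast / 60.9% anterograde; patient 2.3% /
86.1%; the epothilone-D preset restores control values). Within-class speed
parameters are not published; the defaults above were chosen once, by a
seed-swept calibration of the generator alone, so that a control population
reproduces the reported regime: population mean speed ≈ 0.06 μm/s, 90th
percentile ≈ 0.14 μm/s, and a fast class that is separable at the 0.14 μm/s
threshold (sensitivity ≈ 0.96, specificity > 0.99). The 70/30 split of the
non-fast mass between slow and immobile is a free parameter. All of these
are config-exposed, none is hard-coded.

Rendering. Spots are Gaussian PSFs (σ = 0.25 μm) with peak `photon_scale`
photons, distributed over z-slices with normalised Gaussian weights around a
per-track focal depth (total photons conserved per spot to <1% across
frames, the PSF truncation tolerance); Poisson shot noise on signal plus
background, then Gaussian read noise. `shot_noise=False` with zero read
noise gives exactly reproducible noiseless movies for fidelity tests.

Cell fields. For the cytoplasmic-marker pipeline, fields of non-overlapping
disc cells (nucleus disc inside a larger cell disc) carry a marker channel
whose per-cell cytoplasmic value is drawn from
N(condition mean, cell SD); nuclei carry no marker, mirroring a cytoplasmic
adduct stain. Ground-truth per-cell means are returned for recovery tests.

What the generator does *not* emulate: curved or branching neurites,
photobleaching, focus drift, organelle fission/fusion, crowding at real
densities (~80 organelles per process), or motion blur within an exposure.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under its stated assumptions (resolvable spots, complete tracks), not
robustness to every real-data pathology.

## Detection and tracking

Detection runs on per-frame maximum projections: a Laplacian-of-Gaussian
band-pass at σ = expected_diameter / (2√2) (expected diameter 0.75 μm, the
middle of the organelle size range), an automatic robust threshold
(median + 10·MAD of the filtered response; a k of 5 was found to admit
spurious background peaks on large sparse fields), deterministic
local-maximum selection (ties broken by row, then column), merging of
maxima within `min_separation` keeping the brighter, and subpixel refinement
by intensity-weighted centroid in a one-diameter window. On noiseless
renders the centroid error is ~0.05 px.

Linking solves, per consecutive frame pair, the gated linear assignment
problem: minimise total squared displacement plus a birth/death penalty of
gate² × 1.0001 per unmatched endpoint (gate default 2.5 μm/frame ≈ 1.25
μm/s, above any plausible burst displacement). Optimal assignment rather
than greedy nearest-neighbour makes the result invariant to detection order;
the tests verify equivalence with exhaustive enumeration for up to 5 spots
per frame. `max_gap` defaults to 0 because the completeness filter discards
gapped tracks anyway; gap-closing with linear interpolation is available.

For end-to-end validation, simulated tracks are packed into rendering
fields by greedy first-fit such that no two organelles in one field ever
come closer than 5 μm (twice the link gate). Packing only chooses which
organelles are imaged together — the per-track motion statistics are
untouched — and corresponds to imaging sparse processes, where the original
analysis was in any case manually curated. Within that regime the tests
require zero identity swaps and sub-half-pixel RMSE.

## Statistics (population_stats)

One quantile convention is used everywhere: the τ-quantile is the minimiser
of the check loss Σ ρ_τ(x_i − q), with the midpoint of the minimising
interval when nτ is integral. The quantile-regression group contrast
exploits the binary-covariate identity — the check-loss-minimising group
coefficient equals the difference of group quantiles — and attaches a
case-resampling bootstrap (seeded, default 1000 resamples) for SE and 95%
CI, with a two-sided p from the normal approximation; analytic
quantile-regression standard errors are estimator-specific and were not
reported for the original analysis, so the bootstrap is used instead.

t tests are Student (pooled-variance): the published degrees of freedom
(df = 8 at n = 5 + 5) are the pooled convention. `t_from_summary` computes
t = (m₁ − m₂)/√(SEM₁² + SEM₂²) from printed summaries and agrees with
`t_from_values` exactly for equal group sizes. The chi-square test is plain
Pearson against independence. The mixed repeated-measures ANOVA (between:
disease group; within: treatment condition; subjects = cell lines nested in
group) is computed from sums of squares, with subjects-within-groups as the
error for the between effect and condition × subjects-within-groups for the
within effects; it is cross-checked in the tests against an independent
reference implementation and a fully hand-worked 2×2 design. The unit of
analysis for group tests is the cell line (n = 5 per group); track-level
pooling is used only for frequency distributions and quantile contrasts.

p-values are reported but never used as acceptance surfaces; only
statistics and effect estimates are asserted in tests.

## Cell fluorescence

Nuclei are segmented by Otsu threshold + connected components with a
minimum-size filter (an optional distance-transform watershed splits
touching nuclei; by default they merge, and the tests document that
behaviour). The thresholded cell-mask channel is partitioned among nuclei by
a watershed on the distance to the nearest nucleus; each cell's cytoplasm is
its territory minus its nucleus, so masks are disjoint by construction.
Edge-touching cells are excluded (standard high-content practice).
Intensities are arbitrary units: only within-experiment contrasts are
meaningful, and no attempt is made to reproduce absolute published
intensity values, which depend on instrument and staining. A minimum-cell
gate (1000 cells/line in real screens) is configurable and relaxed for
synthetic fixtures.

## Numerical choices and degenerate inputs

- Detection ties at equal filtered response break by (row, column); all
  stages are deterministic given their seeds, and pipeline runs are
  byte-for-byte reproducible.
- Zero-variance t tests are flagged (`note`) with an infinite/zero
  statistic rather than raising; all-equal ANOVA tables return F = 0.
- Degenerate bootstrap distributions (all resamples tied) are flagged and
  still return an estimate.
- Empty detection frames, empty track sets and zero-cell fields are valid
  inputs yielding empty outputs, not errors; genuinely uninterpretable
  inputs (missing calibration, unbalanced ANOVA designs, soma outside the
  process) raise typed errors.

## Problem sizes used in validation

The recovery studies use 5 synthetic lines × 400 tracks per condition
(2000 tracks/group, matching the reported number of analysed cell lines and
a comparable track count per line), rendered as single-plane movies at
0.2 μm/px — detection operates on projections, so extra z-planes add cost
without changing the recovery question. Tracking-fidelity checks use 80
tracks on noiseless movies; fluorescence recovery uses 5 lines × 20 cells ×
2 conditions. Statistical acceptance bands are binomial 95% CIs at the
stated n.

## Known limitations

- The linker has no motion model (no Kalman prediction); it is correct in
  the sparse, slow-per-frame regime it targets and validated only there.
  At realistic organelle densities, crossing trajectories would require
  curation, as in the original semi-automated analysis.
- Mean speeds are computed on projected 2-D coordinates; axial (z) motion
  within the stack is invisible, exactly as in the projection-based
  measurement being modelled.
- The direction chi-square of the original analysis was printed with df = 4,
  which no 2×2 anterograde/retrograde layout yields; since the underlying
  table layout is unknowable, the package provides the general r × c test
  and does not attempt to reproduce that statistic.
- Published mean-speed t statistics appear with two slightly different
  values in different places (3.659 vs 3.663); neither is reproducible
  without the unrounded per-line means, so neither is asserted.
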