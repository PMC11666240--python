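# Methods

## Coordinate frame and data model

All positions are in micrometres with x = mediolateral (ML, + lateral),
y = dorsoventral (DV, + dorsal), z = anteroposterior (AP, + anterior). The
signs are a package convention: the biology fixes the axes but not their
orientation, and only displays (rose plots) are orientation-sensitive.
Masks are 2D label images indexed (row = DV, column = ML); boundary
polylines extracted from them are ordered ventral→dorsal so the first/last
vertices are the ventral-most/dorsal-most points by construction.

A track is a strictly time-ordered list of 3D samples with a cohort label
(`op_cell`, `brain_cell`, `growth_cone`, `ncc`, `other`). Tracks in one
`TrackSet` share a nominal frame interval `dt` (10 min in the imaging
regimes this package emulates); sample times must be integer multiples of
`dt`, and missing multiples are *gaps*. Gaps are never interpolated:
downstream lag statistics skip pairs that span them, because interpolated
positions would systematically deflate short-lag MSD. The Fiji
"Manual Tracking" dialect maps slice s → t = (s−1)·dt and pixels →
micrometres with a user-supplied pixel size; the pixel size of a movie is
deliberately a required parameter with no default, since the export does
not record it. A missing Z column is accepted (z = 0, logged), degrading
the analysis to 2D.

## MSD

For each track, MSD_i(τ) at lag τ = k·dt is the time average of
|r(t+τ) − r(t)|² over all admissible sample pairs; the ensemble curve is
the unweighted mean of MSD_i over tracks that contribute at that lag, with
the total pair count reported per lag so weighted variants can be audited.
This time-averaged-then-ensemble estimator is the standard choice for
short single-particle tracks, where per-track weighting by pair count
would let long tracks dominate. Lags are reported up to a fraction
(default 0.5) of each track's duration — long-lag estimates rest on very
few pairs and are statistically unstable. Analytic anchors used in tests:
MSD(τ) = |v|²τ² for pure drift at velocity v, and slope 6D for isotropic
3D diffusion with coefficient D.

## Tissue drift and its subtraction

The flexure movement of the forebrain displaces OP cells, brain cells and
growth cones together. The drift estimate is intentionally simple: for
every frame interval, the mean 3D step of a reference cohort (typically OP
cell bodies) over the tracks present at both ends of the interval. No
smoothing or fitting is applied — a fitted trajectory would import model
assumptions the data does not need. Intervals with no eligible reference
cell carry a zero step and a warning rather than an interpolated value.

A track is corrected by subtracting the accumulated reference motion,
anchored so its first sample is unchanged:
r′(tₙ) = r(tₙ) − Σ_{m<n} mean_step[m]. By construction, correcting a
cohort against its own drift zeroes the cohort's ensemble mean net
displacement, and growth cones simulated as intrinsic walk + reference
motion return exactly their intrinsic walk.

## Windows, speed, persistence, orientation

Windowed summaries mirror the growth-cone analysis design: closed windows
[t₀ + i·w, t₀ + (i+1)·w] (default emulation: w = 200 min from t₀ = 200 min
over a 1000-min movie, giving 4 windows), with a sample on a shared
boundary belonging to both adjacent windows; a track contributes to a
window only with ≥ 2 samples inside it. Mean speed is in-window path
length over in-window elapsed time with data (gaps excluded from both
numerator and denominator). Persistence is |net displacement| / path
length ∈ [0, 1]: 1 for strictly collinear forward motion, 0 for closed
loops. Orientation is the angle of the *net* (endpoint) displacement
against the DV axis — atan2(Δml, Δdv), so pure dorsal = 0°, pure lateral
(+ML) = +90°, range (−180°, 180°] — not a per-step mean direction; the
per-cell net vector is what a rose plot of track orientations shows.
Tracks with zero net in-plane displacement have no orientation; they are
excluded from circular samples and counted in the log.

## Circular ANOVA

Orientations are modelled as von Mises(μ, κ). The mean direction is the
resultant direction; κ is estimated by inverting A(κ) = I₁(κ)/I₀(κ) = r̄
with bracketed root-finding (Brent, bracket [0, 10⁴]; κ capped with a
warning for numerically degenerate r̄ → 1 samples). Closed-form
approximations are used nowhere as final answers.

The between-group test is a likelihood-ratio ANOVA for equality of mean
directions with a single shared concentration: with Rᵢ the within-group
resultant lengths, R the pooled resultant length, and κ̂ solving
A(κ̂) = (ΣᵢRᵢ)/n, the likelihood ratio at κ̂ reduces to
2κ̂(ΣᵢRᵢ − R), referred to χ² with (groups − 1) degrees of freedom.
Because the χ² approximation of this statistic is anti-conservative at
moderate concentration (empirically, type-I ≈ 0.057 instead of 0.05 at
κ = 2, n = 15/group), the statistic is divided by the standard
concentration correction 1 + 3/(8κ̂) familiar from high-concentration
circular ANOVA; with the correction the measured type-I error is ≈ 0.047
at the same design, and power at a 90° mean-direction separation is
≈ 0.99. Whether the original analyses assumed equal κ per group is not
knowable from a test name alone, so the κ treatment is recorded in the
result's `kappa_treatment` metadata rather than left implicit. No
small-sample or multiple-testing correction is applied; p-values are per
comparison. Rose histograms use equal-width, right-closed bins on
(−π, π], so an angle exactly on an interior edge falls in the bin it
right-closes.

## Morphometry

**Extents.** AP/ML/DV extents are max − min over main-flagged points only.
"Physically separated from the main cluster" is operationalised as
single-linkage connectivity at a threshold (default 15 µm ≈ two cell
diameters): components chained by pairwise distances ≤ threshold form one
cluster; the largest is main, the rest ectopic; a size tie goes to the
component containing the medoid of all points, which makes the rule
deterministic. Manual flags in input files always take precedence —
auto-flagging is opt-in.

**Brain width.** Width at an (AP, DV) level is the ML distance between
the left and right boundary polylines of that AP section, each evaluated
at the DV level by linear interpolation along the polyline; a level
outside a wall's DV span, or crossing walls (negative width), is an
error, not a clamped value.

**Distortion index.** Arc length of the boundary divided by the
*Euclidean* distance between its dorsal-most and ventral-most vertices
("distance between positions" read literally as point-to-point, not a
DV-coordinate difference). The index is ≥ 1 up to polyline sampling
error, equals 1 only for a straight DV segment, is invariant under
translation and ML reflection, and is deliberately *not*
rotation-invariant — the DV axis enters through endpoint selection.
Because the per-z-level pooling of such indices is a reporting choice,
the pipeline computes per-boundary indices and leaves averaging to the
caller.

**Interface thickness.** Stations are placed by arc length along
membrane A every `step_px` pixels (s = step, 2·step, … ≤ region length),
giving ⌊region/step⌋ measurements — 10 for the canonical 1000-px region at
100-px steps. Thickness at a station is the *minimal* distance from the
station point to membrane B (point-to-polyline, robust to membrane
roughness, unlike a normal-projection rule which is ill-defined at
corners), scaled to nanometres. Region means are averaged per embryo with
equal weight per region.

**Mask→boundary tracing.** The interface between two labels is the chain
of pixel edges separating 4-adjacent pixels of the two labels inside the
ROI. The polyline runs through the chain's grid corners and every edge
midpoint, which makes its arc length exactly (number of interface edges) ×
pixel size and invariant under mask translation and 90° rotation. More
than one connected interface component, a closed loop, or a branching
interface is an error instructing the caller to tighten the ROI.

## Synthetic data

Generators are pure functions of (config, seed) — identical inputs give
bit-identical outputs — and their defaults emulate the imaging regimes the
analyses target: dt = 10 min, 101 frames (1000 min), D = 0.05 µm²/min
(measured OP-cell scale MSDs of tens of µm² at 100-min lags), drifts of
0.05–0.3 µm/min. Steps are drift·dt plus AR(1) noise with stationary
per-axis variance 2D·dt and lag-1 correlation `persistence_p`; this
generator parameter is a step-direction correlation and is *not* the
measured persistence statistic (net/path). Coupled cohorts receive one
shared drift series on top of their own motion — the synthetic flexure.
Growth cones are an intrinsic walk plus the accumulated frame-wise mean
motion of a supplied reference cohort, so drift subtraction recovers the
intrinsic walk identically in the noise-free limit and within sampling
error otherwise.

What the generators do **not** emulate: spatial interactions between cells,
tissue elasticity or forces, localisation error, track fragmentation from
mis-linking, anisotropic point-spread along z, or drift that varies across
the field of view. Passing tests therefore demonstrate the correctness of
the estimators under the stated stochastic model, not robustness to every
artefact of real microscopy data.

## Group comparisons

`compare_groups` follows the convention of checking normality first:
Shapiro–Wilk at α = 0.05 per group (n ≥ 3 required; zero-spread groups
cannot pass), unpaired two-tailed t when both groups pass, Mann–Whitney U
otherwise; the choice is recorded and overridable with a logged warning.
For total n ≤ 16 the Mann–Whitney p-value comes from an exhaustive
permutation null, which is exact even with ties (e.g. two fully separated
groups of 4 give p = 2/70 ≈ 0.0286); larger samples use the standard
asymptotic method with tie correction.

## Determinism and problem sizes

Every stochastic computation takes an explicit seed; the pipeline writes
no timestamps into result files, so a config + seed reproduces outputs
byte-for-byte. Default verification scales — 200 tracks × 60 frames for
MSD slope recovery, 2000 replicates for test calibration, 100 random
instances for oracle-equivalence sweeps, 4000-vertex polylines for
quadrature comparisons — were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the tolerances being checked.

## Known limitations

- Drift subtraction assumes the tissue moves rigidly within the field of
  view; a spatially varying flexure would need a position-dependent model.
- The circular ANOVA assumes a common concentration across groups; a
  genotype that changes κ but not μ is invisible to it.
- Orientation of a meandering track is summarised by its endpoint vector;
  two tracks with identical endpoints but different paths get the same
  angle.
- The distortion index is 2D per section; no 3D surface tortuosity is
  computed.
- Cohort membership (e.g. anterior/central/posterior subpopulations) is
  taken as input and never inferred from positions.
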