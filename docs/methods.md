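# Methods

## The quadrangle spike model

A spike silhouette, oriented with the rachis horizontal (stem left, apex
right), is described by two quadrangles sharing the rachis as a base. Each
side's contour is approximated by a piecewise-linear half-width function:
zero at the stem end, rising to height *y1* at breakpoint *x1*, changing to
*y2* at *x1 + x2*, and falling to zero at the apex *L = x1 + x2 + x3*. The
two sides are estimated independently and averaged parameter-by-parameter
into a mirror-symmetric model (`q_x1s = (x_u1 + x_b1)/2`, etc.). Angles of
the quadrangle edges are not used as traits.

Segment areas follow from the unique vertical decomposition of the
half-spike quadrangle with vertices (0,0), (q_x1s, q_y1s),
(q_x1s+q_x2s, q_y2s), (q_L, 0): a basal triangle `q_S1 = q_x1s·q_y1s/2`, a
central trapezoid `q_S2 = q_x2s·(q_y1s+q_y2s)/2` and an apical triangle
`q_S3 = q_x3s·q_y2s/2`. The width index `q_ym = q_S/q_L` estimates half the
spike width; the half-spike area `q_S` estimates half the silhouette area,
so `q_S/c_SA ≈ 0.5` on quadrangle-like shapes. Normalized shares
(`q_x1ns = q_x1s/q_L`, `q_S1S = q_S1/q_S`, …) are dimensionless; when
`q_S = 0` the area shares are reported as missing (0/0 is undefined and a
zero would silently bias downstream statistics).

Units: all lengths mm, areas mm². Manual traits recorded in cm are
multiplied by 10 on ingest. The spike density index
`SDI = (SSC − 1)·100/SL` with SL in mm is spikelets per decimetre (dm⁻¹).

## Image pipeline

**Segmentation.** The imaging protocol fixes a uniform saturated-blue
backdrop, so plant pixels are those whose CIELAB a\*b\*-chroma distance to
the configured background colour exceeds a threshold (default 25; the
backdrop and straw-coloured tissue are ~80 apart, so the threshold is not
delicate). Speckle below 64 px is removed. Awns are separated from the
body by thickness: a morphological opening with a disk of radius 5 px
(default, at ≈0.2 mm/px) removes structures thinner than the disk; the
body is the largest surviving component. Because that opening also shaves
the tapered spike tips and the crests of spikelet-scale boundary bumps, an
awn-free estimate of the plant (opening by the awn core radius, 2 px,
followed by an equal dilation) is built and the body grows back into it by
binary propagation; awns — absent from the awn-free mask — stay out.

**Straightening.** The body's medial axis is the longest path of its
skeleton (double-BFS diameter of the 8-connected skeleton graph), smoothed
by univariate splines in arclength and extended tangentially at both ends
until it exits the silhouette, using a secant direction over the outer 15%
of the axis (endpoint derivatives wobble where the skeleton meets a wide,
rounded apex) with a ±2 px perpendicular snap so the ray can follow a thin
tapering tip. The extension may continue through plant pixels classified
as awn — a tapering tip is indistinguishable from an awn by thickness — but
is capped at 25% of the axis length per end so a stray apex awn cannot
dominate the measured length. Spike length is the arclength of this
(possibly curved) axis, i.e. the digitally straightened length.
Perpendicular half-widths to each side are sampled at 200 positions.
Objects with axis-to-width ratio below 1.5 are flagged as degenerate.

**Quadrangle fitting.** For fixed breakpoints the model is linear in the
two heights, so the sum of squared residuals has a closed-form minimum (a
2×2 solve, heights clipped at zero). The two breakpoints are searched
exhaustively over the profile's own sample positions (subsampled to a
60-candidate budget), ties broken toward the smallest x1 then smallest x2,
followed by Nelder–Mead refinement started from the three best grid pairs
(the SSE surface has local minima between sample positions). The fitter is
deterministic.

**Contour descriptors.** Area is the body pixel count times scale²; the
perimeter uses the Crofton estimator, which is unbiased on rasterized
smooth boundaries where the marching-squares polygon overshoots by its
staircase (~5% on a disk). The convex hull is taken over the
marching-squares contour points; the major axis for roundness is the
maximum Feret diameter (largest pairwise hull-vertex distance), measured
on the mask, not on the fitted model. Circularity, roundness, solidity and
rugosity follow the standard image-morphometry definitions (all equal 1
for a disk); these exact formulas are this package's choice — the trait
names are standard but not uniquely defined in the literature.

## Synthetic data

The renderer draws the mirrored quadrangle silhouette, optionally adding a
sinusoidal boundary term `amp·(1 − cos(2πnt/L))/2` per side (emulating
spikelet-scale undulation; discrete spikelet rendering is out of scope),
bending the centerline along a circular arc of given curvature (arclength
preserved), and attaching thin awn strokes angled toward the apex. It
returns exact body/awn masks and the generative arclength. Rendering is
deterministic given the seed.

The population sampler draws the five model parameters, awn area and
manual traits from truncated-at-zero normals around per-class means. Its
default parameterization is the published per-species summary (eight
classes: seven hexaploid wheat species and one amphidiploid; SDs
reconstructed from standard errors as SE·√n). Trait-only mode derives the
full 31-trait table analytically from each sampled model (contour traits
from the model polygon, with a fixed rugosity factor of 1.12 on the
perimeter representing boundary undulation); this is the fast path used
for statistics and classification tests. For rendering experiments the
sampler floors half-width draws at 1.5 mm — the thinnest species in the
study averages about 2 mm, and a sub-millimetre silhouette cannot be
resolved at the working scale.

What the synthetic data does *not* emulate: lighting gradients, shadow,
colour texture, glume detail, overlapping or branched spikes, and
photographic noise. Passing recovery tests therefore demonstrates the
geometry of the pipeline (segmentation topology, straightening, fitting),
not robustness to real-world photographic artefacts.

## Statistics

Group tests per trait: one-factor ANOVA, Brown–Forsythe (Levene from
medians) and Kruskal–Wallis with tie correction; listwise deletion within
each test, groups under 2 observations excluded with a warning. Trait
similarity uses Pearson correlations (pairwise-complete) and UPGMA
(average linkage) on distance `d = 1 − r`; `1 − |r|` is available as a
switch. Two-accession comparisons use the pooled-variance t test by
default — the convention of the desktop statistics software these
comparisons are traditionally run in, and the variant that reproduces the
published two-accession p-values from their printed summaries — with Welch
as an option; the variance F test is two-sided (`p = 2·min(tails)`, capped
at 1); Mann–Whitney is exact for small tie-free samples and a
tie-corrected normal approximation otherwise, and is unavailable in
summary-statistics mode. No multiple-testing correction is applied by
default.

## Classification

Box–Cox lambdas are estimated per trait by profile maximum likelihood on
the whole sample (not per class); traits with any non-positive value are
shifted by `1 − min` first; constant traits pass through flagged. LDA
standardizes traits, then fits Fisher discriminants with the within-class
covariance shrunk toward its trace-scaled diagonal (intensity 1e−4) so the
31-trait scatter stays invertible for small classes; standardization makes
the shrinkage — and hence accuracies and scores — invariant to affine
rescaling of any trait. Accuracy is the percentage of correctly classified
spikes under resubstitution (default) or leave-one-out; both are exposed
because published accuracy grids of this kind rarely state the protocol.
The biplot reports per-plant scores on the first two axes, trait loadings,
and each class's convex hull.

## Validation experiments and problem sizes

The acceptance experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 1000 random models for the geometric
identities (tolerance 1e−9 relative); 50 clean and 25 bump-and-bend
renders for parameter recovery; 20 noisy profiles of 36 samples for the
fitter-vs-exhaustive-search comparison (ratio ≤ 1.01); 500 null replicates
of 3 groups × 30 for test calibration (band 0.03–0.07 at α = 0.05); and
25 plants per class for the LDA ordering.

Parameter recovery is summarized by the **median** relative error. The
quadrangle parameterization is not identifiable for every shape: when two
adjacent segments are nearly collinear, distinct parameter vectors
describe the same silhouette and the least-squares optimum legitimately
lands on any of them, so individual draws can show large parameter error
at equal or better residual. Median clean-render errors are about 1%.

Null-simulation groups of 30 keep Brown–Forsythe near its nominal level:
the median-centred Levene test is conservative for small groups (true
level ≈ 3–4.5% at α = 5%, and *more* groups make it worse), so a
500-replicate estimate of its rejection rate can occasionally fall below
the 0.03 band edge by sampling noise alone.

## Limitations

- Branched spikes and multi-spike images are out of scope; the pipeline
  assumes one connected spike body per image.
- Spikelet counting and glume characteristics are not estimated.
- The breakpoint fit is least-squares on the width profile; no uncertainty
  is attached to the fitted parameters.
- Digital length estimates measure to the outermost silhouette pixels and
  therefore tend to exceed ruler measurements of the same spike.
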