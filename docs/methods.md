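# Methods

This note documents the models, algorithms and numerical choices behind
`taproot`, and what the synthetic validation does and does not show.

## Image model and coordinate conventions

A root is represented as a boolean raster (`RootMask`), oriented
shoulder-up: row 0 is nearest the crown, the tip points down. All point
arrays are `(row, col)` with the origin at the top-left; physical scale
is a single `mm_per_px` factor, conventionally 100 mm divided by the
pixel length of a scale bar encoded in the filename
(`{genotype}_{rootid}_{barpx}.png`). Masks produced from photographs go
through grayscale conversion, an edge-preserving bilateral filter
(spatial σ 3 px, range σ 0.1 in normalised luminance), a binary threshold
(Otsu by default, fixed value optional, inverted for light backgrounds),
selection of the largest connected component above 64 px, and hole
filling. Hole filling is needed because specular highlights on glossy
roots otherwise punch holes that corrupt the distance transform. Two
surviving components within 10% of each other in area abort with an
error rather than guessing which is the root.

## Contours and curvature

Contours are extracted at the 0.5 iso-level with sub-pixel precision,
resampled to unit point density (one point per boundary pixel), smoothed
with a wrapped Gaussian (σ 2 points), and oriented to positive shoelace
area. Unit density makes "the 50 contour points around the crown" cover
a comparable physical extent across images of similar resolution; the
choice is a declared convention, and region windows are centred on the
crown centre and on the bottom-most point respectively.

Curvature at a point is computed from a local cubic least-squares fit to
x(t) and y(t) over a centred window of 2·7+1 points, with t the
chord-length parameter, evaluated as K = (x′y″ − y′x″)/((x′)²+(y′)²)^{3/2}.
With the enforced orientation, K is positive where the boundary is
convex (bending toward the root interior). The estimator is exact for
lines, and on circles of radius R its relative bias scales like
(window/R)²: 0.16% at R = 50 px, 0.04% at R = 100 px. Duplicate
consecutive points raise an error rather than producing NaNs.

The tip is the curvature argmax found iteratively: starting from a
segment spanning half the contour centred on the bottom-most point, the
segment is re-centred on the argmax and halved until one fitting window
remains. Ties go to the point farthest from the shoulder row. A
`low_confidence` flag marks shapes with no distinguished tip; it fires
when the maximum curvature is within a factor of two of the segment
median. (A tighter margin would be appropriate for analytic curves, but
rasterisation alone spreads K by tens of percent — a perfect disk shows
a max/median ratio near 1.6, a genuine tip a ratio above 10.)

## Midline, widths, straightening

The midline is traced from the tip by walking the ridge of the
Euclidean distance transform smoothed with a Gaussian (σ 3 px,
configurable). Each 1 px step moves in whichever of 13 directions within
a 120° forward cone maximises the smoothed field while staying inside
the mask, with two regularisers: a small straight-ahead preference
(0.02 px equivalent) that is decisive only where the field is flat —
inside a thin residual taproot the ridge signal is of order 10⁻³ px and
an unregularised greedy walk can cycle — and a dead-end recovery that
searches the full circle when no in-cone candidate is inside the mask.
The walk ends at the shoulder row and the terminal point is forced to
the mid-width of the shoulder row. Two post-passes follow: the path is
smoothed (Gaussian σ 3 steps) and resampled to unit arc-length steps, so
zigzag jitter does not inflate arc length; and the start is rectified by
estimating the local axis direction just above the tip region and
marching it back to the boundary. The rectification matters for blunt
roots, where the curvature tip is a corner of the bottom cap and a walk
started there would otherwise add up to half a cap-width of spurious
length.

Widths are sampled at every midline step along the normal to the local
tangent (centred difference over ±5 steps), ray-marching both ways in
0.25 px steps with bilinear interpolation and refining the 0.5-level
crossing linearly. Normal sampling rather than row-wise sampling is what
keeps widths honest on bent roots; the suite checks that a 30 px bend
does not inflate widths beyond 3% of the generating width function. A
ray that reaches the raster edge while still inside the mask raises an
error (the mask must not touch the border). Straightening renders row k
as a centred run of round(width_k) pixels, shoulder at top; area is
conserved within 2% on bent roots.

Width profiles are stored shoulder-first (index 0 at the crown), which
keeps straightening (row k = width k), quantile widths ("measured from
the shoulder") and the de-tip convention (`cut_index` = number of body
rows; a root with no residual tip has its cut at the profile end)
mutually consistent.

## De-tipping

The residual taproot is removed by a random-forest classifier that
scores every candidate cut index of a profile from scale-free features:
normalised width at and just before the candidate, tail mean and max
beyond it, tail length fraction, and a local width gradient. Training
examples are synthetic width profiles with exact cut labels; indices
within a small tolerance of the true cut are positives and negatives are
subsampled outside a guard band (features within a few pixels of the cut
are nearly identical to the positives and would only dilute the
classes). Prediction takes the highest-scoring index, ties resolved
toward keeping more of the root. The model is seeded and serialisable;
identical data and seed give identical predictions. De-tipping an
already de-tipped profile is a no-op, and the raw widths are always
retained alongside the cut.

## Traits

From the de-tipped profile and its straightened mask: length (body rows
× mm/px), maximum width, widths at the deciles (row floor(q·(n−1)) from
the shoulder), aspect ratio, root size (foreground area), tip angle (the
interior angle at the tip between segments to the left and right
boundary points 10% of the length above it), and shoulder hull area
(background area within the bounding box of the top 10% of rows — zero
for a square crown). Validation utilities include the RMSE about y = x
used to compare image and hand measurements, and the least significant
difference t(1−α/2, df)·√(2·MS_error/n) with the two-sided t quantile.

## Shape spaces

Root fill is the first principal component of normalised width profiles:
each de-tipped profile is linearly resampled to 1000 points and divided
by its maximum width, so all roots have unit length and unit maximum
width; PCA is on the covariance (inputs share a common scale). PCA
operates on the width vectors, not on (x, y) boundary coordinates.
Curvature shape spaces are PCAs of the 50-point K vectors of the crown
and tip regions. Eigenvector signs are fixed deterministically so scores
are comparable across runs: contour PC1 is oriented so a higher score
means a more tapered root (smaller area under the normalised profile),
curvature PC1 correlates positively with summed curvature, and every
other component has its largest-magnitude loading positive. On a
noise-free family varying only the taper exponent, PC1 carries ≥ 98% of
the variance and is strictly monotone in the exponent — the parameter-
recovery property that stands in for variance-explained figures which
would require a large field population. The six-trait market-class
matrix (length, max width, root fill, tip and shoulder curvature PC1,
aspect ratio) is z-standardised per column (zero-variance columns are
dropped with a warning) before PCA; per-genotype summaries use plain
means, a deliberate simplification of replicated-trial score modelling.

## Synthetic roots

The generator lays an analytic width function along a parametrised
midline and rasterises it, recording the exact length, width function,
midline and de-tip index. The width family is a plateau–power mixture

    w(s) = W·[(1 − t) + t·(1 − s)^e],   t = 1 − tip_bluntness,

with s the arc-length fraction from crown to tip: e = 0 or
tip_bluntness = 1 gives a rectangle; tip_bluntness = 0 a fully tapered
root. Crown corners can be rounded by a circular arc
(shoulder_radius_frac of the half-width), bends are a lateral cosine
displacement (zero slope at the crown, so the cap is horizontal as for a
photographed root whose crown abuts the top of the frame), and a
residual taproot is a ≤ 5 px spike tapering to 1 px appended past the
true tip. Rasterisation clamps body width at 3 px (thinner analytic
tails are not representable as a connected raster) and rejects
parameters whose analytic width is sub-floor over more than a quarter of
the body. Straight roots are rendered row-wise exactly (a rectangle has
exactly L·W pixels); bent roots are painted densely along normals, with
the segment endpoints pulled half a pixel short of the analytic
half-width so the rasterised edge lands on it on average (area within
~0.2% of the analytic integral).

The validation sweep spans lengths 400–900 px, widths 60–140 px, taper
exponents 0.3–3, shoulder rounding 0–0.8, tip bluntness 0–1, bends up to
30 px, and residual tips of 30–80 px on half the roots. Two realism
constraints are built in: pointed roots (bluntness < 0.1) cap the taper
exponent at 1.2 so the analytic width stays above the floor, and
residual tips only attach to bodies with bluntness ≥ 0.15 — a storage
root already tapered to spike width has no physical body/tail boundary,
so a cut label there would be meaningless. Against this sweep the
pipeline keeps measured length and maximum width within 2% of truth,
conserves straightened area within 2%, and locates the de-tip point with
a median error under 5 px per 1000 px of root length (200 roots,
~25 s on one core — the problem size is chosen so the whole suite runs
in well under a minute per criterion).

What the generator does not emulate: photographic texture and lighting,
lateral-root hairs, forked or branched roots (excluded by the platform's
single-root assumption), soil occlusion, and perspective distortion.
Passing the synthetic sweep therefore demonstrates the geometry of the
measurement chain, not robustness to segmentation artefacts in field
images.

## Half-diallel analysis

Phenotypes arrive as one record per root (`parent_i, parent_j, rep,
root_id, value`, i < j, no selfs or reciprocals). Roots are aggregated
to plot means first — this makes r the number of replicate plots and
tolerates unequal roots per plot — and the fixed-effects Method IV model
is fitted to cross means with Σg = 0: the balanced-design closed form
ĝ_i = (p·T_i − 2·T)/(p(p−2)), s_ij as residuals. The suite verifies the
fit coincides with a brute-force least-squares projection to 1e-9 on
integer toy diallels for p ∈ {4, 5, 6}. Sums of squares use df p−1 and
p(p−3)/2, and mean squares are reported on the entry-mean (cross-mean)
basis, the scale on which the expected-mean-square equations are
written, so V_GCA = (MS_GCA − MS_SCA)/(p−2) and V_SCA = MS_SCA − Vε with
Vε the plot-mean error MS divided by r. Heritability denominators use
Vε/r — note Vε is already entry-mean based, so the error enters the
denominators as σ²_plot/r²; this is the convention under which the
published variance-component table is internally consistent, and the
package follows it exactly. The per-root residual variance is reported
separately as `v_eps_root` and is the quantity that recovers a simulated
σ²_ε. Negative variance-component estimates are reported as-is with a
warning flag; truncation would bias the parameter-recovery checks.
Heritabilities are returned raw and clamped to [0, 1] only in the
CSV report. A single user-supplied inbreeding coefficient F (default 1)
covers mixed parentage.

Simulation-based validation draws g ~ N(0, σ²_GCA), symmetric
s ~ N(0, σ²_SCA) and per-root ε ~ N(0, σ²_ε); with p = 8, r = 2 and 15
roots per plot, the mean estimates over 200 simulated trials recover
(25, 5, 50) within 15% / 25% / 10%. Estimates from a single trial are
noisy — the GCA component has a sampling CV of roughly √(2/(p−1)) ≈ 50%
— which is inherent to an 8-parent design, not to the estimator.

## Known limitations

- The pipeline assumes one non-branching root per image, shoulder-up.
- "50 contour points" is resolution-dependent; images of very different
  resolutions should be rescaled before curvature regions are compared.
- The de-tip model is only as good as the profiles it was trained on;
  retrain on measured profiles when the acquisition setup changes.
- Method IV here is fixed-effects and single-environment: no reciprocal
  or maternal effects, no G×E partitioning, no REML for unbalanced data.
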