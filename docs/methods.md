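# Methods

This note records the models, numerical choices and known limitations of
`catmetric`, in the order data flows through the package.

## Colour coordinates and CIE formulas

All conversions fix the sRGB standard's defaults: the IEC nonlinear
transfer function, D65 white, 2° observer.  `skimage.color` performs the
sRGB↔CIELAB conversions and evaluates CIE76 (Euclidean in CIELAB), CIE94
and CIEDE2000; the test suite pins CIEDE2000 against the published
verification pairs and the conversion chain against an independently
hand-coded reference.  The sRGB unit cube is used throughout as a
convenient approximation of the solid of surface colours; no gamut
mapping or chromatic adaptation beyond the fixed D65 pipeline is
attempted.

**Tensorizing a distance formula.**  To compare non-Euclidean formulas
with Riemannian fields, a 3×3 tensor is fitted at each colour from 13
probe pairs aligned with the axes, face diagonals and body diagonals of
the RGB frame.  Each pair spans Δ = 0.1 sRGB units, the two points
sitting Δ/2 either side of the location — the same half-offset
convention as the finite differences used for the categorical tensor.
The choice matters: CIEDE2000 is not additive along paths, so the
measured locus/axis length ratio depends on the probe scale (2.8 at
separation Δ, 3.1 at Δ/2, 3.7 in the infinitesimal limit).  The 6 free
components solve the 13 equations vᵀTv = d² in least squares; the result
is clipped to the PSD cone.  Near cube faces the probe set is translated
inward so both ends of every pair stay in gamut.  CIE94's fitted
quadratic is genuinely semidefinite at a small set of near-neutral
colours; the distortion machinery floors such eigenvalues at 10⁻⁸ of the
local leading eigenvalue and rejects only meaningfully indefinite
tensors.

## Naming tables and cleaning

Tables are long-format UTF-8 CSV/TSV with header and columns
`subject, r, g, b, name` (optional `chip_id`, `presentation_index`,
`is_repeat`).  Cleaning, in order: lower-case and whitespace-normalize
names; apply the spelling-variant map; drop flagged repeat presentations
(by default records with `presentation_index == 18`, the repeat slot of
the 20-presentation session design); drop names whose every use comes
from a single subject — one subject using a name three times still makes
it idiosyncratic.  Cleaning is idempotent and fully accounted for in the
report (dropped + retained = input).  Entropies are in bits; the
conditional entropy uses the count-weighted per-chip entropies so that
H(name|chip) = H(name) − I(chip;name) holds exactly on the empirical
joint.  Inter-subject agreement uses the unbiased per-chip
pair-coincidence statistic Σ r(r−1)/(R(R−1)); intra-subject agreement is
the fraction of repeat pairs given the same name, computed only when
repeat metadata exists.  Per-chip statistics are computed after
cleaning.

## The response model and its fitting

Parameters per name: peak rate k ∈ (0,1], CIELAB peak location μ, SPD
covariance Σ with eigenvalues ≥ 3.0² CIELAB², sharpness α ∈ [0.5, 3.0],
global rate g; a shared lapse rate γ = 0.01.  The α ceiling is the
model's stated maximum; the 0.5 floor guards against degenerate
heavy-tail shapes.  μ and Σ live in CIELAB; the metric machinery samples
in sRGB and converts at query time.

The penalized objective L − λ(k|Σ|)^0.12 (λ = 100, cross-validatable) is
maximized with L-BFGS in an unconstrained parameterization: logistic
boxes for k and α, location scaled by 25 CIELAB units, and Σ = LLᵀ + 9I
via a log-Cholesky factor — the additive floor enforces the eigenvalue
constraint exactly and smoothly (a projected-step scheme would need an
optimizer hook scipy does not expose).  Five restarts: the first from
the response-weighted mean/covariance of the name's chips, the rest
jittered by a stream derived from the seed and a stable hash of the
name, so per-name fits are independent of vocabulary and execution
order.  Chip order changes only float summation order; optima agree to
optimizer tolerance, not bit-exactly.

Two properties of the penalty are worth knowing.  First, it is designed
to shrink k|Σ| — rare names get tighter, lower response functions, which
is what regularizes generalization.  Second, at λ = 100 on desk-scale
synthetic data the optimum often sits at the α floor with k near 1 and
|Σ| small: a heavy-tailed shape that imitates a broad Gaussian while
evading the determinant penalty.  Location recovery is unaffected, but
k and Σ individually are biased; the recovery tests therefore assert
k/Σ recovery at λ = 0 and only the shrinkage direction at λ = 100.

Fitting targets the per-name rates Q, while datasets are generated from
the normalized field P = Q/ΣQ.  Where the generating categories tile the
space (ΣQ well above the lapse floor everywhere) the two nearly agree
and locations are recovered to a few CIELAB units (the dataset-level
test freezes a 10-unit median threshold from a pilot run); where
coverage gaps exist, normalization amplifies the lapse into a large
stimulus-independent background and Q-fitting genuinely cannot recover
the generating k/Σ.  The exact-model harness `binomial_name_table`
(r ~ Binomial(n, Q) per chip) sidesteps normalization and measures pure
estimator error.  Model comparison uses full multinomial likelihoods
(coefficient included; it cancels in deviances) and the parameter-count
formulas V−1 / 12V / C(V−1); deviances are judged against parameter
differences per the AIC rule of thumb.

## Metric computation

The fitted distributions are blurred *after* normalization (blur each
P_n, renormalize — for the alternative, blur Q_n first and normalize
afterwards, compose the field accordingly); the comb filter is the 3-D
outer product of the 5-point dirac comb with spacing Δ/3 and weights
[1 3 4 3 1]/12, 1-D spread 0.36Δ.  Blur sample points outside the cube
are clamped to it (replicate boundary).  Derivatives of the
square-rooted field use central differences with half-step Δ/2 per side;
near a face the step is clamped to the available room (one-sided exactly
on the face) with the normalization adjusted to the realized span — a
symmetric-only shortening would degenerate to a zero step on the face
itself.  Γ = DᵀD is symmetric PSD by construction.

The grid stores Γ at 21³ nodes (spacing Δ/2 = 0.05, R index fastest in
the serialized text format); queries use separable piecewise-quadratic
Lagrange interpolation on the 3³ stencil centred at the nearest node,
PSD-clipped after interpolation.  Node queries reproduce stored tensors
exactly; against direct computation at random interior points the median
relative Frobenius error is ~0.5% for the demo model (tolerance 5%).

## Geometry analysis

Path lengths integrate √(v̇ᵀΓv̇) by the trapezoid rule at a configurable
density (default 200 samples per unit sRGB length; the suite checks
<0.5% change on doubling).  Mesh areas restrict the centroid tensor to
each triangle's plane and weight the Euclidean area by √det; cube
volumes use the midpoint rule on √det Γ.  The cube capacity integrates
restricted tensors over each of the six faces for the boundary term and
reports both the corrected and uncorrected counts — the boundary
correction assumes consistently low boundary curvature and
under-estimates otherwise.

Global distortion between two fields is the |C|-weighted standard
deviation of ½log₂(vᵀAv/vᵀBv) over 10⁵ Monte Carlo samples (z uniform in
the cube, v ~ N(0, C⁻¹)), with C the SPD geometric mean A#B, which makes
the comparison symmetric and scale-aware; C = A when A = B.  The
literal squared form (A#B)² is available as a config switch but changes
the weighting scale.  The normal-range conversion 2^(±1.96·sd) assumes
normally distributed local distortions.

1-D embeddings are arc-length maps (closed paths become circles of
radius L/2π, first vertex at angle 0, counter-clockwise — an arbitrary
but fixed convention).  The full colour surface spans the colour locus
with a disk mesh (centre + concentric rings) whose interior vertices
solve the graph Laplace equation over the triangle-edge adjacency;
residuals are at solver precision.  Sphere embeddings place mesh
vertices on a sphere of optimized radius minimizing the length-weighted
mean square of log₂(great-circle edge length / categorical edge length),
with an analytic gradient; the initial layout is a spherical cap built
from a planar PCA of the mesh, and restarts jitter it.  The mean-square
(rather than variance) objective is what identifies the radius.  On a
synthetic pullback metric of a known sphere the radius is recovered
within 2% with 95% of edge ratios inside [0.98, 1.02]; a near-flat patch
is correctly pushed to a large radius, so the radius is only meaningful
when the patch subtends appreciable curvature.

## Synthetic data

The demo model's 13 categories sit at familiar anchor colours with
isotropic CIELAB covariances chosen so the categories tile the cube (as
real naming data does — every colour has names); global rates follow the
rank^−1.4 law.  Datasets draw 31 responses per chip (i.i.d. from the
normalized field) over a jittered 8×8×8 chip grid, then assign subjects
in blocks of 20 presentations with the 18th a repeat of the 3rd.  The
generator reproduces the qualitative statistics of crowdsourced naming
data (heavy-tailed rates, per-chip entropies, agreement rates) but not
display-calibration noise, subject-level vocabularies, or the long tail
of hundreds of rare names — so passing tests demonstrate correctness of
the machinery, not that a 13-name model matches human naming.  Toy 1-D
specs are Gaussian bumps (optionally hard indicators for exactly
disjoint categories); their capacities and metric-variability orderings
mirror the qualitative behaviour of chromatic-vs-tonal category systems,
and the quantitative values are properties of these parameterized
families, not of any published figure.

## Known limitations

- Everything is computed on the sRGB cube; the true body colour solid is
  only approximated.
- CIE94/CIEDE2000 are not metrics (no triangle inequality), so their
  tensorizations are probe-scale-dependent; we fix separation Δ = 0.1.
- The per-name/normalize split means the fitted P is not the maximum-
  likelihood multinomial field; joint optimization is deliberately out
  of scope.
- The published parameter-count formula 12·N_names is implemented as
  printed even though 12 × 804 = 9,648, not the 9,720 printed beside it;
  the table's own numbers are internally inconsistent and the formula is
  treated as authoritative.
- In the univariate-normal worked example the distance from ⟨0,1⟩ to
  ⟨0,1+ε/2⟩ is ε/(2√2) under the Fisher tensor, not equal to the ε/2 of
  a mean shift; the tensor is treated as authoritative.
- Geodesics are not computed: all measurements are of specified paths,
  surfaces and volumes.
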