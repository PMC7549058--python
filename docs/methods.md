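# Methods

This note documents the models, numerical choices and limitations behind
`impressionface`.  The package implements a two-study computation: a
*modeling* study relating facial shape (72 2D landmarks per face) to a
two-dimensional impression space extracted from 18 adjective ratings, and a
*validation* study testing whether shape transformations along those two
dimensions move the impressions that load on them.

## Impression space

Ratings are faces × items × raters on a 0–100 visual analog scale.
Reliability per item is Cronbach's α with raters as the k scale items and
faces as cases (sample variances, n−1 denominators).  Mean ratings over
raters enter a **correlation-matrix PCA**: items are z-scored across faces
and the item correlation matrix is eigendecomposed.  Loadings are unit
eigenvectors (not √eigenvalue-scaled), variance explained is
eigenvalue/n_items, and scores are the z-matrix projected on the loadings.
Standardized PCA makes the analysis invariant to per-item scale and produces
near-uniform loading magnitudes (≈1/√18 ≈ 0.236 for an equicorrelated block),
the scale on which published loading tables of this design are printed.
Eigenvector signs are arbitrary; they are fixed by anchor items ("lively"
positive on PC1 = valence, "dignified" positive on PC2 = dominance).  When
items are unnamed, components are oriented by positive loading sum instead.

No factor rotation or formal component-count selection is performed; two
components are taken by design.

## Geometric morphometrics

The landmark scheme declares 36 fixed landmarks and 36 semilandmarks on five
curves (face outline, two brows, upper and lower lip) plus two nose-side
curves, with bilateral pairing and a midline set.  The processing order is
slide → symmetrize → GPA → PCA:

* **GPA.** Each configuration is centered and scaled to unit centroid size,
  then iteratively rotated to the running consensus (SVD-based orthogonal
  Procrustes restricted to det +1; reflections are excluded because bilateral
  asymmetry is handled explicitly).  The consensus is renormalized to unit
  centroid size each round; iteration stops when it moves < 1e-10 in
  Frobenius norm (max 100 rounds; non-convergence is flagged, not fatal).
* **Bending energy.** The TPS bending-energy matrix of a reference is the
  upper-left K×K block of L⁻¹ with kernel U(r) = r² log r²; it is
  symmetrized numerically and annihilates affine displacement fields.
* **Sliding.** Per outer iteration (default 3): tangent directions at each
  semilandmark are central differences of curve neighbors (one-sided at curve
  ends); sliding amounts for all semilandmarks of a configuration are solved
  jointly by least squares to minimize the TPS bending energy of the
  configuration relative to the current consensus; GPA is re-run after each
  pass.  Sliding minimizes bending energy against the *consensus* (the
  default behavior of the standard relative-warps tools) rather than minimum
  Procrustes distance; because the consensus moves between passes, total
  bending energy is monotone only up to a small tolerance, which is how the
  tests assert it.
* **Symmetrization.** Each configuration is averaged with its relabeled
  reflection (x negated about the centroid's vertical axis, labels swapped
  through the bilateral pairing, mirror fitted back by a two-shape rotation).
  The fit-and-average step is iterated to a fixed point and finished with an
  exact reflect-relabel projection, so outputs satisfy
  reflect-relabel(out) = out to machine precision and the operation is
  idempotent.
* **Shape PCA.** Covariance PCA (SVD) of the flattened aligned coordinates;
  no tangent-space projection is applied first — at facial shape variance
  scales (Procrustes distances ≪ 0.1) the difference is far below test
  tolerances.  Components are retained as the smallest leading set reaching
  95% cumulative variance.

## Shape–impression association

The association test is a distance-based multivariate regression: Euclidean
distances among retained shape-PC score rows are Gower-centered
(G = −½·J·D²·J, which for Euclidean distances equals the double-centered Gram
matrix), sums of squares are partitioned sequentially (Type I) over
predictors via hat matrices of nested designs, and pseudo-F per term is
compared against the distribution obtained by permuting response rows
(raw-response permutation, the named tool's default; p uses the
(count+1)/(n_perm+1) estimator and is never 0).  Covariate control (e.g.
age) is sequential entry: the covariate goes first, the impression terms
after.  For a univariate response the pseudo-F reduces exactly to the
classical regression F, which the tests exploit as an oracle, along with
exhaustive enumeration at n = 5.  Permutations are evaluated vectorized in
chunks of 256; an exhaustive mode enumerates all n! permutations.

Shape-regression fields are per-coordinate simple linear regressions of
aligned coordinates on one impression score: `field` is the slope array
(displacement per score unit), `intercept_shape` the fitted shape at the
mean score, `predictor_sd` the score's sample SD, so `k·SD` transforms are
`mean + k·predictor_sd·field`.

## Image warping and stimuli

Warps are exact TPS interpolants (affine part + U(r) = r² log r² kernel,
zero regularization) fitted backward from target to source landmarks; output
pixels sample the source bilinearly (`scipy.ndimage.map_coordinates`,
order 1), out-of-range samples take the background (corner) value.  Landmark
files use the TPS convention (origin bottom-left, y up); raster code converts
at the warp boundary only, with **pixel centers at half-integers** — the same
convention as the schematic renderer, which makes warping and rendering
jointly mirror-covariant.  The average face warps every image onto the GPA
mean configuration mapped into pixel space via the mean centroid size and
mean centroid position, then averages pixelwise.  The 3×3 stimulus grid
applies the valence and dominance fields additively at −3/0/+3 SD; every
cell warps once from the average (warps are never composed), and the (0,0)
cell is the average image itself.

The ±3 SD scale is the SD of the impression PC scores across the sample of
faces, the only spread available to the pipeline.

## Validation statistics

Each adjective's stimulus ratings are fitted with
`score ~ V + D + (V + D | rater)` by REML (statsmodels `MixedLM` stands
behind this module's surface).  V and D enter as raw SD units (−3, 0, +3),
treated as continuous.  Fixed-slope p-values are Wald z tests against the
normal reference — the small-sample df correction is deliberately out of
scope and per-item significance stars are not a target; Bonferroni correction
multiplies p by the number of items (18), separately per dimension.  Singular
random-effects fits are flagged (`boundary=True`) with estimates still
returned.  The loadings-versus-slopes correlation reports Pearson r, t with
df = n−2, a two-sided p, and a 95% Fisher-z interval.

Two published 18-item reference tables (impression-PCA loadings;
validation-study mixed-model coefficients) ship with the package, transcribed
at their printed 2-decimal precision, so the four correlations between them
can be recomputed without any raw data.  At that rounding the recomputed
values are r = .912 (t = 8.91), r = .813 (t = 5.58), r = −.082, r = .159.

## Synthetic data: what it emulates and what it does not

The generator substitutes for a photograph corpus that is not public.

* **Template.** A bilaterally symmetric 72-point schematic face (36 fixed,
  36 semilandmarks), built from one side plus midline and mirrored, so
  symmetry and pairing hold by construction; normalized to centroid 0, size 1.
* **Shape model.** Low-rank: configurations are
  `base + Σ_d z_d·sd_d·field_d + ε` with standard-normal latents and iid
  landmark noise.  The valence and dominance fields are smooth Gaussian-bump
  fields (smile-like and stern-like patterns); nuisance variation comprises
  two structured fields (elongation, vertical feature placement) and eleven
  Gaussian-process-smoothed random symmetric fields.  All fields are
  projected off the directions the pipeline cannot recover — the similarity
  group (removed by GPA) and, for each semilandmark tangent t_j, the
  direction E·t_j (the first-order fixed-point condition of bending-energy
  sliding) — then orthonormalized.  Planting signal in those directions
  would be unrecoverable *by definition* of superimposition and sliding, so
  excluding them keeps the generating model and the recovered shape space in
  the same coordinates.
* **Variance budget.** Valence 8% of total shape variance (an association
  strength of R² ≈ 0.08, the regime of interest), dominance 7.5% (slightly
  weaker; both sized so per-landmark regression recovers the fields with
  cosine similarity > 0.9 at 102 faces — a power analysis shows weaker
  planted fields are not reliably recoverable at this sample size), nuisance
  on a gently decaying spectrum (9% down to 3.8%) totaling 83%, landmark
  noise 1.5% (well under a quarter of the planted signal).  A flat-ish
  many-mode spectrum reflects a demographically narrow, pose-controlled
  sample; it also implies a double-digit count of shape PCs to reach 95%
  variance (14 in expectation).  The dataset's ground-truth count is
  computed from the realized latent draws (singular values of the realized
  low-rank signal) plus the surviving noise fraction — sliding removes the
  curve-tangent share of isotropic noise at semilandmarks and symmetrization
  halves the rest.
* **Ratings.** `clip(intercept_i + loadings_i·(V,D) + b_rater + ε, 0, 100)`;
  planted loadings have a strong near-uniform valence column and a weaker
  mixed-sign dominance column (orthogonalized so both are identifiable);
  intercepts are mid-scale so clipping is rare.  Rater SD 6 and residual
  SD 8 give α ≈ 0.9 at 24 raters, matching the high reliability regime of
  adjective ratings.  Validation-stage ratings respond linearly to the
  stimulus's nominal (V, D) levels with the same item loadings, plus random
  rater intercepts and slopes.
* **Renders.** Grayscale schematic faces drawn by analytic pixel-coverage of
  the curve polylines, eye outlines and pupils: deterministic, exactly
  mirror-symmetric for symmetric input, translation-equivariant for integer
  shifts.

What passing tests on this generator do **not** show: anything about texture,
color, hair, lighting or photographic artifacts; about landmark digitization
error structure in real photographs (the generator's noise is iid); or about
the true effect sizes in any real population — the planted shares fix the
*regime*, not an empirical claim.

## Numerical choices and degenerate inputs

Seeds are explicit everywhere; a pipeline run fans one global seed into
per-stage child seeds at fixed offsets, so stages rerun standalone
reproducibly.  GPA tolerance 1e-10/100 iterations; sliding systems solved by
`lstsq`; TPS systems by dense `solve` with an explicit coincident-point
check; hat matrices by rank-revealing QR with a relative threshold of 1e-10
(collinear designs are rejected).  Degenerate inputs raise informative
errors: zero centroid size, zero-length curve tangents, constant rating
items, constant regression scores, non-involutive pairings, coincident TPS
landmarks, out-of-range or missing rating cells (the first offending cell is
named).

Problem sizes used by the test suite: the full 102-face, 24-rater study for
end-to-end recovery checks (permutation tests at 199–999 permutations there;
the 9,999 default is exercised by the acceptance script), 2,000 simulations
at n = 24 for the type-I calibration, and 30–40-face studies for pipeline
smoke tests.

## Known limitations

* 2D landmarks only; no 3D morphometrics, no relative-warp weighting
  (α ≠ 0), no allometry regression.
* Sequential (Type I) sums of squares only; no strata/blocked permutations,
  no non-Euclidean distances.
* The mixed models use Wald z inference; no Satterthwaite/Kenward-Roger df.
* The landmark template is a schematic stand-in, not a reproduction of any
  published digitization template (which is not public); the scheme ships as
  configuration.
* Image averaging is shape-only: no shape-free texture averaging or masking
  protocol beyond the renderer's plain background.
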