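# impressionface

Landmark-based geometric morphometrics linking facial shape to a
two-dimensional psychological impression space.

## The problem

People form a wide range of trait impressions from a face — lively, cute,
dignified, irritated — yet these impressions are highly correlated and
collapse onto a small number of underlying dimensions, classically **valence**
(emotionally negative–positive) and **dominance** (obedient–dominant).  For
Japanese female faces rated by Japanese female observers, the question is
which *shape* features of the face drive those two dimensions, and whether
manipulating exactly those features manipulates the impressions.

`impressionface` implements that two-study computation as a tested, reusable
pipeline:

**Modeling study.** Faces are rated on 18 adjectives (visual analog scale,
0–100) by multiple raters; rater reliability is checked with Cronbach's α and
the item correlation matrix of the mean ratings is decomposed by PCA, giving
valence (PC1) and dominance (PC2) scores per face.  In parallel, each face is
described by K = 72 landmarks (36 fixed anatomical points, 36 semilandmarks
on the outline, brow, nose and lip curves).  Configurations are processed by
the standard geometric-morphometric chain:

1. **sliding semilandmarks** along curve tangents to minimize thin-plate-spline
   bending energy against the sample consensus,
2. **symmetrization** — each configuration is averaged with its relabeled
   reflection (faces are bilaterally symmetric objects),
3. **generalized Procrustes analysis** (translation, scale, proper rotation),
4. **shape PCA** (relative warps) with retention of the smallest leading
   component set reaching 95% cumulative variance.

The association between the retained shape-PC scores *Y* and the impression
scores is tested by distance-based permutational multivariate regression
(`adonis`-style): with *G* the Gower-centered matrix of Euclidean distances
among rows of *Y* and *H_t* the hat matrices of nested design matrices,

    SS_t    = tr[(H_t − H_{t−1}) G],     pseudo-F_t = (SS_t/df_t) / (SS_res/df_res)

with significance from permuting response rows (9,999 permutations by
default, *p* = (#{F\* ≥ F}+1)/(n_perm+1)).  Per-landmark regression of the
aligned coordinates on an impression score gives a **shape-regression field**
(displacement per SD of the score) for visualization and stimulus
construction.

**Validation study.** The average face image is built by warping every face
image onto the Procrustes mean (thin-plate-spline warping, kernel
U(r) = r²·log r²), and a 3 × 3 grid of stimuli is generated at −3/0/+3 SD
along the valence and dominance fields.  New raters' scores on the nine
stimuli are analyzed per adjective with a random-intercept, random-slope
linear mixed model

    score = β₀ + β_V·V + β_D·D + (u₀ + u_V·V + u_D·D)_rater + ε,

and the key statistic is the Pearson correlation across the 18 adjectives
between the impression-PCA loadings on one dimension and the fitted
mixed-model slopes for a manipulated dimension.  A high matched-dimension
correlation with near-zero crossed correlations shows the shape manipulation
moves exactly the impressions that load on that dimension.

Because the study's photographs are not public, a first-class synthetic-face
module generates 72-point face configurations with planted valence/dominance
shape fields, nuisance shape variation, rater-level ratings with known item
loadings, and schematic renders — so the whole pipeline is testable with
known ground truth.

## Worked example

```python
import numpy as np
from impressionface.synthetic_faces import (build_template, default_shape_sim_config,
    simulate_shapes, simulate_ratings, RatingSimConfig)
from impressionface.shape_pipeline import (slide_semilandmarks, symmetrize,
    generalized_procrustes, shape_pca, select_components)
from impressionface.impression_space import impression_pca, mean_over_raters, cronbach_alpha
from impressionface.shape_association import permanova_regression

template = build_template()
cfg = default_shape_sim_config(template, n_faces=102, seed=1)
configs, latent = simulate_shapes(template, cfg)
ratings = simulate_ratings(latent, RatingSimConfig(n_raters=24, seed=2))

alphas = [cronbach_alpha(ratings.values[:, i, :]) for i in range(18)]
print(f"Cronbach's alpha range: [{min(alphas):.2f}, {max(alphas):.2f}]")

imp = impression_pca(mean_over_raters(ratings), item_order=list(ratings.items))
print(f"impression PC1 (valence)  : {100*imp.variance_explained[0]:.1f}% of rating variance")
print(f"impression PC2 (dominance): {100*imp.variance_explained[1]:.1f}% of rating variance")

slid = slide_semilandmarks(configs, template.scheme)
proc = generalized_procrustes(symmetrize(slid, template.scheme))
space = shape_pca(proc)
sel = select_components(space, 0.95)
print(f"shape PCs retained for 95% variance: {len(sel)}")

assoc = permanova_regression(space.scores[:, sel],
                             np.column_stack([imp.valence, imp.dominance]),
                             labels=["valence", "dominance"], n_perm=9999, seed=3)
print(assoc.summary().to_string(float_format=lambda v: f"{v:.4f}"))
```

Output:

```
Cronbach's alpha range: [0.87, 0.95]
impression PC1 (valence)  : 77.4% of rating variance
impression PC2 (dominance): 15.8% of rating variance
shape PCs retained for 95% variance: 14
           df     SS pseudo_F     R2 p_perm
valence     1 0.0105  10.0318 0.0849 0.0001
dominance   1 0.0096   9.1842 0.0777 0.0001
Residual   99 0.1035          0.8374       
Total         0.1236          1.0000
```

Every adjective is rated reliably across the 24 simulated raters (α ≥ .87);
the impression PCA recovers a dominant valence dimension and a weaker
dominance dimension; 14 shape PCs carry 95% of the shape variation; and the
permutational regression detects the planted valence–shape association at
R² ≈ 0.08 with p = 10⁻⁴ (the smallest attainable p at 9,999 permutations).

The same analysis is available from the shell:

```bash
impressionface simulate --n-faces 102 --n-raters 24 --seed 1 --out study/
impressionface run --config pipeline.yaml --stage all
impressionface fig-correlations --out fig4/        # packaged reference tables
```

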