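# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `kneessfm`. Units are millimetres throughout; the canonical
frame is right-handed with x = mediolateral, y = anteroposterior,
z = proximodistal. Sex is coded female = 0, male = 1.

## Geometry

**Vertex normals** are area-weighted averages of incident-face normals
(summing raw cross products, which equal twice the face area times the unit
normal). Orientation follows the face winding, with a global flip if the
majority point inward relative to the centroid. On an icosphere at the
resolution used for the synthetic bones (subdivision 3) the worst deviation
from the exact radial normal is ~0.7°, decreasing with refinement.

**Rigid alignment** is closed-form Kabsch on corresponding points. No
scaling or reflection is estimated: overall size must survive into the
statistical model as a mode, so alignment is similarity-free by design.
Degenerate (collinear/coincident) configurations are rejected. When no
correspondence is known, alignment is classic ICP initialised from
principal axes; all four proper sign combinations are tried and the lowest
closest-point RMS wins. A caveat that matters for the synthetic shapes:
a pure superellipsoid is symmetric under 180° flips, so surface-based
alignment of such a shape is inherently ambiguous. The bump-bearing
(femur-like) shapes are asymmetric and align unambiguously; tests that
exercise ICP use those.

**Poisson-disk resampling** is seeded dart throwing over area-uniform
candidate points with a spatial-hash rejection test. With heavy candidate
oversampling (15 candidates per spacing² of area) the sample saturates, and
the empirical mean nearest-neighbour distance is 0.93–0.97× the rejection
radius, so the radius is set equal to the requested spacing. At 0.5 mm
spacing this yields ~2.6–3 points/mm², the regime the bone templates are
meant to operate in. The sampler is deterministic per seed.

**Closest points** are computed with a k-d tree but are contractually equal
to the brute-force scan; exact distance ties break to the lowest reference
index so every downstream result is deterministic.

**Cropping** keeps geometry within a signed height along an axis from a
reference point (e.g. a distal femur kept to one epicondylar width from the
most distal point); mesh faces survive only if all three vertices do.

## Correspondence

A template point cloud is warped onto each subject by a displacement field
`d(x) = Σ w_j exp(-|x - k_j|² / 2h²)` fitted per stage to closest-point
residuals by ridge least squares (default ridge weight 1e-3). Stages go
coarse to fine — default kernel widths 20/10/5 mm with knots thinned from
the template at 4/2/1× the node spacing — and each stage runs a few inner
closest-point iterations. "Adaptive" refinement adds knots only where the
residual exceeds the stage RMS. Duplicate knots raise; an RMS increase
between stages logs a warning.

The outer loop alternates: rigid alignment of each subject into the
template frame (ICP on the first pass, Kabsch on correspondent nodes
after), RBF warp, Kabsch re-alignment of the warped clouds to the template,
coordinate PCA, and replacement of the template by the PCA mean. It
terminates when the pooled per-node RMS change of the correspondent clouds
between successive iterations falls below a tolerance (default 0.01 mm,
max 20 iterations). The RMS criterion is pooled over subjects rather than
per subject; with rigid-copy inputs the loop converges to machine precision
in two iterations. The achievable tolerance scales with the sampling
density: closest-point residuals against a discrete target cloud jitter at
a fraction of the point spacing, so at the coarse desk-scale spacings used
in the test suite (2.5 mm) the loop plateaus near 0.1 mm and the tolerance
should be set accordingly; the 0.01 mm default corresponds to the 0.5 mm
operating spacing.

## Thickness

Subchondral bone nodes are those within an inclusion radius of the
subchondral cartilage cloud (default 2× the node spacing; the per-subject
sets are combined by union so all subjects share one node list — an
intersection option exists but is off by default). Thickness at a node is
measured along the outward normal: among articular points within a search
radius (default 10 mm) whose perpendicular distance to the normal line is
at most 1 mm, the one closest to the line is projected onto the normal and
the positive projection magnitude is the thickness. The perpendicular gate
and the positive-projection requirement prevent capturing far-condyle or
behind-surface points. Nodes with no admissible candidate are flagged and
carry thickness 0, keeping the feature matrix rectangular; flag counts are
logged. The measurement is rigid-motion invariant to machine precision and
its error on analytic spherical shells falls below 0.01 mm at 16 points/mm²
articular sampling.

## The shape-and-field PCA

Features are the concatenated nodal coordinates of all bones followed by
thickness at the shared subchondral nodes, in a deterministic documented
column order. Columns are mean-centred and divided by their own standard
deviation (n−1 denominator) — correlation-style PCA, so millimetre-scale
coordinates do not drown the thickness field. The sentence-level ambiguity
of "divide by its standard deviation" (per column vs per block) is resolved
per column by default; a per-block variant (each block scaled by its pooled
RMS standard deviation) is available behind `normalization="per-block"`.
Zero-variance columns are centred but not scaled, are excluded from the
mode loadings by construction, and reproduce their mean under synthesis.

The decomposition is a thin SVD of the normalised matrix; modes are
orthonormal, variances are score variances sorted descending, and
`k = min(n−1, m)` components are retained. PCA signs are arbitrary, so each
mode is flipped to make its largest-magnitude loading positive — results
are then reproducible run to run. Full-rank reconstruction is exact to
1e-8; scores of training subjects are recovered exactly by projection.

## Demographic statistics

Per-mode standardized multiple linear regression z-scores the response and
all four predictors, then fits OLS (statsmodels); the reported betas are
therefore unit-free and invariant to affine unit changes. Condition numbers
above 1e8 raise. Significance is flagged at the 95% and 99% levels.

The sex classifier is greedy forward-stepwise logistic regression: at each
step the candidate mode with the smallest likelihood-ratio p-value against
the current model enters, stopping when the best candidate's p ≥ α
(default 0.05); the final model is refit on all data. Wald and AIC entry
rules were deliberately not used — the LRT is the likelihood-native test at
these sample sizes. Perfect separation makes the MLE diverge; the fit then
falls back to an L2-penalised logistic regression with a logged warning.
Under label permutation with five candidate modes, the probability that no
candidate clears α is roughly 0.95⁵ ≈ 0.77 (empirically ~0.8–0.85 with the
discreteness of the LRT), which is what the null-behaviour test asserts.

Cross-validation is stratified k-fold (default 10) with shuffling
controlled by a seed; the model is refit per fold and predictions are
pooled over all held-out subjects, so the accuracy is a single binomial
count (e.g. 47/51) — matching how one would quote a single confidence
interval for the whole cohort — and the AUC is computed from the pooled
predicted probabilities. The confidence interval is the exact
Clopper–Pearson interval in its beta-quantile form, which a bisection on
binomial tail probabilities reproduces to 1e-6; for 47/51 it gives
[81.1%, 97.8%]. Decision geometry reports the probability-0.5 hyperplane
(unit normal along the coefficient vector, offset −b/‖w‖) and the
male−female axis (difference of class mean score vectors).

## Synthetic cohorts

The generator emulates the *structure* of a knee-imaging study: closed
bone-like surfaces carrying a cartilage layer whose thickness field and
shape co-vary through a small number of latent modes linearly coupled to
demographics. It does not emulate anatomical realism, MR acquisition,
segmentation error structure, or osteoarthritic change — pseudo-bones are
superellipsoids (femur 22×20×28 mm semiaxes, tibia 20×18×24, patella
12×10×9, icosphere-parameterised with a constant vertex count, so vertex
index *is* the true correspondence) with an optional smooth "condylar"
bump. Analytic surfaces were chosen precisely because they give exact
oracles (ellipsoid area via elliptic integrals, offset shells, known
correspondence); real meshes can be substituted through the same file
interfaces.

Demographics are drawn per sex from normal distributions matching the study
cohort (30 F / 21 M prevalence; female height 167.5 ± 5.9 cm, mass
60.6 ± 7.7 kg, age 28.2 ± 4.6 y; male 178.4 ± 7.4, 72.7 ± 9.0, 29.3 ± 3.7).
Height, mass and age are conditionally independent given sex, which fixes
the full demographic correlation matrix analytically (e.g.
corr(sex, height) ≈ 0.63).

Latent scores emulate principal-component scores of a population model, so
they are constructed to be mutually uncorrelated with unit variance:
`z = B d_std + ε` with structural coefficient matrix B (default size mode:
sex −0.323, height −0.508; aspect mode: sex −0.500, height +0.548; condyle
mode: sex −0.415) and residual covariance `I − B Σ_d Bᵀ` (raising if the
coefficients alone exceed unit variance). Standardized regression of a
latent score on demographics therefore recovers exactly the rows of B in
population.

Each mode acts through a displacement field on the template (isotropic
scale; mediolateral widening with a compensating proximodistal change;
condylar bump plus a global shaft/plateau shear — the shear is there
because condylar-depth variation in real knees co-occurs with shaft-angle
and plateau-tilt changes, and because a purely local bump cannot carry a
two-digit share of column-normalised variance) plus a thickness field
(offset and/or mediolateral gradient). The raw fields overlap, so they are
Gram–Schmidt orthogonalised in the *normalised-column* metric, jointly with
a fixed-point calibration of per-mode score scales and the two isotropic
noise SDs (geometry, thickness) such that mode k owns exactly its target
share of normalised variance (default 60/25/10%) and noise owns the rest
(default 5%, split between coordinate and thickness columns by column
count). The overall scale is pinned by the leading mode, so a unit size
score means exactly a 4% size change. One consequence of the column-wise
normalisation worth knowing: template coordinates that are exactly zero
produce pure-noise columns, and an iid noise share defined in normalised
space implies small millimetre noise SDs; the pipeline's own measurement
process (sampling, interpolation, thickness projection) adds further,
realistic perturbation on top.

A bounded random rigid transform (±30°, ±50 mm) is applied per subject to
exercise the alignment stages; transforms, latent scores, true thickness
fields and patch indices are all emitted as ground truth. A five-mode
configuration (`classifier_config`) confines sex dimorphism to modes 1, 2
and 4 for classifier studies; its mode-2 height coefficient is +0.30 rather
than +0.548, because with the stronger value the sex and height effects on
that mode cancel almost exactly in the marginal (corr(z₂, sex) ≈ −0.15
through the sex–height correlation), leaving too little dimorphism for any
method to detect at desk-scale cohort sizes. The Bayes-optimal sex
classification accuracy of a configuration is computed from the analytic
Gaussian class conditionals (quadratic discriminant rule, Monte Carlo
integration) and serves as the reference for cross-validated accuracy.

## Problem sizes in the shipped studies

The test suite and acceptance script run: structure recovery on one n = 60
cohort at icosphere subdivision 3 (642 vertices/bone, ~4 points/mm²
cartilage sampling) through the built-in-correspondence pipeline path;
regression recovery over 20 seeds at n = 60; classifier behaviour over 20
seeds at n = 200 on latent scores directly (the geometry-free path of the
same generator); the full RBF registration path on an n = 6 cohort at
2.5 mm spacing; and the analytic oracles above. These sizes were chosen so
that each study's sampling error is small relative to the effect it
measures while the whole battery completes in about a minute.

## Known limitations

- Pseudo-bones are not anatomical; conclusions about registration accuracy
  on real femora do not follow from the synthetic tests, only the
  correctness of the machinery does.
- The iid noise model has no spatial correlation, unlike segmentation
  error; the measurement stages add some realistic correlated error, but a
  smooth-field noise model would be a natural extension.
- ICP initialisation assumes shapes with distinct principal axes and no
  flip symmetry (true of real bones and of the bump-bearing synthetic
  femur; not of pure superellipsoids).
- The correspondence convergence tolerance is meaningful only relative to
  the sampling density (see above).
- Thickness at nodes whose cartilage coverage varies across subjects is
  zero-filled and flagged rather than imputed; with the default union rule
  a boundary ring of partially covered nodes can carry bimodal values.
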