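# kneessfm

Statistical shape and cartilage-thickness **field** modelling of knee bones
(femur, tibia, patella), for musculoskeletal researchers studying how bone
morphology and the spatial distribution of cartilage thickness co-vary across
a population — e.g. as a function of sex, height, body mass and age.

Bone shape alone, or summary cartilage measures like mean thickness or
volume, miss the coupling between the two tissues. This package builds a
**statistical shape and field model (SSFM)**: dense point correspondence is
established across subjects, cartilage thickness is measured at every
subchondral bone node by projection onto the node's surface normal, and a
single PCA couples the two.

## Model

For each of *n* subjects, the feature vector concatenates the correspondent
bone node coordinates with the cartilage thickness at shared subchondral
nodes:

```
x_i = [ femur xyz … | tibia xyz … | patella xyz … | t_femur … | t_tibia … | t_patella … ]
```

The *n × m* matrix is column-wise mean-centred and divided by the per-column
standard deviation, and decomposed by PCA:

```
X = 1 μᵀ + S Φᵀ diag(σ),     Φᵀ Φ = I
```

where the columns of Φ are the **modes** (coupled bone-shape + thickness
patterns), the rows of S are per-subject **mode scores**, and the score
variances give each mode's share of the population variance. Mode scores of
the modes covering 90% of the variance are then related to demographics by

- **standardized multiple linear regression** (per mode, z-scored response
  and predictors: sex, height, mass, age → comparable betas), and
- a **forward-stepwise logistic regression** classifying sex from mode
  scores (likelihood-ratio entry tests at α = 0.05), evaluated by stratified
  ten-fold cross-validation with an exact Clopper–Pearson 95% interval on
  the pooled accuracy and the pooled-probability AUC.

The geometric stages — Poisson-disk surface resampling, rigid Kabsch/ICP
alignment (no scaling: size must survive as a mode), coarse-to-fine Gaussian
RBF template-to-target fitting with an iterative PCA-template loop, and
normal-projection thickness mapping — are all part of the package, as is a
synthetic pseudo-knee cohort generator with known latent modes, so every
stage is testable without any imaging data.

## Worked example

Simulate a 24-knee cohort and run the full pipeline (the synthetic meshes
are vertex-correspondent, so the fast `builtin` correspondence is used;
`rbf` runs the full non-rigid registration):

```bash
kneessfm simulate demo_cohort --n-subjects 24 --seed 3
kneessfm run-all demo_cohort --output-dir demo_out --correspondence builtin --seed 3
```

which prints

```
Variance spectrum (top 10 modes):
  mode  1:  51.30%   cumulative  51.30%
  mode  2:  37.28%   cumulative  88.57%
  mode  3:   9.58%   cumulative  98.16%
  ...
Standardized regression of mode scores on demographics:
           mode1   mode2   mode3
sex       0.3647 -0.5258  0.2033
height    0.4825  0.2882  0.2311
...
Modes to reach 90% variance: 3
Stepwise-selected modes: [1]
CV accuracy 83.3% (20/24), 95% CI [62.6%, 95.3%], AUC 90.2%
```

Reading this: the cohort was generated with three latent modes (size,
mediolateral aspect, condylar depth), and three principal components indeed
carry ~98% of the variance. Mode 1 (size) is significantly associated with
height (β = 0.48, p = 0.007) and sex (β = 0.36) — larger knees with thicker
cartilage for taller/male subjects. At n = 24 the stepwise classifier keeps
only the strongest dimorphic mode and classifies sex with 83% cross-
validated accuracy; the bracketed interval is the exact binomial 95% CI on
20/24 pooled correct predictions. `demo_out/` additionally contains the
model container (HDF5), per-node thickness CSV, the regression table,
per-fold CV predictions, and ±2 SD synthesized shapes per mode as point
clouds.

The same pipeline runs on real segmented surfaces laid out as
`<subject>/<bone>.ply` + `<bone>_subchondral.xyz` + `<bone>_articular.xyz`
with a top-level `demographics.csv`.

## Library use

```python
from kneessfm import (generate_cohort, default_config,
                      PipelineConfig, run_pipeline)

cohort = generate_cohort(default_config(n_subjects=60, seed=7))
result = run_pipeline(PipelineConfig(correspondence="builtin",
                                     output_dir="out", seed=7), cohort=cohort)
model = result["model"]            # ShapeFieldPCA (sklearn-style transformer)
model.modes_to_reach(0.90)         # -> 3
model.synthesize_mode(1, +2.0)     # mean + 2 SD along mode 1, in mm
```

`ShapeFieldPCA`, `StepwiseSexClassifier` and `StandardizedLinearModel`
follow the scikit-learn estimator contract (`fit` / `transform` or
`predict`, `get_params`, trailing-underscore fitted attributes) and compose
with sklearn pipelines and model selection.

## Documentation

See `docs/methods.md` for the modelling assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and known
limitations.
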