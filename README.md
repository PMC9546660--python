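# oralcad

Computer-aided classification of oral histopathology images into normal
epithelium (NEOR) and oral squamous cell carcinoma (OSCC).

Whole-slide H&E images collected in different labs show systematic staining
and scanner color shifts that degrade any downstream classifier. `oralcad`
implements the full pipeline that addresses this:

1. **Reinhard stain normalization** — each image is mapped into the
   decorrelated lαβ color space (RGB → LMS cone response → log → orthogonal
   opponent rotation), where its per-channel global mean μ_g and standard
   deviation σ_g are replaced by a template image's:
   `out_c = μ_t,c + (in_c − μ_s,c) · σ_t,c / σ_s,c`, then mapped back to RGB.
2. **Deep-feature extraction** — images are resized to each backbone's input
   geometry (VGG16 224×224, AlexNet 227×227, ResNet50 224×224,
   InceptionV3 299×299) and passed through a pluggable backbone: any callable
   mapping an image to a fixed-length vector, e.g. a pretrained CNN's
   penultimate layer or the bundled deterministic stub extractor.
3. **BPSO wrapper feature selection** — binary particle swarm optimization
   over feature masks. Velocities follow
   `v' = w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)` (clamped to ±v_max);
   positions are resampled through the sigmoid transfer
   `S(v) = 1/(1+e^(−v))`; the fitness is the error rate of a k-nearest-
   neighbour classifier on the masked columns (lower is better); personal
   and global bests update on strict improvement only.
4. **Classification and evaluation** — XGBoost, random forest or an MLP on a
   stratified 80/20 split, with confusion-matrix metrics
   (sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
   accuracy = (TP+TN)/total, as percentages; OSCC is the positive class),
   multi-run repetition and Welch two-sample t-tests between conditions.

A synthetic-data module generates H&E-toned two-class image fixtures (with
controllable staining color jitter) and feature matrices with planted
informative columns, so every stage is testable without any image download.

## Worked example

```python
import numpy as np
from oralcad import *

# two-class stained-tissue fixture with lab-to-lab color jitter
images, labels, _ = make_image_fixture(
    ImageFixtureSpec(n_per_class=20, color_jitter=0.15, seed=0))

# full pipeline, both normalization conditions, 10 seeded repetitions
rep = run_pipeline({"seed": 0, "runs": 10, "normalize": {"compare": True}},
                   images=list(images), labels=labels)
c = rep["normalization_comparison"]
print(f"normalized   mean accuracy: {c['mean_accuracy_normalized']:.1f}%")
print(f"unnormalized mean accuracy: {c['mean_accuracy_unnormalized']:.1f}%")
print(f"Welch t-test: t = {c['t_statistic']:.2f}, p = {c['p_value']:.3g}")
```

prints

```
normalized   mean accuracy: 97.5%
unnormalized mean accuracy: 81.2%
Welch t-test: t = 3.88, p = 0.0021
```

— under simulated staining variation, normalizing every image against a
single template recovers ~16 accuracy points, and the difference is
significant at the 95% level.

Feature selection on a matrix with two planted informative columns among 50
noise columns:

```python
ds = make_feature_fixture(FeatureFixtureSpec(seed=7))    # n=200, D=52
res = bpso_select(ds, BpsoConfig(swarm_size=20, max_iter=50, seed=1))
print(ds.meta["informative"], res.n_selected, res.gbest_fitness)
```

prints `[43, 48] 30 0.0`: BPSO keeps 30 of 52 columns, including both
planted ones, and drives the held-out kNN error to zero.

Confusion-matrix metrics from counts (TP=184, TN=52, FP=7, FN=2 on a
245-image test set):

```python
print(compute_metrics(ConfusionCounts(TP=184, TN=52, FP=7, FN=2)).rounded())
# {'sensitivity': 98.9, 'precision': 96.3, 'accuracy': 96.3}
```

## Command line

```bash
oralcad synth images --out data/ --jitter 0.15 --seed 0
oralcad normalize --input-dir data --template data/class0_000.png \
    --output-dir norm --pdf-report pdf.csv
oralcad extract --manifest data/manifest.csv --backbone stub --out features.csv
oralcad select --features features.csv --swarm 20 --iters 100 --k 5 \
    --seed 0 --runs 20 --out mask.json --history history.csv
oralcad run --manifest data/manifest.csv --config pipeline.yaml --out run1/
```

Exit codes: 0 success, 2 configuration error, 1 runtime failure. Every run
directory receives a `config_echo.yaml` and `report.json` for provenance.

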