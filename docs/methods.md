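# Methods

## Reinhard stain normalization

The transfer operates in the lαβ color space: 8-bit RGB is scaled to [0, 1],
multiplied by the RGB→LMS cone-response matrix, logged (base 10), and rotated
by the fixed orthogonal opponent transform diag(1/√3, 1/√6, 1/√2) · B with
B = [[1,1,1],[1,1,−2],[1,−1,0]]. An offset of ε = 1/255 is added to the LMS
responses before the logarithm so black pixels stay finite; the inverse path
subtracts it again, which makes the round trip exact up to 8-bit
quantization (observed error 0 levels on random images; the contract allows
±2).

Channel statistics are the global per-channel mean and **population**
standard deviation (divide by N) over all pixels: the statistic describes
the image itself, not a sample from a larger population, and one convention
has to be fixed for the identity-transfer property to be testable. The
transfer replaces the source image's lαβ moments with the template's; the
transformed array's moments match the target to machine precision before
the final RGB clipping (values outside [0, 255] are clipped, not wrapped —
they are physical intensities).

A source channel whose standard deviation is below 1e-12 (a constant channel
up to float residue) makes the scaling undefined and raises a
degenerate-source error rather than producing infinities.

Which image serves as the template is a user choice; the CLI requires it
explicitly and the pipeline defaults to the first image listed in the
manifest. PDF diagnostics (per-RGB-channel normalized histograms over
[0, 255]) quantify how far a normalized image's color distribution has moved
toward the template's.

## Feature extraction

A backbone is any callable `image -> 1-D finite vector` of fixed length.
Images are first resized (bilinear, aspect ratio not preserved) to the
backbone's input geometry; the four standard architectures use
VGG16/ResNet50 224×224, AlexNet 227×227, InceptionV3 299×299, with
`feature_dim` set to the canonical penultimate-layer widths (4096, 4096,
2048, 2048). Pretrained networks require a deep-learning runtime and are
plugged in by the caller through this contract; the package itself ships a
deterministic **stub backbone** that projects hand-crafted statistics
(3×16-bin channel histograms plus 4×4 block channel means, 96 raw values)
through a seeded random Gaussian matrix. The block means carry the spatial
signal (nuclei density/size), the histograms the color signal, which is
exactly what the synthetic classes differ in — so the stub supports
meaningful end-to-end evaluation, including the interaction between color
jitter and stain normalization. It is not a surrogate for CNN feature
quality on real tissue.

Feature columns are standardized (zero mean, unit variance, training-set
statistics) before selection and classification: the kNN wrapper fitness is
scale-sensitive. Optional fine-tuning hooks are deliberately out of scope.

## BPSO feature selection

Particles hold binary positions (feature masks) and real velocities.
Defaults, all exposed in `BpsoConfig`: swarm 20, T = 100 iterations,
inertia w decayed linearly 0.9 → 0.4 over T, c1 = c2 = 2.0, v_max = 6,
kNN k = 5. Velocity clamping to ±v_max keeps the sigmoid from saturating
and freezing exploration; at |v| = 6, S(v) is within 0.25% of its asymptote,
so ±6 bounds the per-coordinate flip probabilities to [0.0025, 0.9975].

Positions are *resampled* from the sigmoid-transferred velocity (x_d = 1 iff
rand < S(v_d)), not flipped. An all-zero mask has undefined fitness; it is
repaired by setting one uniformly random coordinate to 1. Personal and
global bests update on strict improvement only, so ties keep the incumbent
and the best-so-far history is non-increasing by construction.

The fitness is the plain kNN (Euclidean) misclassification rate on the
masked columns — no feature-count penalty — estimated on a stratified 80/20
holdout of the data handed to the selector, drawn once per run from the run
seed. A fixed holdout keeps the fitness landscape deterministic within a
run, which makes the search reproducible and lets evaluations be memoised
by mask. Multi-seed batches (`bpso_select_runs`) support mean-convergence-
curve reporting across independent runs.

## Classification and evaluation protocol

The reported metrics come from a stratified 80/20 outer holdout (per-class
test allocation `round(n_c × 0.2)`, seeded); 10-fold cross-validation within
the training partition is available as a sanity check
(`cross_validate_train`). These two mechanisms are deliberately composed
this way — an outer holdout for reported numbers, inner CV for diagnostics —
since using the same folds for both would leak the test data into model
assessment.

Classifiers: XGBoost, random forest, and a multilayer perceptron, each with
library-default hyperparameters and a fixed seed, overridable via config.
OSCC (label 1) is the positive class. Metrics with a zero denominator are
reported as NaN and flagged `undefined`, never silently zero. Per-run
accuracies across conditions are compared with a Welch (unequal-variance)
two-sample t-test at the 95% confidence level; the safer default when
nothing is known about the variances. Two degenerate zero-variance samples
with equal means return (t=0, p=1).

`run_pipeline` repeats split → (select) → train → evaluate across `runs`
seeds (seed, seed+1, …); each repetition re-splits the data, so run-to-run
variance reflects both the split and classifier stochasticity. BPSO
selection is run once (first repetition's training partition) and reused by
default; `selection.per_run` re-runs it every repetition.

## Synthetic data

Image fixtures: eosin-pink background, hematoxylin-purple elliptical nuclei;
the carcinoma-like class has more, larger and more pleomorphic nuclei
(counts 14–22 vs 4–8, radii 3–7 vs 2–4 px) and a slightly denser palette.
Per-pixel Gaussian texture noise (σ = 4 levels) keeps channels
non-degenerate. Color jitter applies a per-image random channel gain
(1 ± jitter) and offset (± jitter·255), emulating lab-to-lab staining
variation; it is a *global affine* color nuisance, which is exactly the
family of distortions Reinhard transfer can remove — real staining variation
is only approximately affine, so passing tests demonstrate the mechanism,
not real-data performance. Default fixture size is 64×64 with 20 images per
class: large enough for stable block statistics, small enough for fast
tests.

Feature fixtures: informative columns are class-shifted normals (shift =
separation × σ, default separation 3), noise columns are class-independent;
columns and rows are shuffled and the planted indices recorded in metadata.
Defaults (n = 200, 2 informative, 50 noise) give a problem where selection
visibly helps but a full-feature kNN is still above chance.

## Numerical choices and limitations

- Problem sizes for the multi-run checks: 20 seeded BPSO runs at swarm 20 ×
  T 50; exhaustive comparisons at D = 8 (255 masks). These sizes give stable
  medians while keeping the whole verification suite fast.
- The end-to-end comparison uses 10 seeded repetitions at jitter 0.15.
- Reported metric tables round to one decimal; machine outputs keep full
  precision.
- Published penultimate-layer widths do not match some reported per-model
  feature counts in the literature this pipeline targets; the backbone
  contract treats the width as whatever the extractor produces.
- Real pretrained CNN backbones are not bundled (they need a DL runtime);
  all shipped end-to-end results use the stub backbone and synthetic data,
  and no claim is made about real histopathology accuracy.
- The kNN fitness holdout is a single split; a cross-validated fitness would
  be less noisy but T × swarm times more expensive and is not what the
  wrapper protocol specifies.
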