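# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data the test suite runs on, and the
numerical choices made where the design was genuinely open.

## Problem setting

The package targets binary classification of breast lesions (benign vs
malignant) from two imaging modalities: ultrasound (US), characterised by
multiplicative speckle and low contrast, and mammography (MG), characterised
by low-contrast masses plus bright non-anatomical artifacts (film labels,
markers). The clinical intuition encoded throughout is the BI-RADS one: a
round, circumscribed mass is more likely benign; an irregular, spiculated
one more likely malignant. The pipeline therefore combines shape features
that capture that intuition directly with texture descriptors and generic
deep features, and lets two statistical selectors decide which columns carry
signal.

## Segmentation

Chain: histogram equalization → median(3×3) → threshold → median(9×9) →
hole filling → border following → largest component → bounding box + 25 px.

* **Equalization** uses the cumulative-histogram mapping
  `H'(v) = round(255·cdf(v)/N)`. It is monotone, so intensity ordering is
  preserved; a constant image maps to a constant image.
* **Threshold** defaults to Otsu's between-class-variance criterion
  (`threshold="auto"`), overridable with a fixed value in [0, 255]. The mask
  is `intensity > threshold`. Global equalization followed by Otsu assumes a
  roughly uniform background: on a flat background the lesion is recovered
  almost exactly (Jaccard ≈ 0.99 on noiseless synthetic patches), while a
  strong low-frequency background gradient degrades it. This is why a
  provided mask in the manifest (`mask_path`) bypasses segmentation
  entirely — the analogue of manual ROI delineation for ultrasound.
* **Median windows**: 3×3 before thresholding (denoising), 9×9 after
  (binary cleanup), both with edge replication; both configurable (5×5
  pre-threshold is a supported variant).
* **Border following** is the Suzuki–Abe-style outer-border trace with
  8-connectivity (clockwise Moore neighbourhood scan with Jacob's stopping
  criterion). For every 8-connected component the ordered closed contour
  visits exactly the foreground pixels with a 4-connected background
  neighbour in the hole-filled component; interior hole borders are not
  traced (the pipeline hole-fills before tracing, so none exist there).
* **Largest lesion**: the component with the largest hole-filled area wins;
  ties break to the component whose first pixel comes first in raster order.
* **Bounding box**: the contour's tight rectangle expanded by 25 px per
  side, clipped to the image; the ROI is that crop of the *original* image.
* "Fill the gaps" is implemented as morphological hole filling of the binary
  mask (one open interpretation; flagged here).

## Texture descriptors

* **LBP** (p=8, r=1): bit *i* is set when ring neighbour *i* (clockwise from
  the top-right) is ≥ the centre. This is the standard convention; on a
  constant image every code is 255. An alternative `literal_sign` flag flips
  the comparison (bit set when neighbour < centre) for comparison studies.
  Border pixels are not coded. The 256-bin code histogram is normalized to
  frequencies so image size does not rescale the feature.
* **HOG**: central differences with edge replication; orientation folded to
  the unsigned range [0°, 180°). Cells are 8×8 px with 9 bins of width 20°;
  each pixel's magnitude is split linearly between the two bins whose
  centres (c_j = 20°·(j+½)) straddle its orientation, with circular wrap, so
  per-cell vote mass equals the cell's summed magnitude exactly. Blocks are
  2×2 cells stepped one cell (8 px stride), flattened to 36 values and
  normalized by `v/√(‖v‖² + ε)` with ε = 1e-5; an all-zero block stays zero.
* **Input normalization**: ROIs are resized (bilinear) to 128×128 before
  description, a multiple of the cell size, giving a fixed texture length of
  15·15·36 + 256 = 8356.
* **PCA** reduces the texture vector to 199 components by default; on runs
  with fewer than 200 samples the count is capped at
  min(n_samples − 1, n_features) with a warning rather than an error. The
  implementation delegates to a full-SVD PCA and then fixes each component's
  sign so its largest-magnitude loading is positive, making fitted bases
  bit-reproducible.

## Shape features

Area is the mask pixel count. Perimeter is the Euclidean chain length of the
closed traced contour (1 per axis step, √2 per diagonal), floored at 1 px so
circularity stays finite for degenerate single-pixel regions. Circularity is
4π·Area/Perimeter²: ≈ 0.9–1.0 for rasterized disks (the digital chain
slightly overestimates a smooth perimeter) and markedly lower for spiculated
outlines of the same area. Eccentricity is computed from *raw* central
moments as `((μ02 − μ20)² + 4·μ11)/Area`. That expression is dimensional
(it grows with region size) and is kept for fidelity with the feature set
this package standardises on; `standard_eccentricity=True` switches to the
usual ellipse-axis eccentricity in [0, 1) derived from the normalized
second-moment matrix.

## Deep feature contract

Deep features enter through a two-field contract: a fixed `output_dim` and a
deterministic `extract(image) -> vector`. The default `StubExtractor`
resizes the ROI to 32×32, projects the flattened, [0,1]-scaled pixels
through a fixed random N(0, 1/1024) map drawn once from its seed, and
applies tanh. It is not a trained network and is not claimed to produce
discriminative features beyond the linear image geometry it preserves; its
role is to give the pipeline the exact shape, determinism and pluggability
of a pretrained backbone (width 1920, the global-average-pool width of
DenseNet-201) with zero downloads. An optional adapter to a real
DenseNet-201 exists behind the same contract and raises a clear ImportError
when no deep-learning runtime is installed.

## Feature selection

* **GA wrapper**: individuals are boolean genomes over feature columns.
  Fitness is the mean stratified 5-fold cross-validated accuracy of a
  decision tree (fixed random state) restricted to the genome's columns; the
  empty genome scores 0. Defaults: population 500, crossover fraction 0.5
  (midpoint single-cut exchange), per-gene mutation rate 0.05, μ = 50
  survivors, λ = 100 offspring, at most 35 generations, early stop after 5
  generations without best-fitness improvement, initial gene probability
  0.5. Survivor selection pools parents and offspring and keeps the best μ
  (elitism), so best fitness is non-decreasing. Fitness values are cached by
  genome, and everything derives from one seed. Reported scores are each
  column's inclusion frequency in the final surviving population.
* **MI filter**: per-feature mutual information with the class label via the
  k-nearest-neighbour Chebyshev-distance estimator in its mixed
  continuous/discrete form: for each sample, the distance to its k-th
  neighbour *within its own class* sets a radius; the number of samples of
  any class strictly inside that radius (the sample itself included) enters
  a digamma identity together with the class counts. Defaults k = 3, tiny
  seeded jitter (1e-10 of the feature scale) breaks ties, constant features
  score 0, and negative estimates are clamped to 0. The top 26 features are
  kept by default; ties break to the lower column index. A
  continuous–continuous variant of the same estimator (`ksg_mi`) is exposed
  and validated against the Gaussian closed form −½·ln(1−ρ²).
* **Fusion** concatenates the GA picks then the MI picks, *retaining
  duplicates* (output width is always |GA| + |MI|, e.g. 20 + 26 = 46), with
  method-suffixed column names to stay unique.
* **Random undersampling** draws, per class and without replacement, the
  minority-class count of samples with a seeded generator, then shuffles.

## Pipeline orchestration

Per-sample hybrid vectors concatenate deep (1920), PCA texture (199) and
shape (4) blocks, in that fixed order, for 2123 columns. With two
modalities, each modality table is first undersampled to the common
per-class minimum, rows are paired within class by a seeded random
permutation (no natural cross-modality patient key exists in this setting;
the pairing rule is a documented interpretation), and columns are
concatenated with modality prefixes (2 × 2123 = 4246). Selection, fusion,
undersampling, a stratified 80/20 split (test share floored per class:
420 balanced samples split 336/84) and classification follow. Every seed is
echoed into the evaluation JSON; identical manifest + config reproduce an
identical report byte for byte.

## Classifiers and evaluation

* **Native AdaBoost**: depth-1 decision-stump weak learners on weighted
  samples; ε_t is the weighted error, clipped to [1e-10, 1−1e-10] before
  α_t = ½·ln((1−ε_t)/ε_t) so α stays finite; weights update
  multiplicatively and are renormalized (Z_t) each round; training stops
  early on a perfect round (ε = 0) or a no-better-than-chance round
  (ε ≥ 0.5). Prediction is the sign of the α-weighted vote; exact ties go
  to the positive (malignant) class.
* **XGBoost / MLP** are consumed through their established implementations
  behind the same fit/predict contract (seeded; MLP standardises inputs).
* **Metrics**: malignant is the positive class. Accuracy, recall
  (sensitivity), specificity, precision, F1, Dominance = Recall −
  Specificity, and IBA = (1 + 0.1·Dominance)·(Recall·Specificity) are
  reported for both class views and macro-averaged. When Recall =
  Specificity, IBA reduces exactly to their product. Metrics with a zero
  denominator return NaN with a warning rather than a silent 0.
* **Rank-sum test**: pooled midranks; W is group A's rank sum. When
  C(N, n_A) ≤ 20 000 the two-sided p-value is computed by exhaustive
  enumeration of all rank assignments (the normal approximation is visibly
  off at such sizes: for groups {1,2,3} vs {4,5,6} the exact two-sided p is
  0.1 while the z-approximation gives ≈ 0.05); otherwise the tie-corrected
  normal approximation is used. Decisions are at α = 0.05.

## Synthetic data

`make_lesion_image` rasterizes an ellipse (default minor/major aspect 0.85)
whose boundary radius is perturbed by `depth·sin(count·θ)`. Benign specs
have zero spiculations; malignant specs at least five, which monotonically
lowers circularity. US corruption is multiplicative uniform speckle
`I·(1+u)`, `u ~ U(−a, a)` (default a = 0.12 in the dataset writer); MG
corruption is an additive low-frequency planar gradient (amplitude =
`noise_level`, default 30 intensity units) plus 1–3 bright 230-intensity
rectangles placed away from the lesion. Lesion contrast defaults to +100 on
a background of 60. What this emulates — and what it does not: the
generator reproduces the *geometric* class difference (margin regularity)
and the artifact/noise structure the preprocessing must survive, but not
acoustic shadowing, tissue texture, density patterns, or any realistic
radiometric calibration. Passing tests therefore demonstrate that each
algorithmic stage is implemented correctly and that the chain preserves a
known geometric signal; they say nothing about clinical performance on real
ultrasound or mammography data, which additionally requires a trained deep
backbone in place of the stub.

`make_planted_feature_table` draws unit-variance Gaussian columns; the
designated informative columns get class means separated by `effect_size`
(in noise-SD units, default 3 — comfortably recoverable at 200 samples per
class, which is the scale the selector tests run at).

## Problem sizes and defaults used in validation

The test and example runs use desk-scale sizes chosen once: 200 samples per
class for selector recovery; n = 5000 for the Gaussian mutual-information
check; 1000 replicates for the rank-sum type-I-error estimate; 60
images per class for the end-to-end smoke run, with a reduced GA
(population 24, μ = 8, λ = 16, ≤ 5 generations) since the full
population-500 default is meant for real feature-selection runs, not
smoke-testing. Library defaults always remain the full-scale ones.

## Known limitations

* Global equalize + Otsu segmentation assumes a near-uniform background
  (see above); strong gradients require a fixed threshold or a mask.
* The verbatim moment eccentricity is size-dependent; use the standard
  variant for cross-scale comparisons.
* The stub extractor carries no learned semantics; plug a real backbone for
  any claim about deep-feature quality.
* Binary labels only; no multi-class BI-RADS grading, no DICOM I/O, no
  pectoral-muscle removal, single-lesion output only.
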