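# Methods

## Problem and model

`nucleoscore` classifies histology material into tumors with and without
PTC-like nuclei via interpretable nuclear morphometry. The unit of
prediction is the patient: nucleus-level measurements are aggregated to a
fixed-length patient descriptor and classified with standard shallow
learners under nested cross-validation. The method assumes (i) instance
segmentation of nuclei is available or obtainable at the working
resolution, (ii) the discriminative signal lives in per-nucleus color,
shape and neighborhood statistics rather than tissue architecture, and
(iii) images per patient are exchangeable, so nuclei can be pooled across
images.

## Segmentation post-processing

Segmentation is a pluggable input. The bundled baseline
(luminance grayscale → Otsu threshold, nuclei darker than background →
hole filling → removal of objects under 12 px → Euclidean distance
transform → peak markers with a 7 px minimum separation → watershed) is
deterministic and adequate for the synthetic fixtures only; it makes no
claim on clinical H&E. Both routes share the size filter: per image the
median instance area *m* is computed **once** on the pre-filter
population, and instances with area strictly above 2*m* or strictly below
0.5*m* are removed. Instances exactly at the bounds survive (the removal
criteria are read as strict inequalities). For an even instance count the
median is the mean of the two middle areas. Border-touching nuclei are
not removed by default — the size filter is the designated mechanism for
partially visible nuclei — but `drop_border=True` (CLI `--drop-border`)
removes frame-touching instances when wanted.

## Feature definitions and numerical choices

Canonical order: 23 color, 4 shape, 9 spatial (36 total); the order is
frozen in `features.ALL_FEATURES` and all tables use it.

- Grayscale: ITU-R 709 luminance (0.2125 R + 0.7154 G + 0.0721 B), kept
  real-valued in [0, 255]; quantized to 8 bits only for histogram and GLCM
  computations.
- Concentric zones: the mask is partitioned into border / middle / center
  as tertiles of the Euclidean distance-to-edge transform. Pixels are
  sorted by (distance, row, col) and split into three groups whose sizes
  differ pairwise by at most one (extras go to the border first); the
  lexicographic tie-break makes the partition deterministic. Zone ratios
  are mean(border)/mean(middle) and mean(border)/mean(center) per channel,
  NA on a zero denominator or masks under 3 px.
- GLCM: distance 1 px; angles 0°, 45°, 90°, 135°, properties averaged over
  the four directions (this is what makes the texture features invariant
  under 90° rotations); 256 levels; symmetric, normalized. Out-of-mask
  pixels are assigned a reserved 257th level and every co-occurrence pair
  touching it is discarded before normalization, so background never
  contaminates texture. For a single-valued crop the correlation is
  defined as 0.
- Shannon entropy: base 2, from the 256-bin histogram of masked grayscale
  pixels.
- Shape: pixel-count area; contour-weighted perimeter; eccentricity of the
  second-moment-matched ellipse; solidity = area / convex-hull area (all
  via `skimage.measure.regionprops`).
- Spatial: r_mean = (1/n) Σ √(Aₖ/π) over the post-filter nuclei of the
  same image (per-image, not per-patient); crowding counts use inclusive
  centroid distances d ≤ x·r_mean, self excluded, multipliers
  {3, 5, 7, 9, 15, 20, 25, 30}; no border correction. Nearest-neighbor
  distance is NA when an image holds a single nucleus.
- Channel statistics use population standard deviation (ddof 0); only
  masked pixels enter any statistic.

## Aggregation

Nuclei are pooled across all images of a patient before summarizing, so an
image with more nuclei weighs proportionally more; mean and population
std per feature give 72 values. Per-feature NAs are dropped from that
feature's aggregate; an all-NA feature yields NA and a warning. A
single-nucleus patient gets std 0 (population convention — defined for all
n ≥ 1). `n_nuclei` is carried as metadata and never fed to classifiers.

## Classification

Preprocessing (median imputation, then optional quantile transform with
uniform target and n_quantiles = min(1000, n_train), then optional
standard scaling) is fitted on training folds only. Feature selection —
univariate χ² or greedy sequential forward selection (SFS, implemented
in-package as a scikit-learn `SelectorMixin`) — is fitted on the outer
training portion; the inner 4-fold stratified grid search tunes only the
classifier hyperparameters, mirroring the stated trade-off of keeping the
preprocessing / selector / classifier combination a fixed, reportable
configuration. χ² requires non-negative inputs, so features are min-max
mapped to [0, 1] on the training fold *for scoring only*. SFS ties are
broken by canonical column order, which makes selected sets nested across
k. Default hyperparameter grids (SVC: C ∈ {0.1, 1, 10, 100}, kernel ∈
{rbf, linear}, γ ∈ {scale, 0.01, 0.001}; KNN: k ∈ {3, 5, 7, 11}, weights ∈
{uniform, distance}; DT: depth ∈ {3, 5, 10, ∞}; LogReg: C ∈ {0.01, 0.1, 1,
10}; RF: {100, 300} trees × depth {5, ∞}; GNB: none) are representative,
config-overridable stand-ins; the binding contract is the nested-CV
mechanics. Grid-score ties resolve to the first grid entry.

Decision scores for ROC are the signed decision function where available,
else the positive-class probability. The untuned baseline configuration
(standard scaling, no selection, default SVC, empty grid) shares outer
splits with a tuned run at the same seed, so the two are directly
comparable. Patient-level majority voting over per-image predictions uses
the pessimistic tie rule: an exact 50–50 split is scored as the wrong
class.

All randomness flows from one top-level seed through a splitmix64-style
stream derivation (`model_selection.derive_seed`), giving independent,
reproducible child seeds for fold shuffling, quantile subsampling, model
initialization and the synthetic generator.

## Expert agreement

The rating c_i = max(c_iⁿ, c_iᵖ)/(c_iⁿ + c_iᵖ) ∈ [0.5, 1] is symmetric in
the two counts. Label derivation: re-reviewed cases are non-PTC-like below
13 PTC-like re-review scores, PTC-like above 15, and excluded on the
closed interval [13, 15] (the published protocol excluded cases at exactly
13 and 15 and never states how 14 would be handled; the closed-interval
rule keeps every count defined). Non-re-reviewed cases take the majority
vote; exact ties are excluded. Threshold subsets use inclusive comparison
(c_i ≥ t), so subsets are nested and sizes non-increasing in t.
Percentages are reported to one decimal.

## Synthetic generator

Defaults are fixed once: 256×256 px tiles, 10 patients per class, 2 images
per patient, 18–26 nuclei per image placed by a 4-cluster point process
with a minimum centroid separation of 1.7 r. Class presets (PTC-like vs
non-PTC-like): equivalent radius 13 ± 1.6 px vs 9 ± 1.1 px — roughly 6 vs
4 μm at a 0.23 μm/px working resolution, matching the enlarged-nucleus
criterion; boundary irregularity 0.22 vs 0.05 (harmonics 2–6 radial
perturbation, driving solidity/eccentricity apart); central clearing 1.7
vs 1.1 (center-to-border intensity ratio emulating chromatin clearing);
tighter clustering for the PTC-like class (scatter 22 vs 34 px). Colors
are hematoxylin purple (88, 60, 130) on eosin pink (235, 200, 215) with
Gaussian noise σ = 6 — purely cosmetic. Overlapping nuclei resolve by
later-placed-wins occlusion, and the ground truth records visible regions.
Vote tables draw each case's PTC-vote probability from a beta distribution
with class-dependent mean (0.85 / 0.15) and concentration 12 (lower ⇒ more
borderline cases), then binomial votes from a 24-rater panel.

The generator reproduces the *directions and magnitudes of contrast* the
morphometry is meant to detect, not real histology: no stain variation,
scanner artifacts, chromatin texture, overlapping tissue layers or
segmentation noise of a trained network. Passing tests therefore
demonstrate that the pipeline measures and classifies the intended
geometric/chromatic properties correctly — not that a particular accuracy
transfers to clinical slides, which additionally depends on upstream
segmentation quality and cohort composition.

## Problem sizes

The test suite uses a compact cohort (6 patients/class, one 224×224 tile
each) shared across tests; the acceptance script runs the generator
defaults (10 patients/class, two tiles each, ≈ 900 nuclei) for the
end-to-end experiment and a 20-permutation label-shuffle null with the
untuned baseline. These sizes were chosen as the smallest at which the
stratified 5-outer/4-inner fold structure and the class-separation checks
are statistically meaningful.

## Known limitations

- The baseline segmenter is a fixture tool; real H&E requires an external
  instance segmenter at the working resolution (0.23 μm/px by default;
  other resolutions are harmonized by order-3 spline rescaling).
- The exact composition of the 23 color features reconstructs the three
  named ingredient families (channel statistics, zone ratios, GLCM +
  entropy); the canonical order and the 23/4/9 counts are the binding
  contract.
- Headline accuracies on the two clinical cohorts the method was designed
  around are not reproducible here: they require the cohorts themselves
  and a trained segmentation network, both out of scope.
- Aggregation to mean/std discards higher distribution moments by design.
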