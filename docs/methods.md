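# Methods

## The classification problem

Breast ducts are lined by a myoepithelial cell layer whose nuclear
morphology changes with the histological state of the duct: in DCIS the
nuclei flatten into spindle shapes and their stain texture coarsens. The
pipeline quantifies each segmented myoepithelial nucleus with 32 shape,
texture and intensity features and trains a four-class RBF-SVM
(Normal / UDH / LG-DCIS / HG-DCIS). Because cells are labeled with their
duct's diagnosis (label noise is inherent — cells at different neoplastic
stages coexist in one duct), single-cell accuracy is modest by design;
duct- and patient-level weighted majority voting over the cell decisions
recovers high accuracy. All evaluation runs through confusion matrices,
overall accuracy, and Cohen's kappa, both for the four classes and after
collapsing to Benign (Normal + UDH) vs DCIS (LG + HG).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream stage is validated.

**Geometry.** Each ROI contains non-overlapping circular ducts.
Myoepithelial nuclei are ellipses centered on the duct boundary with the
major axis tangential. Per histotype, the full minor-axis length is
drawn from N(mean, sd) and the minor/major ratio from N(mean, sd) clipped
to (0.2, 1]; the per-duct count is capped so that tangential neighbors
cannot overlap. Proliferative histotypes (UDH, LG, HG) additionally fill
the duct with round luminal nuclei; Normal ducts keep an empty lumen.
Elongated fibroblast nuclei are scattered in the stroma and covered by
the exclusion mask (the synthetic analogue of manually masking
fibroblasts and necrosis).

**Class effect sizes.** Defaults encode a monotone Normal → HG-DCIS
trend: minor axis 14 / 13 / 11.5 / 10 px, minor/major ratio 0.75 / 0.70 /
0.60 / 0.52, texture-contrast amplitude 0.05 / 0.10 / 0.18 / 0.25, all
configurable per class. The ratio trend direction follows the
flatter-with-grade observation; magnitudes are package choices (per-class
population statistics are not published), so passing tests demonstrate
that the pipeline recovers *this* kind of effect structure, not the exact
effect sizes of any real cohort. Case-level biological variation jitters
the class means per case (sd 0.6 px minor axis, 0.03 ratio, 0.02
contrast), which makes patients within one class heterogeneous but still
separable.

**Rendering.** One geometric scene is rendered into both stains —
idealized serial sections with exact cross-stain correspondence and no
section-to-section deformation. Stain concentrations mix in optical
density: OD(pixel) = Σ_s c_s · v_s with unit color vectors v_s
(Ruifrok–Johnston hematoxylin, eosin, DAB), then I = (I₀+1)·10^(−OD) − 1
plus Gaussian pixel noise (default sd 2 grey levels). Nuclei carry
multiplicative smooth speckle with the class contrast amplitude;
background stain is displaced under nuclear chromatin so strongly stained
nuclei give near-pure stain pixels. In HE renderings all nuclei are
hematoxylin; in p63 renderings only myoepithelial nuclei are DAB-brown
over a light hematoxylin counterstain, so the brown signal is the
myoepithelial marker exactly as in p63 immunohistochemistry.

**Scale.** The full-size spec mirrors the study design: 22 cases
(7/5/5/5), 2174 px ≈ 1 mm ROIs (0.46 µm/px), 3 ROIs per case, 40–70
nuclei per duct, ~11k myoepithelial nuclei. The default *pipeline*
configuration is a proportionally scaled benchmark — 384 px ROIs, 2 ROIs
per case, 2 ducts per ROI, 9–14 nuclei per duct (~1k nuclei in total) —
chosen as the package's standard problem size so that a complete
two-stain run finishes in a few minutes on a single core. Both are plain
`CohortSpec` values; nothing in the code depends on the scale.

**What it does not emulate:** scanner color profiles, focus blur,
necrosis texture, overlapping/touching nuclei within the ring, ADH, or
section-to-section misalignment. Results on synthetic data therefore
bound segmentation difficulty from below; the segmentation accuracy
figures reported on real slides by the original analysis are not
reproducible here and are replaced by ground-truth-based detection
agreement and IoU properties.

## Stain model

RGB → OD uses OD = −log10((I+1)/(I₀+1)) per channel, clipped at 0
(default background I₀ = 255). Stain vectors are estimated per ROI by a
deterministic plane fit (the original analysis used an unpublished
trained color predictor): uncentered SVD of pixels with ‖OD‖ > 0.08
yields the dominant plane; the two stain vectors are the 1st/99th
angular-percentile directions of the pixel cloud within that plane
(Macenko-style). The hematoxylin-like vector is ordered first — larger
blue OD component, with near-ties (Δ < 0.05) broken by the larger red
component, which robustly separates hematoxylin from eosin. Rank-1 OD
clouds are treated as one-stain images: the principal direction is
returned first and an in-plane orthogonal placeholder second with
`confidence < 0.5`; achromatic (grey) clouds raise an error since they
have no stain plane. Projection is the per-pixel dot product with the
unit vector, clipped at 0 — linear in OD by construction.

## HE segmentation

Detection runs on the estimated hematoxylin projection normalized by its
99.5th percentile. Three response maps are computed: DoG(σ, 1.6σ) at
σ = 2.5 and 5 px, and a circular Hough transform (radii 8–20 px) of the
Canny edges. Each map is expressed on a [0, 1] scale where 1 is an ideal
detection: the DoG maps are divided by 0.3336 — the center response of a
DoG(σ, 1.6σ) filter to a perfectly matched unit-amplitude disc, which is
independent of σ — and the Hough accumulator is already normalized (1 = a
full circle of edge votes). A min–max stretch would instead promote
off-scale edge-band noise to full strength. The maps are aggregated by
pixelwise maximum, thresholded (floor 0.25), and local maxima become
candidates; greedy non-maxima suppression (8 px) follows. Defaults match
nucleus diameters of ~5–15 µm at 0.46 µm/px; none of these operator
parameters were published, so all are configurable.

Per candidate, the map is resampled on 72 rays × 30 radii (bilinear,
edge-extended). "Snake" tracking is implemented as an exact circular
dynamic program rather than an iterative active contour: the cost of
(ray, radius) is the negative magnitude of the radial gradient
(normalized to [−1, 0]), transitions are limited to |Δr| ≤ 2 px with an
elasticity penalty λ|Δr| (λ = 0.12), and closure is enforced exactly by
solving the DP once per admissible start radius (vectorized over start
states). λ → ∞ yields a perfect circle; an all-flat polar sample raises
"no boundary evidence". Contours are star-shaped by construction (one
radius per ray), hence simple polygons with exactly `n_rays` vertices.

## p63 segmentation

An Ilastik-style fixed feature recipe: per pixel, raw RGB plus
Gaussian-smoothed value, gradient magnitude and Laplacian per channel at
scales {1, 2.5, 5} px (30 features). A 100-tree random forest is trained
once on sparse labels from a single DCIS ROI (eroded nuclei vs far
background, boundary band unlabeled, ≤20k samples per class) and applied
to every other ROI. Post-processing: threshold the nucleus probability at
0.5, fill holes, connected components, drop components < 30 px or with
centroid in the exclusion mask, and trace each component boundary as its
contour. Touching-nuclei splitting is deliberately not attempted; merged
blobs land in the size tails that the trim rule removes. Raising the
probability threshold could in principle split a blob into two
components; on the unimodal probability blobs this classifier produces,
the nucleus count is monotone non-increasing in both the threshold and
the area floor (verified on fixtures).

## Morphometry

The 32-feature manifest is fixed in code (shape 13, Haralick 13,
intensity 6) and covers every named discriminative feature (MinorAxisLength,
MinFeretDiameter, MinorMajorRatio, Contrast, InverseDifferenceMoment,
DifferenceEntropy, ...). Conventions:

* Axis lengths come from the second central moments of the rasterized
  mask (4·√eigenvalue). Feret diameters use rotating calipers on the
  convex hull of pixel *corners* (each pixel treated as a unit square).
* All lengths are in pixels; the µm/px scale (0.46) travels as metadata.
* GLCM: per-nucleus min–max quantization to 8 levels (making texture
  features invariant to affine intensity rescaling), co-occurrences
  accumulated only over pixel pairs fully inside the mask, the four
  distance-1 offsets symmetrized and averaged. Natural logarithms.
  Degenerate single-level patches: Contrast 0, IDM 1, entropies 0,
  ASM 1, Correlation pinned to 0 (undefined at zero variance).
* Intensity features are computed on the grey-level stain projection
  (hematoxylin map for HE, DAB map for p63), not on raw RGB.
* The trim rule ranks by Area *within each ROI* and drops
  floor(0.1·n) from each end — per-ROI because the rule targets
  ROI-level contour noise; whether the original trim was per-ROI or
  global is unrecorded.

## Classification

Normalization (mean/SD), F-score ranking and the (C, γ) grid search use
training rows only; the test transform reuses training statistics
(zero-variance features pass through with scale 1). The multi-class
F-score is Σ_c(x̄_c − x̄)² / Σ_c s²_c with n−1 within-class variances;
+∞ flags zero-variance perfect separation. The canonical grid is
C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} in powers of 4 with 5-fold stratified CV
(ties → smallest C, then smallest γ); the pipeline's default grid is a
coarser sweep of the same exponential lattice (C ∈ 2^{−3,0,3,6,9},
γ ∈ 2^{−9,−7,−5,−3,−1}) since it re-tunes per split repetition.
Multi-class handling is one-vs-one voting. The 70/30 protocol splits at
cell level, stratified by class, exactly 5 times; the case protocol
holds out 1 of 22 cases, 10 times without replacement. All 32 features
are used by default (feature selection is exposed via the ranking, and
using all features is the expected optimum).

## Aggregation and evaluation

Group proportions are normalized class histograms of cell predictions
per duct (ROI-level group) and per patient. The weighted majority
decision is argmax of proportion × weight; the published method does not
define its weights, so two reconstructions are exposed: reciprocal
training-class frequencies (default — the nucleus counts are strongly
imbalanced) and uniform. Ties break toward the more severe class
(clinically conservative, deterministic). Scaling all weights by a
positive constant never changes a decision.

Accuracy is 100·trace/total rounded half-up to 1 decimal; kappa to 2
decimals — the rounding convention of the benchmark tables, which the
evaluation layer reproduces exactly from the bundled counts. Repeated
splits are pooled into one confusion matrix by default (`pooling:
"mean"` averages per-repetition metrics instead; which convention the
original tables used is not recorded). Detection agreement is a
reconstruction — mean per-ROI 100·(1 − |detected − reference|/reference),
clipped at 0 — used only against synthetic ground truth.

## Known limitations

* Synthetic nuclei never touch or overlap within a ring, so the trim
  rule's main real-world target (merged contours) occurs only via
  segmentation artifacts.
* Stain projection is not spectral unmixing: hematoxylin-stained nuclei
  have a nonzero DAB projection (the vectors are ~37° apart). The p63
  path relies on the random forest, not on thresholding the projection.
* The HE path detects *all* nuclei; restriction to myoepithelial cells
  uses ground-truth identity, standing in for the manual picking against
  the paired p63 image that real data requires.
* Case-level variation is Gaussian jitter of class means; real
  inter-patient heterogeneity (mixed-grade lesions, staining batch
  effects) is richer, so end-to-end accuracies here are upper bounds.
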