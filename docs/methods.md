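# Methods

This note documents the models, parameter choices and limitations of
`akstage`, in the order the pipeline runs.

## Phantom generator (`akstage.synthetic`)

**HFUS model.**  A B-scan phantom is a stack of horizontal tissue
bands: an echo-free gel zone (mean intensity 4), the entry echo
(mean 200), an optional SLEB, and dermis (mean 120), on a 256 × 128
grid by default (rows = depth; the clinical-resolution 512 × 224 /
3024 px variant is available via `PhantomParams.at_full_scale()`).
Band boundaries are smooth random curves; the per-lesion entry-echo
thickness is drawn from a stage-dependent normal distribution and the
lower boundary carries stage-dependent waviness.  Speckle is
first-order only: pixel = layer mean × ((1 − w) + w·R) with R a
mean-one Rayleigh variate, mildly smoothed for lateral correlation,
clipped to 8 bits.  With w = 0 the image is exactly piecewise constant,
which the tests exploit.  This is a texture proxy, not an acoustic
simulation — no point-spread function, attenuation, or shadowing.

**Encoded stage trends** (the quantities the downstream analysis is
meant to recover):

| parameter | stage 1 | stage 2 | stage 3 | drives |
|---|---|---|---|---|
| entry thickness mean (px) | 12 | 16 | 22 | thickness statistics ↑ |
| entry boundary roughness (px) | 1.5 | 3 | 5 | roughness/Q3 ↑ |
| entry speckle weight w | 0.22 | 0.34 | 0.46 | entry entropy ↑ |
| SLEB mean intensity | 56 | 46 | 38 | SLEB/dermis ratios ↓ |
| SLEB speckle weight w | 0.15 | 0.40 | 0.65 | SLEB GLCM homogeneity ↓ |

The SLEB noise spread is deliberately wide: the falling SLEB mean
shrinks the *absolute* speckle amplitude, and a narrower weight spread
does not produce a monotone homogeneity trend after 32-level
quantization.  SLEB presence probability is 0.9; absent SLEBs carry
explicit missing features downstream.

**Dermatoscopy model.**  A stage-coloured lesion disk on skin
background: pink-red pseudonetwork (stage 1), erythematous base with
yellow keratinized follicle dots (stage 2), bright white-yellow scale
with strong texture (stage 3) — so lesion brightness and texture
amplitude rise with stage.  Artifacts with exact ground-truth masks:
dark round-corner frame, ruler ticks, and 4–12 Bézier-curve hairs of
width 3–7 px, dark (intensity 20–55) or light (228–250).  Default
canvas 512 × 512.

**Cohorts.**  Lesions are dealt to patients round-robin, so patients
hold multiple stages.  The default composition is the clinical one —
92/42/27 lesions over 54 patients; note these counts sum to 161 while
the source dataset's printed total is 162 (the generator logs this
discrepancy rather than resolving it).  All generators are pure
functions of (params, stage, seed).

## Segmentation (`akstage.segmentation`)

A compact CFPNet-style U-net implemented in NumPy (im2col convolutions,
hand-written backward passes, Adam): a 3×3 stem at full resolution,
two encoder stages of contextual-feature-pyramid blocks (parallel 3×3
convolutions at dilations 1/2/4, concatenated, fused 1×1) at 1/2 and
1/4 resolution, and a decoder with skip concatenations.  1×1
projections ahead of the 3×3 decoder convolutions keep the full-
resolution convolutions narrow — a throughput choice that costs no
measurable Dice on phantoms.  Default widths (8, 16, 32) give ~19k
parameters; everything is exposed in `SegModelConfig`.

Training: cross-entropy plus class-mean soft Dice (the Dice term keeps
gradients alive for the thin foreground bands), Adam at 2e-3, batch 4,
He initialization; one model per patient-grouped fold, trained only on
its split (asserted).  Optional pre-training accepts any compatible
checkpoint via `CFPNetM.load` / the `pretrained` argument; for phantom
experiments it is unnecessary.  Inference keeps the largest connected
component per layer, gives the entry echo priority where classes
overlap, flags an empty entry-echo prediction as degenerate (never
silently), and derives the dermis reference geometrically — a band of
50 px (configurable) directly below the lower SLEB boundary, or below
the entry echo where the SLEB is absent — since only the entry echo
and SLEB are predicted by default (`n_classes=4` predicts it instead).
Dice of two empty masks is defined as 1.0 — agreement on absence —
and logged when it occurs.

Desk-scale problem size: 40 phantoms, 4 patient-grouped folds, 20
epochs at 256 × 128 reach held-out Dice ≈ 0.99 (entry echo) and ≈ 0.97
(SLEB) in a few minutes on one CPU; the package makes no claim that
those values transfer to clinical scans.

## HFUS features (`akstage.features`)

Naming scheme `modality.family.region.stat`, e.g.
`hfus.glcm.sleb.contrast`.  Conventions, all config-exposed:

* **Morphology** — per-column thickness mean/sd/min/median/Q1/Q3,
  boundary roughness (SD of the per-column lower-boundary row), SLEB
  depth (per-column max and mean of its lower boundary).  Perimeter is
  the count of exposed 4-neighbour pixel edges, so a solid n×n square
  has perimeter 4n and a single pixel 4; perimeter-to-area divides by
  the pixel count.  Lengths are in pixels; `*_mm` variants appear only
  when pixel-size metadata exists.
* **Echogenicity** — LEP/MEP/HEP fractions with cuts at 30 and 150 on
  the 8-bit scale (conventional HFUS banding; the bands partition
  [0, 255] and the three fractions are nudged by the float rounding
  residual so they sum to exactly 1.0).  SLEB statistics are divided
  by the dermis-reference statistics (`*_over_dermis`); a zero dermis
  denominator yields NaN with a warning.
* **Histogram** — mean, SD, skewness, Fisher kurtosis, Shannon entropy
  (256 bins, log₂).
* **GLCM** — 32 levels over [0, 256), distance 1, offsets 0°/45°/90°/
  135°, symmetric and normalized, statistics averaged over offsets.
  Pairs are restricted to pixels both inside the mask via a sentinel
  gray level.  A constant region has correlation 1 by convention.
* **LBP** — uniform patterns, radius 1, 8 points; codes histogrammed
  only where the full neighbourhood lies inside both the mask and the
  image (the mask is padded with background before erosion — scikit-
  image's erosion alone would keep border pixels).
* **Scattering** — in-package Morlet scattering transform, 2 dyadic
  scales × 6 orientations, order 2 (49 paths), computed on the mask
  bounding box (background replaced by the in-mask mean) resampled to
  64 × 64, globally average-pooled; global pooling provides the
  translation stability the tests check.

Regions too small for an operation yield NaN (missing), as do all SLEB
features of SLEB-free lesions; imputation happens only inside the
classifier's training folds.  Every feature depends only on pixels
inside its mask (a padding-invariance test enforces this).

## Dermatoscopy pipeline (`akstage.dermoscopy`)

**Frame/background removal**: percentile contrast stretch; frame
pixels must be dark both relative to the stretched range (< 0.22) and
absolutely (< 0.25 of full scale — lesion borders are relatively dark
but never near-black), opened with a disk of radius 5 so thin dark
hairs are not mistaken for frame; 2-cluster fuzzy c-means on
(intensity, local sharpness) drops a background cluster only when it
is both markedly blurrier than the other (ratio < 0.35) and essentially
structureless (mean sharpness < 0.015) — sharp frameless images
survive intact; finally the largest component containing the image
centre, holes filled.

**Hair/ruler removal** (dual-polarity DullRazor): grayscale closing
detects dark structures and opening light ones, with linear
structuring elements of length 15 px at 0°/45°/90°/135°; candidate
pixels where the strongest directional response exceeds 10 intensity
units.  Directional closing also fills the space *between* nearby
hairs, so the raw candidate blob is thicker than the hairs: thick
cores (opening by a disk of radius 6) are stripped, the remaining thin
segments are kept when elongated (major/minor ≥ 4) or long
(major ≥ 30 px), and accepted segments are grown back inside the
candidate mask by morphological reconstruction — this handles networks
of crossing hairs whose merged component is not elongated, while
compact keratotic follicles fail both tests.  The mask is dilated 2 px
and inpainted by neighbourhood diffusion (Jacobi relaxation of the
3×3-mean equation with the surrounding image fixed), which converges
quickly for thin structures.  A hairless image is returned untouched,
byte for byte.

**Channels**: R, G, B plus H, S, V, each scaled to [0, 255] (hue
mapped linearly from its circular range).  Handcrafted texture
features reuse the HFUS texture operations per channel inside the
valid region.

**CNN features**: the extractor interface is deterministic
image → vector; features are the activations of the last fully
connected hidden layer.  The bundled desk-scale extractor is a small
NumPy CNN (3 conv stages, global average pooling, 24-unit FC) trained
in-repo to separate AK phantoms from lesion-free skin phantoms — the
same "train on AK-vs-not, reuse for staging" transfer idea at phantom
scale.  Externally trained checkpoints load through
`SmallCNNExtractor.load`; reproducing published large-scale extractor
weights is out of scope.

## Staging classifier (`akstage.classify`)

Outer loop: leave-one-patient-out.  Per training fold, in order:
median imputation (training medians; all-missing columns dropped),
z-score with the sample (n−1) SD (constant columns map to zero with a
warning), greedy MRMR ranking, joint selection of the feature-count
cutoff and SVM hyperparameters by 5-fold patient-grouped inner CV,
SMOTE, RBF-SVM (one-vs-one), prediction of the held-out patient.

MRMR uses the difference criterion: relevance − mean |Pearson r| with
already-selected features.  Relevance is the one-way correlation ratio
(ANOVA η²) rather than the raw F statistic: η² is bounded in [0, 1]
and therefore commensurate with the redundancy term, so an exact
duplicate of a selected feature (redundancy 1) falls behind every
feature that adds information — with unbounded F the redundancy
penalty is negligible and duplicates rank immediately after their
originals.  F and η² are monotonically related at fixed group sizes,
so the first-ranked feature is identical under either.

SMOTE draws synthetic minority samples x + u·(x_nn − x), u ~ U(0, 1),
x_nn among the k = 5 same-class nearest neighbours (k reduced to
class size − 1 when smaller); originals are always kept; single-member
classes raise unless duplication is explicitly allowed (the duplication
fallback is on inside the full experiment, where tiny inner folds can
isolate a class).  The SVM grid is C ∈ {0.1, 1, 10, 100} and
γ ∈ {0.1, 1, 10} × the scale heuristic 1/(n_features · Var(X));
candidate feature counts default to {5, 10, 20, 40}.  Ties break
toward the smallest feature count, then smallest C, then smallest γ —
reproducibility over any other rule.  Reported feature count is the
mode across folds (per-fold counts are kept too, since the fold-wise
optimum may vary).

No step ever sees held-out rows.  Beyond construction, this is checked
by a leakage canary: `select_and_classify(..., leakage_canary=col)`
overwrites that column with the true stage *on the held-out rows only*
at the start of each fold — a leak-free pipeline stays at chance
accuracy, any fit on test rows would exploit the canary.  The
complementary ceiling check (a genuinely informative feature) must
reach accuracy ≈ 1.

Unweighted Cohen's kappa follows the standard formula; for count
matrices chance agreement p_e = 1 only when observed agreement is also
1 (then κ = 1), but a defensive 0.0-with-warning branch exists.
Agreement bands: < 0 none, ≤ 0.20 none-to-slight, ≤ 0.40 fair,
≤ 0.60 moderate, ≤ 0.80 substantial, else almost perfect.

## Group statistics (`akstage.stats`)

Kruskal–Wallis (tie-corrected, χ² approximation) per feature at
α = 0.05; effect size η² = (H − k + 1)/(n − k), floored at 0, with
qualitative bands small/medium/large at 0.01/0.06/0.14; Dunn's
post-hoc z from mean ranks with tie correction, two-sided p values
Bonferroni-multiplied by the number of pairs.  **No multiplicity
correction is applied across features at the screening stage** — each
feature is reported with its own raw Kruskal–Wallis p value, and
Bonferroni applies only within each feature's pairwise Dunn family;
readers screening many features should account for this.  The
screening set is tag-based (morphology, echogenicity, histogram, GLCM
by default) and configurable.

## What the phantoms do and do not show

The phantoms encode the stage trends directly and cleanly, so the
staging experiment saturates (accuracy ≈ 1 on 90 lesions) — the
meaningful results are the *contrasts*: encoded features are flagged
by the screen with the (1,3) Dunn pair significant, permuted labels
drive kappa to ≈ 0, the canary stays at chance, preprocessing recovers
the injected artifacts (frame IoU ≥ 0.95, hair recall ≥ 0.8,
inpainting strictly reduces error), and the Kruskal–Wallis type-I rate
is calibrated.  None of this demonstrates clinical performance: real
HFUS speckle, device-dependent gain, lesion heterogeneity, hair/scale
confounds and inter-rater label noise are all absent.  Cross-device
intensity calibration is explicitly out of scope.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to keep a full
cycle in minutes on one CPU: 40-phantom / 4-fold / 20-epoch
segmentation, 30-patient / 90-lesion staging cohorts, 1000-replicate
calibration loops, 5-phantom preprocessing scores.  All randomness
flows from one seed through named, CRC-derived substreams
(`akstage.pipeline.substream`); identical seeds give bit-identical
phantoms, fold assignments, training trajectories and reports.
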