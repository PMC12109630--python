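# Methods

## The problem

Prostate adenocarcinoma arises almost entirely from glandular
epithelium. Quantitative nuclear imaging of Feulgen-Thionin-stained
biopsies (a DNA-stoichiometric stain: absorbance is proportional to DNA
content) can grade biological aggressiveness cell by cell, but those
analyses need to know whether each nucleus sits in a gland or in the
stroma — and manual gland annotation does not scale. This package
implements a cell-centric recognition workflow: every segmented nucleus
becomes a square image patch centered on that nucleus, a convolutional
classifier assigns each patch a gland probability, and a two-round
semi-supervised loop corrects a specific, structured annotation defect.

Nuclei segmentation itself is out of scope; segmentation output
(centers + boundary polygons) is a pipeline input.

## Patch geometry

Coordinates are 0-based `(row, col)` with half-open patch extents. An
even patch of size *s* has no true center pixel; the convention here is
that the nucleus center occupies index `floor(s/2)` on each axis, which
is self-consistent across sizes (a 128 and a 256 patch of the same
nucleus have offsets differing by exactly 64 per axis). The slide is
mirror-padded by *s*/2 before cutting so border nuclei yield full-size
patches without black bands that would bias the classifier.

A nucleus is labeled **gland** iff its center lies inside or on the
boundary of any annotated gland polygon (inclusive point-in-polygon via
shapely, cross-checked against a ray-casting oracle in the tests).
Boundary-overlap voting was rejected for simplicity and determinism; how
the original annotators handled exactly-on-border nuclei is unknown, so
the inclusive convention is a documented divergence risk.

Cohort splits are always at the biopsy level (largest-remainder
rounding, seeded shuffle), never at the cell level, so no biopsy
contributes nuclei to two cohorts.

## The container

Patches, boundaries, offsets, labels and predictions live in a single
appendable per-biopsy binary container (`docs/cmg_format.md` is the
normative layout). Write–read round trips are byte-identical, and
reconstruction restores every covered pixel exactly when the patches
came from one source image; both properties are enforced by tests.

## The classifier

GlandNet is a VGG16-lineage stack: five convolution blocks
(2+2+3+3+3 = 13 conv layers, 3×3, stride 1, same padding) each followed
by 2×2 max pooling, then global average pooling and a dense head
`dense → Gaussian noise → dense → Gaussian noise → dense(2) → softmax`
— 24 layers, 16 of which carry weights (13 conv + 3 dense). Block
widths default to the canonical 64/128/256/512/512 progression and head
widths to (256, 64); all widths are configuration, and a `width_scale`
multiplier shrinks them uniformly (layer sequence invariant) for
desk-scale runs.

The engine is a small hand-written numpy layer stack with explicit
backpropagation and Adam (β₁ = 0.9, β₂ = 0.999), verified against
finite-difference gradients. Hidden activations are leaky ReLU with
slope 0.1: at narrow scaled widths a strict ReLU stack of this depth can
collapse into a dead all-negative state with zero gradient flow, and the
leaky slope removes that failure mode; at full width the choice is
essentially inert.

Training uses weighted categorical cross-entropy
`−Σ w_i·y_i·log(p_i)` with probabilities clipped to `[1e−12, 1−1e−12]`.
Class weights default to inverse class frequency on the training cohort
(gland runs at roughly one third of nuclei), countering the class
imbalance. Softmax is stabilized by max-subtraction. A nucleus is
called gland iff its probability is **strictly greater** than the
decision threshold τ = 0.5 (ties go to stroma).

Augmentation (flip → rotate ≤ 45° → zoom ±20% → shift ±20%, mirror
fill, order fixed) and input standardization (per-dataset mean/std of
the training patches, stored on the model) are applied at train time.
Pretrained convolutional initialization is supported only from a
user-supplied checkpoint — nothing is downloaded — and seeded random
init is the default everywhere.

Full-scale defaults mirror the reference recipe (lr 1e−5, batch 128,
100 epochs, head-noise σ 1.0–1.5, constant lr). The desk-scale preset
(`TrainConfig.desk_scale`) trains the width-1/8 network from random init
on a few hundred patches, which needs a hotter but damped optimizer:
lr 4e−4 with cosine decay, batch 32, 14 epochs, gradient-norm clipping
at 5, flips-only augmentation, and head-noise σ scaled to 0.1 (σ = 1
noise would swamp the O(0.5) activations of the narrow head). The
final-epoch weights are kept by default; best-validation-epoch selection
is available as configuration.

## Synthetic tissue

Real biopsies cannot be shared, so the generator renders scenes with
known truth: glands as rings of near-round nuclei (semi-axes ≈ 4.5–6 ×
3.5–4.8 px, radially oriented) around an empty lumen, inside an
annotated circular gland polygon; stromal nuclei elongated (≈ 2.5:1)
and sparser, strictly outside every gland polygon. The image is a pale
background (215) minus rasterized nuclear densities (80–140, additive
where nuclei overlap, as DNA absorbance is), Gaussian-blurred (σ 0.8)
with additive noise (σ 4), 8-bit. Scenes are rendered at 1.316 µm/px —
4× coarser than the 0.329 µm/px scanner sampling — so a 64-px desk patch
covers the same ~84 µm field of view as a full-scale 256-px patch. The
default scene (384² px, 4 glands, ~160 nuclei) runs at about one third
gland nuclei, matching the real cohorts' prevalence. A small-gland
preset (ring radius 13–19 px, 6–9 nuclei) covers the regime where
recognition errors concentrate.

Ground-truth labels equal the patching module's own labeler on every
rendered nucleus by construction (placement margins exceed the polygon
discretization error), and this is asserted in tests.

Annotation misses are injected one-sidedly: exactly `round(q·n_gland)`
gland labels flip to stroma, chosen uniformly under a seed; stroma truth
never flips. The flipped set is returned as hidden truth.

What the generator does **not** emulate: real stain and focus
variability, nuclear texture/chromatin structure, touching/overlapping
nuclei with segmentation errors, distorted gland architecture, and
scanner optics. Passing tests therefore demonstrate the machinery and
the direction of the semi-supervised effect under controlled conditions,
not clinical-grade performance on patient material.

## Two-round semi-supervised training

Round 1 trains on the (possibly defective) human labels. On the
validation cohort, every nucleus annotated stroma but predicted gland at
τ (the same 0.5 as classification; configurable) is harvested and
appended to the training set as a hard pseudo-positive — provenance
`round-1-pseudo`, original human label retained immutably. Round 2
retrains from scratch with the same seeded init (warm start available
but off: the procedure is a retrain). Relabeling is strictly one-sided
(stroma → gland); the ledger enforces conservation (round-2 set =
round-1 set ∪ harvest) and an empty harvest degenerates to an identical
retrain, which with identical seeds reproduces round 1 exactly. A
soft-label mode and k > 2 rounds exist behind flags but are off by
default. Only validation-cohort false positives are harvested by
default; in-place relabeling of training nuclei is the non-default
alternative.

## The recovery experiment

`glandcell.experiments.recovery_trial` freezes the desk-scale protocol:
width-1/8 model on 64-px patches; two standard scenes for training; one
standard plus two small-gland scenes for validation (small glands give
the round-1 model measurable room to improve, mirroring where the
full-scale study found its mislabeled false positives); miss rate q
applied to every cohort's annotation; FNR of each round evaluated on the
validation cohort against the hidden truth. Across seeds 0–4 and
q ∈ {0.1, 0.2, 0.3}, round-2 FNR is not worse than round-1 FNR in at
least 4 of 5 replicates per q, and the pooled harvest precision exceeds
q — the directional analogue of the reported full-scale FNR drops,
with no claim about their magnitudes.

## Evaluation

Gland is the positive class in every entry point. The eight-statistic
ledger (accuracy, SN, SP, PPV, NPV, FNR, FPR, F1, as percentages)
reports zero-denominator statistics as undefined (`None`), never 0, so
biopsy-set averages — which are unweighted means over biopsies — are
not silently inflated. ROC sweeps the distinct scores descending with
tied scores moving as one block; the trapezoid AUC then equals pairwise
concordance with ties counted ½ (verified against an O(n²) oracle).
AP is the step sum Σ(R_i − R_{i−1})·P_i; with all scores tied it equals
the positive prevalence. Overlays color each nucleus by outcome
(red TP, blue TN, green FN, magenta FP). Observer consensus intersects
all observers' best-k (worst-k) lists.

## Numerical and degenerate-input choices

* Max-pool ties resolve to the first index (deterministic).
* All randomness flows through explicit `numpy.random.Generator`
  seeds; training, rendering and the pipeline are bit-reproducible
  under fixed seeds on a fixed BLAS configuration.
* Containers accept uint8 and float32 rasters, 1 or 3 channels;
  mixed dtypes within one container are rejected.
* `p = τ` classifies as stroma (strict inequality).
* Probabilities are clipped before logs; softmax underflow at extreme
  logit gaps may round to exactly 0/1 in float64.
* Degenerate polygons (< 3 vertices, self-intersecting) are rejected at
  construction.

## Known limitations

* The published headline accuracies were measured on a private
  110-biopsy cohort and are not reproducible here; the published metric
  tables are carried as reference data for internal-consistency checks
  only.
* The desk-scale network is trained on hundreds of patches, versus
  ~1.26 M full-scale; its absolute accuracies on synthetic scenes say
  nothing quantitative about patient material.
* Harvest precision at low miss rates is bounded by the round-1 false
  positive rate on genuine stroma; the procedure assumes annotation
  misses are one-sided, and would amplify errors if stroma labels were
  also wrong.
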