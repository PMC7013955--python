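# Methods

This note documents the models and procedures implemented in `kelpcover`,
the parameters that matter, the numerical conventions, and what the
synthetic data can and cannot show.

## Data model

The unit of everything is the *annotated point*: a pixel (x, y) of a survey
image, 0-based with x the column and origin at the top-left, carrying a
class label plus image/site/year/depth metadata. An `AnnotationTable` is an
ordered list of such points; row order is the join key to the feature
matrix, and `(image_id, x, y)` triples are unique. "Up to 50" points per
image means the table stores what exists — there is no padding.

The class hierarchy is a rooted tree whose nodes own disjoint sets of leaf
labels; `subtree_labels(t)` is the union over t and its descendants.
Sibling subtree label sets are disjoint and union to the parent's set.
Labels absent from the hierarchy (real inventories run to ~145 labels while
a kelp-focused tree covers a few nodes) are excluded from node training
sets, with the excluded count reported rather than silently dropped.

## Enhancement

Underwater images are blue-green shifted; each colour channel is stretched
independently. With P pixels per channel and tail size k = ⌈0.01·P⌉, let L
be the mean of the k smallest intensities and H the mean of the k largest;
the output is clip((I − L)/(H − L), 0, 1). Two conventions deserve note,
both configurable:

- The bright reference is read as the *top-1% tail mean* (default). The
  alternative reading — the mean of everything above the bottom tail — is
  available via `StretchParams(high_mode="all_but_low")`. The default is
  the standard percentile stretch and maps the bright tail to 1.
- The divisor is H − L (post-subtraction), not raw H, so a constant channel
  is cleanly degenerate: if H − L < ε (default 1e−6) the channel returns
  all zeros.

The stretch is monotone per channel and invariant to per-channel affine
rescaling of the input. Enhancement is applied whole-image, before patch
extraction.

## Patches

Patches are S × S (S = 224 for backbone features; the test surface uses
S = 32, see below), S a positive even integer. The source pixel sits at
patch index (S/2, S/2); the patch spans the half-open ranges
[c − S/2, c + S/2). Border points are completed by edge-inclusive mirror
padding (a corner patch is mirror-symmetric about the corner), or by
constant fill for ablation. The centre-pixel identity
`patch[S/2, S/2] == image[y, x]` holds for every in-bounds point.

## Features

The reference pathway taps a pretrained residual backbone at the output of
its last convolutional block — deliberately *not* the final fully connected
layer, which is specific to the pretraining classes — and collapses the
7 × 7 × 2048 grid with a channel-wise global max pool to a 2048-D vector.
`global_max_pool` is exact and spatially permutation-invariant. The backbone
itself is a plug-in callable (patch → activation grid); nothing in the
package downloads weights, and the absence of a backbone raises a clear
error naming the self-contained alternatives:

- **handcrafted** (52-D, default): per-channel mean/std/10th/50th/90th
  percentiles, an 8-bin orientation histogram of gradient energy, and
  band-pass texture energies (RMS detail after Gaussian smoothing at
  σ = 1, 2, 4), each computed over the full patch and over its centre
  half-crop. The centre window ties the descriptor to the annotated pixel's
  own class when a patch straddles a class boundary.
- **random_projection**: a seeded Gaussian projection of the flattened
  pixels; a structure-free control.

All extractors are pure functions of (patch, spec). Features are not
normalised or standardised by default; `l2_normalize` is available behind a
flag and the choice is recorded in the model artifact via the extractor id,
which models check at prediction time.

## Classifiers

One binary linear SVM per non-root hierarchy node. For target node t:
positives are rows with labels in L(t); negatives are all other assigned
rows (*inclusive*) or only rows under parent(t) outside L(t) (*sibling*).
Sibling training sets are subsets of inclusive ones with identical
positives — sibling models train faster but face only the look-alike
classes. A *flat* model is a single one-vs-all SVM over all leaf labels
with ties broken toward the lexicographically first label.

The regularisation constant is selected from the grid
{0.01, 0.1, 1, 10, 100} by stratified 3-fold cross-validation on mean fold
accuracy, ties toward the smallest C, then the model is refit on all
training data. The 5-point log grid is the standard choice for linear SVMs
on deep features; the fold shuffling is seeded, so training is
deterministic given (data, config, seed). Classes with fewer samples than
folds raise a stratification error naming the class; nodes with an empty
class are skipped and listed on the model. No class reweighting is applied
by default (imbalance is a property of the data the evaluation is meant to
expose); `class_weighting="balanced"` exists for experimentation.

The decision threshold is fixed at 0 and a score of exactly 0 counts as
positive; no probability calibration is performed.

Prediction modes: `node_only` applies one node's classifier to every row —
the mode used for node-level evaluation — and `top_down` descends from the
root, following at each level the highest-scoring accepting child and
stopping at the deepest accepting node, which makes predictions
hierarchy-consistent by construction.

**Evaluation populations.** An inclusive model is scored on all test rows.
A sibling model is scored on the test rows whose true label lies in the
parent's subtree — the population it was trained to discriminate within.
This convention makes the sibling score a within-look-alikes measure
(harder, typically lower accuracy but higher focal recall); both
populations can be computed if the other reading is wanted.

## Metrics

Accuracy, per-class precision/recall/f1 with f1 = 2PR/(P+R), mean f1 over
the classes present in the test data, and the focal class's precision and
recall. Every 0/0 is defined as 0 — necessary for long-tail flat evaluation
where many classes have no true positives. Mean f1 under a long tail
collapses toward zero while accuracy stays high; the package reports both
precisely so that gap is visible.

The paired classifier comparison draws n point indices (default 50,000,
capped at the rows available) without replacement, seeded, and runs a
two-sided paired t-test on the per-point correctness differences. The
sampling unit is the labelled point, the classification unit. Zero-variance
differences are handled explicitly: identical performance gives t = 0,
p = 1; a uniform difference is flagged degenerate with p = 0.

## Coverage

Per-image cover of a focal node is the fraction of that image's points
whose label (expert) or prediction (estimated) falls in the focal subtree,
both computed over the identical point set. For hierarchical predictions a
point counts as focal when the focal node lies on its accepted path — cover
estimation therefore uses top-down routing, so a point rejected at the
macroalgae node can never count as kelp. Agreement is OLS of estimated
(response) on expert (predictor) cover, per group and pooled, with R² and a
95% slope CI; fits require ≥ 3 images and non-constant expert cover, else a
degenerate-fit error. Group mean covers are reported in percent,
unweighted over images by default (point-weighted behind a flag; with a
fixed points-per-image design the two coincide).

## Synthetic surveys

The generator emulates the *statistical* structure of a point-annotated
benthic survey, not its photographic appearance. Each scene is rendered by
letting classes claim pixels from smoothed random fields (anisotropic for
blade/frond macroalgae, fine-grained for turf and substrate), so regions
are contiguous blobs and the realized cover of every class is exact to one
pixel of rounding. Colours get zero-mean within-class texture plus a
multiplicative illumination ramp. The confuser class interpolates linearly
in colour, texture kind and scale from a clearly distinct brown alga
(similarity 0) to a visual twin of kelp (similarity 1). Rare classes are
small sand-toned sprinkles forming a long tail of scarce, hard labels.
Points are uniform random distinct pixels labelled from the class map; an
optional expert-error rate flips labels of boundary-adjacent points to the
neighbouring class, emulating expert misclassification at class edges
(off by default). An entire survey — scenes, covers, sites/years, points —
is a pure function of one master seed.

Default study conditions: 200 images of 192 × 192 px, 50 points per image,
six classes with the confuser at similarity 0.3, per-image kelp cover
uniform on [0.05, 0.65]; the long-tail variant adds 20 rare classes at
0.002 cover each (≈ 20 annotated points per rare class across the survey,
enough to train but far too few to learn). Patches are 32 px — the scenes'
blob scale stands in for the real 224-px patch regime at desk scale; these
sizes keep a full pipeline run to a couple of minutes on one CPU and are
fixed as the package's reference conditions.

**What passing tests show — and don't.** On these scenes the sibling kelp
classifier reaches f1 ≥ 0.85 held-out and pooled cover regression attains
R² ≥ 0.9 with slope near 1. That validates the machinery end to end:
policy set-algebra, training, routing, metrics and cover aggregation
recover known ground truth. It does not certify performance on real AUV
imagery, whose within-class variability, blur, scale variation and label
noise the generator deliberately does not model; real-data performance
depends on the plugged-in backbone features.

## Known limitations

- The handcrafted descriptor is a testing-grade feature; real deployments
  should supply a pretrained backbone via `ExtractorSpec(kind="backbone",
  backbone_fn=...)`.
- Global (single multi-label) hierarchical classification is not
  implemented — only flat and local-binary, which are the modes of
  practical interest here.
- No ROC/AUC or bootstrap intervals; dispersion is reported at fold level.
- The 70% per-site split stratifies by site only, not by depth within site.
- No physical underwater colour correction beyond the percentile stretch.
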