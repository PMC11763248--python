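# Methods

This note records the models, the synthetic data they are validated on, and
the numerical and design choices a maintainer needs to know. It states no
result the test suite or `scripts/acceptance.py` does not itself compute.

## Input data model

The pipeline assumes a gray-matter parcellation (default: 132 parcels — 91
cortical, 15 subcortical, 26 cerebellar, in the style of a combined
Harvard-Oxford + AAL cerebellum atlas) given as an integer NIfTI label
volume plus a parcel table (id, name, hemisphere, lobe, group). The exact
132-row table shipped in `parcelcam/data/hoa_aal_parcels.csv` is a
*default*, not ground truth: the bilateral/midline assignment (43 bilateral
cortical regions + 5 midline singles) was chosen so the group totals come
out at 91/15/26; edit the CSV to match your parcellation. The same applies
to the target sets in `parcelcam/data/targets.yaml`: the MTL set is
hippocampus, amygdala and anterior/posterior parahippocampal gyri
bilaterally (8 parcels); the 31-parcel DMN set enumerates the commonly named
core regions (medial prefrontal, paracingulate, subcallosal, anterior and
posterior cingulate, precuneus, angular and supramarginal gyri, lateral
temporal cortex including the temporal poles, hippocampus, amygdala,
anterior parahippocampal gyrus) bilaterally. No unique DMN definition
exists; the file is meant to be edited.

Connectomes are dense symmetric nonnegative N × N matrices with zero
diagonal. Readers validate and reject (asymmetry beyond 1e-8, negative
weights, nonzero diagonal each raise a distinct error class); nothing is
silently repaired.

## Volume preprocessing

MNI-registered scans are center-cropped to 148 × 180 × 144, intensity
normalized, and resampled to 115 × 144 × 118. Choices the upstream protocol
leaves open:

* *Variance scaling* is interpreted as z-scoring over the nonzero (brain)
  voxels, applied to all voxels; divide-only scaling is a config option.
* The crop anchor is the volume center (MNI-registered brains are centered).
* Intensity resampling is trilinear; label volumes travel through the
  identical geometry with nearest-neighbour interpolation, and a parcel that
  becomes empty raises a warning. Resampling uses pixel-center alignment,
  so equal input/output shapes are exactly the identity.

## Classifiers

Both networks are numpy implementations with hand-written reverse-mode
gradients; every layer's backward pass is checked against central finite
differences in `tests/test_nn.py` (agreement ~1e-10).

**Volume network.** A ResNet-style backbone: one stem convolution
(stride 2, as backbone stems downsample), four stages of residual blocks
(two 3 × 3 × 3 convolutions per block with identity or projection shortcut;
default stage strides 1, 2, 2, 2), then the transfer head: global average
pooling → FC 128 (ReLU) → FC 32 (ReLU) → FC 1 → sigmoid. The single output
logit is the AD score; the HC score is its negation (the two class scores
sum to zero). Stage widths are presets: `full` (64, 128, 256, 512),
`reduced` (8, 16, 32, 64), `tiny` (4, 8, 16, 32), and `flat` (4, 4, 4, 4)
for desk-scale attribution experiments. Kernel geometry is not dictated by
the source protocol; 3 × 3 × 3 stem and stage kernels keep small inputs
viable (every axis must be at least the product of the configured strides).
Stem and stage strides are configurable because heatmap resolution at the
tap points — not classification accuracy — is the binding constraint on
small volumes. Pretrained weights are out of scope; the architecture trains
from scratch and can load a saved checkpoint. Like the graph model, the
volume model stores training-set intensity statistics and standardizes its
input internally; standardizing each scan by its own statistics would let
a global mean shift caused by the planted atrophy leak into every voxel,
and a classifier will happily use that diffuse cue instead of the
localized one.

**Graph network (BC-GCN-SE).** The connectivity matrix enters as one
N × N edge-feature channel. The graph path convolution (GPC) is pinned as

```
out_o(i,j) = σ( Σ_c [ α_oc · mean_h in_c(i,h) + β_oc · mean_h in_c(h,j)
                     + γ_oc · in_c(i,j) ] + b_o )
```

— a row aggregate, a column aggregate and a self term per output channel.
This parameterization composes one-step path extensions under stacking, is
permutation-equivariant, and keeps the N × N shape required for Grad-CAM.
Three GPC blocks are each followed by a squeeze-and-excitation (SE) gate
(channel-mean squeeze, bottleneck with reduction 4, sigmoid gate); edge
pooling (row mean) then node pooling (mean) reduce to a graph feature
vector, followed by FC (ReLU) → FC 1 → sigmoid. Mean (not sum) aggregation
is used everywhere for scale stability across N. With `se: off` the SE
gates are removed and the network is the plain BC-GCN chain.

Two optimization aids are config-gated (`batch_norm`, `standardize`, both
on by default) and matter in practice:

* **Batch normalization** between each GPC's linear map and its ReLU, and
  once more after node pooling. Dense connectomes have a large common
  component — every edge weight is near the cohort mean — so without
  normalization all channels saturate to the linear regime and the pooled
  graph features have vanishing between-sample variance, which makes the
  decision threshold drift. Placing the normalization *before* the ReLU
  also keeps tapped activation maps nonnegative and sparse, which is what
  gradient-weighted activation mapping assumes.
* **Edge standardization**: the model stores the training set's
  off-diagonal edge mean and SD and standardizes inputs internally
  (diagonal reset to zero), the graph counterpart of the volumes' variance
  scaling. The statistics travel with the checkpoint.

## Training protocol

Subject-exclusive stratified k-fold cross-validation (default k = 10):
every subject's sessions land in exactly one fold. Stratification is by the
subject's majority session label (ties count as AD), with a greedy
assignment that balances per-class session counts across folds; dual-class
subjects travel as whole units, prioritizing subject exclusivity over exact
ratio. Class imbalance is handled per modality: SMOTE for connectomes
(synthetic minority samples by linear interpolation between k = 5 nearest
minority neighbours in vectorized upper-triangle space, re-symmetrized, zero
diagonal) and inverse-frequency class weights in the binary cross-entropy
for volumes (a balanced batch gets unit weights). Batch sizes: 16 (volumes),
64 (graphs).

Optimization is Adam with gradient-norm clipping at 5 and cosine
learning-rate decay over the epoch budget. Early stopping monitors
validation loss (patience in epochs); the retained state is the epoch with
the highest validation AUC, ties resolved toward the lower validation loss
— AUC saturates while the 0.5 decision threshold is still calibrating, so
among equally discriminative states the better-calibrated one is kept. A
degenerate single-class validation fold falls back to loss-based selection.
The final model uses a subject-exclusive 90/10 split whose 10% part only
drives early stopping and retention; predictions are then produced for
every session, with training sessions flagged `in_sample`.

Fold performance is summarized as median and IQR of TPR, TNR and accuracy,
plus a row-normalized 2 × 2 confusion matrix (median and IQR per cell).

## Explainability

Per-layer heatmaps use the layer's own grid for the gradient average, are
ReLU-rectified, and are resampled to input size with cubic interpolation per
axis (negative interpolation overshoot is clipped to preserve
nonnegativity; the 2D case extends to three axes for volumes; N × N graph
maps are already input-sized). Layer heatmaps are averaged *without*
per-layer renormalization (a plain mean over L = 4 volume stages or L = 3
GPC-SE blocks); max-normalized averaging is deliberately not the default.
Zero gradients yield a valid all-zero heatmap with a warning rather than an
error — a saturated classifier can have no positive evidence for the
losing class.

The graph RV uses row p exactly as defined (off-diagonal row mean,
denominator N − 1) without symmetrizing the heatmap first; a `symmetrize`
option averages the heatmap with its transpose. Min-max normalization of RV
tables is a reporting-only transform (scope: every parcel of every
correctly classified session) and is never fed to the statistics.

Heatmaps are computed for both attribution classes for every session; the
refinement stage then keeps, per session, the heatmap of its true class
(only correctly classified sessions survive, so predicted = true).

## Statistics

Refinement: (i) drop misclassified sessions, (ii) average RVs per parcel
over a subject's remaining same-class sessions, (iii) drop subjects still
carrying both classes, (iv) split by class. Audit counts reconcile exactly
(retained + misclassified + dual-class = input sessions).

Per parcel, sample normality is checked by a Kolmogorov-Smirnov test of the
standardized values against the standard normal (Lilliefors is a config
option); the t-test (Welch by default) is used only when *both* samples pass
at α = 0.05, otherwise the two-sided Mann-Whitney U. Constant samples take
the Mann-Whitney path with a degeneracy warning. Benjamini-Yekutieli
correction is applied across the parcels of one model (not pooled across
models). Ranking uses the per-class mean RV across retained subjects
(median is a config option); the top set is ceil(0.15 × n_parcels) — 20 of
132 — with ties at the cut broken by ascending parcel id. Target overlap is
reported per parcel and with bilateral structures collapsed to one unit
(a unit counts as significant if any of its parcels is).

## Synthetic cohorts

The generator reproduces the statistical structure the pipeline depends on,
not MRI physics:

* session imbalance HC:AD = 557:135 by default (the exact split is honored
  when a total session count is given, e.g. the 543-subject / 692-session
  skeleton of `oasis_like_structure`);
* 1–3 sessions per subject (probabilities 0.76/0.21/0.03, mean ≈ 1.27);
* 2.76% of subjects carry sessions under both labels (one session flipped;
  single-session subjects are then toggled to restore the target split);
* volumes: per-parcel mean intensities drawn once per cohort from
  U(0.6, 1.0), AD means multiplied by (1 − effect_size) inside the effect
  parcels only, i.i.d. Gaussian voxel noise everywhere. The volume effect is
  a multiplicative mean reduction (an atrophy proxy) rather than a geometric
  deformation, so one atlas stays valid for both classes — the RV
  aggregation, not morphometry, is under test;
* graphs: one base matrix per subject with log-normal edge weights (median
  1, log-SD 0.4 — a skewed, strictly positive weight distribution typical
  of streamline counts), sessions add clipped Gaussian edge noise; AD
  sessions attenuate edges with *both* endpoints in the target by
  (1 − effect_size) (single-endpoint attenuation is an option).

What passing recovery tests does and does not show: the generator has no
spatial intensity texture, no partial-volume effects, no registration error,
no tractography biases, and its effect is homogeneous across the target, so
success here certifies the *pipeline machinery* (training, attribution,
aggregation, statistics) under a known ground truth — not performance on
real scans.

## Desk-scale problem sizes

The recovery experiments are sized for a single CPU; training runs in
single precision. The graph arm uses a 200-subject, 40-node cohort with an
8-node planted target at effect 0.5 (edge noise SD 0.05), 5-fold
subject-exclusive cross-validation, reduced channels (8, 8, 8), batch 64,
lr 3e-3, ≤ 80 epochs, patience 15. The volume arm uses 50 subjects
(balanced classes) at 32³ with a 40-parcel synthetic atlas and an 8-parcel
planted target; the network uses the `flat` preset (4, 4, 4, 4) with one
residual block per stage and *no stage downsampling* (stem stride 2 only),
because with further downsampling the deepest class-activation tap shrinks
to one or two voxels per axis and its near-constant upsampled map dominates
the un-renormalized layer average, erasing parcel-level localization.
Volume training: 3-fold cross-validation, batch 16, lr 3e-3, ≤ 20 epochs,
patience 8. The atlas has 40 parcels so the top-15% set
(ceil(0.15 × 40) = 6) is large enough to contain most of an 8-parcel
target. Recovery is scored as the median over three seeds of (a) median
fold accuracy and (b) the number of planted parcels inside the AD top-15%
RV set. The statistics calibration uses 200 replicate null datasets (132
parcels, n = 50 per class) and a separate 200-replicate run with a 2-SD
shift planted in one parcel for power.

## Known limitations

* The GPC parameterization follows the edge-based formulation above; the
  originally tuned hyperparameters of the reference architecture are not
  public, so channel widths, SE reduction and FC sizes are config defaults,
  not claims.
* Grad-CAM attribution is gradient-based and class-signed; on a saturated
  model the losing class's heatmap can be identically zero.
* Recovery of a planted subnetwork through the AD top-RV set depends on the
  final model's quality; a poorly converged run attributes diffusely. The
  acceptance runs therefore score medians over seeds.
* The statistics stage assumes one RV per subject per parcel after
  refinement; cohorts where refinement empties a class raise an error
  naming the class rather than producing empty samples.
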