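# Methods

## Problem and model

The package models a two-class image classification task: given a
pre-treatment CT volume and a binary tumor (GTV) mask, predict whether an
NSCLC patient will respond to chemoradiotherapy (RECIST CR/PR = responsive
vs SD/PD = nonresponsive). The scientific question it is built to study is
not the classifier itself but the *training topology*: whether a federated
model — hospitals exchange only network weights, never images — matches a
centralized model trained on pooled data, when hospital cohorts differ in
size and distribution.

### Classifier

A deliberately small 3D CNN: three blocks of stride-1 same-padded 3³
convolution → ReLU → 2³ max-pool, then flatten → fully-connected → ReLU →
fully-connected(2) → softmax. Defaults: channels (16, 32, 64), hidden
width 128 for 64³ inputs (≈4.26 M parameters); a reduced preset with 16³
inputs, channels (4, 8, 16), hidden 32 (≈8.7 k parameters) is used for all
desk-scale work. There is no normalisation layer and no dropout, so
samples in a batch never interact: predictions are exactly batch-size
invariant and runs are bit-reproducible from the seeds.

The network is implemented directly on NumPy arrays (float64) with
hand-written backpropagation — im2col convolution, argmax-scatter pooling
backward, fused softmax/cross-entropy — and is verified in the test suite
against central finite differences (relative error ~1e-9). This keeps the
package dependency-light and makes the federated reduction argument below
exact rather than subject to framework nondeterminism.

### Training

Per-site stratified 7:3 train/validation split; cross-entropy loss; Adam
(β₁ = 0.9, β₂ = 0.999) or plain SGD at learning rate 0.001. Protocol-scale
presets mirror the reference study: centralized batch 8 / Adam / 100
epochs; federated batch 16 with SGD (two-client simulation preset) or Adam
(three-client preset), 10 rounds × 50 local epochs. The final model is the
last epoch's weights — no early stopping or best-epoch selection, which
keeps runs deterministic. Remainder batches are kept; per-epoch shuffles
and augmentation draws are seeded by `(seed, global_epoch)`.

### Federated averaging

Synchronous FedAvg with full participation: each round the server
broadcasts θ_global, every client trains `local_epochs` epochs from it,
and the server sets θ_global = Σₖ (nₖ/Σⱼnⱼ)·θₖ, accumulated in double
precision, with nₖ the client's *training-split* size (the data actually
trained on, not the site's total). Client optimiser state is reset at each
broadcast — the stateless-client reading of the round protocol; with plain
SGD this is vacuous, and it makes the single-client case an exact
reduction: one client for R rounds of L epochs is bit-identical to
centralized training for R·L epochs, because the local epoch counter
continues across rounds (`epoch_offset`) and aggregation over one client
is the identity. This reduction is asserted in the tests and the
acceptance script. All clients deliberately share one shuffle seed, so two
clients holding identical data produce identical updates (a symmetry the
tests exploit); client updates are exchanged as explicit, copied
`ParameterSet`s, so a networked transport could replace the in-process
loop without touching the training code.

## Preprocessing

Volumes are resampled to 1×1×1 mm: cubic B-spline for images. For masks,
B-spline interpolation of a {0,1} array produces non-binary values, so
masks use nearest-neighbour instead (equivalent to thresholding at 0.5);
volume conservation within 5% for semi-axes ≥ 5 mm is a tested invariant.
The patch centre is the mask centroid rounded half-up; the patch is
`size`³ with the centre voxel at index `size//2`, out-of-volume regions
filled with the normalised minimum (0.0, "air"). Intensities are clipped
to a window and scaled to [0, 1]: a fixed HU-like window (−1000, 400) for
CT-scaled data, or a window derived from the *training* sites' intensity
range for phantom cohorts (derived from training data only, so no
test-set statistics leak into normalisation).

Augmentation (training data only, seeded): left–right flip of the axial
plane with probability 0.5; rotation about the cranio-caudal z axis by
U(−15°, 15°), linear interpolation, constant fill; pad by 4 voxels and
random-crop back to size (the conventional parameterisation of an
otherwise unspecified "random crop"); brightness then mean-preserving
contrast jitter with factors U(0.8, 1.2); re-clip to [0, 1]. Saturation
and hue factors are carried in the config for completeness but are no-ops
on single-channel data. The flip axis and rotation axis are declared
design choices — a 2D-style augmentation list maps most naturally onto
axial slices of a chest CT.

## Synthetic cohorts

The generator emulates the *structure* of a private multicenter CT cohort,
not CT physics. Each patient is an ellipsoidal tumor in a homogeneous
background: image = background + site intensity offset + contrast·mask +
spatially smoothed Gaussian texture (3 mm correlation length) + white
site noise. Site specs carry cohort size, responsive fraction, intensity
offset, noise SD, voxel spacing, and demographic distributions (age
normal, sex Bernoulli — used only by the cohort-statistics module, never
by the images).

The class signal is morphological: the two classes draw tumor semi-axes
from different means, pulled toward their common midpoint by
`label_effect_size` (0 = identical classes → feature AUC 0.5; 1 = the
configured separation) and corrupted by `label_noise` (probability a
patient's morphology is drawn from the opposite class, bounding the
achievable AUC below 1). Labels are assigned per site in exact-count mode
by default (deterministic class counts, mirroring a printed
characteristics table); a Bernoulli mode exists.

Defaults follow the reference study's structure: four sites of
102/42/32/69 patients with per-site responsive fractions 51/102, 31/42,
17/32, 11/69 (overall 110/245 ≈ 45%); the fourth site carries the
distribution shift (intensity offset +40, noise SD 14 vs 8, coarser
spacing) standing in for the "uneven" hospital whose shift was never
quantified — it is a parametrisation, not a reconstruction. Tumor
semi-axes: responsive 7 mm vs nonresponsive 11 mm (SD 1.5 mm), so every
tumor fits the 64 mm patch; `label_noise` 0.15, chosen as a realistic
level of label/morphology decoupling for a task whose real-data AUCs sit
near 0.7. The desk-scale phantom (32×48×48 voxels, semi-axes 3.5 vs 6 mm,
no label noise, 16 mm patches) realises the strong-effect condition used
by the parity benchmark.

Seed discipline: patient *i* of site *j* derives its generator from
`SeedSequence([master_seed, j, i])`, so cohorts are extensible — adding
sites or patients never rewrites existing patients (tested).

What passing on phantoms does **not** show: anything about real CT
(anatomy, partial-volume effects, scanner protocols, RECIST ambiguity) or
about the attainable AUC on hospital data. It shows that the machinery —
preprocessing geometry, optimisation, aggregation arithmetic, evaluation —
is correct, and that federated and centralized training behave comparably
under controlled site shift when a learnable signal exists.

## Evaluation

AUC is the trapezoidal area under the empirical ROC (equivalently
pairwise concordance with half-weight ties; the suite checks this
equivalence to 1e-12 against exhaustive enumeration). The CI method for
AUC is unstated in the reference tables, so the package uses a stratified
percentile bootstrap (resample within each class, 2000 replicates,
seeded); its ~95% coverage is verified by simulation against a binormal
generator with known AUC. Threshold metrics use 0.5 on the positive-class
softmax probability. The positive class defaults to responsive but is
configurable everywhere — printed metrics in multicenter reports are
sometimes integer-consistent only with the opposite orientation, so
neither is hard-coded. Federated runs report pooled train/validation
metrics plus per-client reports, since the aggregation convention for
multi-client "training" rows is ambiguous.

## Cohort statistics

Pearson chi-square without continuity correction (the convention that
reproduces the reference table's printed r×c p-values; expected counts
below 5 are flagged), one-way ANOVA accepting raw samples or (mean, sd, n)
summaries via the same sum-of-squares decomposition, and Fisher's exact
test (scipy's exact 2×2; seeded Monte-Carlo over fixed-margin tables for
larger shapes, flagged as approximate). The shipped reference table
reproduces printed p-values 0.269 / 0.120 / 0.114 / 0.065 for histology,
tumor stage, node stage and metastasis at three decimals. Two rows do
not reproduce under these tests and are excluded from acceptance: age
(ANOVA from the printed summaries gives p ≈ 0.013, not the printed 0.057)
and clinical stage (chi-square gives p ≈ 0.239, not 0.187 — plausibly an
exact r×c test was used on its sparse cells); the discrepancy is reported,
not hidden.

## Numerical and design choices

- float64 throughout the network; aggregation accumulates in float64.
- Max-pool ties resolve to the first window position (deterministic).
- Architecture details (channel counts, kernel 3³, hidden 128) are the
  smallest conventional choices consistent with a 3-conv/3-pool/2-FC
  structure; all are configurable.
- Stratified splits fall back to unstratified with a warning when a class
  has fewer than two members.
- Class weighting is available but off by default (the 110/135 imbalance
  is mild and no weighting is part of the reference protocol).
- Centroid rounding is half-up per axis; empty masks are a hard error.

## Problem sizes

Desk-scale defaults keep every study single-CPU-friendly: the parity
benchmark uses 3 training sites (60/30/30) plus a 40-patient test site,
16³ patches, the reduced network, 5 rounds × 2 local epochs federated vs
10 epochs centralized (matched compute), 3 seeds — a few minutes in
total. The protocol-scale presets (64³ patches, 10×50 rounds) are
provided for completeness and run in hours, not minutes.

## Known limitations

- No DICOM/RT-struct ingestion: the package consumes NIfTI pairs.
- No FedProx, client sampling, stragglers, differential privacy or secure
  aggregation; the simulator is synchronous and in-process.
- Phantoms have no lung anatomy; only the tumor-centred patch is modelled.
- The exact-reduction argument (federated ≡ centralized for one client)
  holds bit-exactly for stateless optimisers; with Adam, per-round state
  reset makes the two schedules differ by design.
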