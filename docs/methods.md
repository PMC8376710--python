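# Methods

`connectocam` implements a complete diagnosis-and-attribution pipeline for
parameter-weighted structural connectomes: microstructure-weighted matrix
construction, a customized convolutional classifier, repeated-trial
cross-validation with paired AUC comparison, and Grad-CAM attribution of
discriminative connections.  This note records the model, its assumptions,
the tunable parameters, and the design decisions taken where the design was
genuinely open.

## Connectome model and preprocessing

Subjects are represented by 84×84 symmetric non-negative matrices on the
Desikan-Killiany cortical parcellation (68 regions) extended with eight
bilateral subcortical/cerebellar nodes.  The base matrix holds streamline
counts (NOS); weighted matrices multiply each edge by the tract-averaged
value of a diffusion or myelin parameter (FA, MD, AD, RD from DTI; MK, AK,
RK from DKI; ICVF, ISOVF, ODI from NODDI; MVF, and the derived AVF and
g-ratio), giving 14 matrices per subject.  The microstructure identities

    AVF = (1 − MVF)(1 − ISOVF)·ICVF
    g   = √(AVF / (MVF + AVF))

are voxelwise identities applied here to tract-averaged edge values, because
the pipeline's inputs are edge-level maps; this is an approximation and is
the package's deliberate scope (no voxelwise model fitting).  Edges where
MVF + AVF = 0 (structurally absent) get g = 0 by convention.

Classifier inputs are built by an exact, invertible transform: the 3486
independent strict-upper-triangle edges ((84·84−84)/2) are extracted in
row-major order (i ascending, j ascending within row, i < j), 114 zeros are
appended to reach 3600 values, the vector is reshaped row-major to 60×60,
and the grid is divided by its maximum.  Flattening order and padding
position are conventions (fixed here and shared by the inverse map);
normalizing before or after padding is equivalent since padding zeros never
exceed the maximum.  `reorganize_to_connectome` inverts the transform
bit-exactly up to the discarded diagonal, which is how attribution maps
return to the connection space.

## Synthetic cohorts

Real NOS matrices are sparse and heavy-tailed.  The generator draws, once
per cohort, a binary edge scaffold (default density 0.6) and a log-normal
edge-strength template (natural-log mean 3.0, sd 1.0); each subject is the
group template times multiplicative log-normal subject noise (log-sd 0.3).
Group effects are multiplicative on a designated edge set, keeping matrices
non-negative; the default planted circuit is the union of 13
basal-ganglia↔cerebellar-cortex pairs (pallidum, putamen, caudate,
hippocampus, amygdala, accumbens partners of the cerebellar cortex),
mirroring the circuit family implicated in Parkinson's disease.  Edges named
in an effect are forced into the scaffold, since an effect on a structurally
absent edge would be vacuous.  The default cohort size is 115 per group, the
reference study's size; the scaled-down studies below override it.
Dominant side alternates left/right across patients to exercise the
subgroup-pooling path; controls are "none".

What the generator does **not** emulate: regional volume and distance
effects on streamline counts, correlated edge noise, site/scanner effects,
or any coupling between a subject's parameter maps and their NOS matrix
(raw parameter maps, when requested, are Beta(5,5)-distributed with small
subject jitter and carry no effect of their own).  Passing recovery tests on
these cohorts therefore demonstrates the pipeline's correctness and
sensitivity under known ground truth, not clinical performance on real
connectomes.

## Classifier

Adjacency in a connectome matrix carries no spatial meaning, so the CNN is
customized: all four convolutional layers (8, 16, 16, 32 channels) use
filter size 1 — each of the 3600 grid cells is transformed independently
across channels — and pooling is omitted, so feature maps stay 60×60
throughout.  The final maps are flattened (position-major) into a fully
connected head of 4096, 4096 and 2 units; outputs are softmax probabilities
against teacher vectors [1,0] (control) and [0,1] (patient).  Training
minimizes softmax cross-entropy with AdaGrad (minibatch 15, 20 epochs,
accumulator initialized at zero) after 6-fold augmentation of training
inputs with zero-mean Gaussian noise (sd 0.002–0.010, added after
max-normalization, to every cell including padding).

Choices the architecture description leaves open, fixed here:

- **Activations**: ReLU after every convolutional and hidden fully connected
  stage — the standard choice for this family, and Grad-CAM presumes
  rectified feature maps.
- **Conv→FC transition**: flatten all 32×60×60 activations (115200 inputs to
  the first FC layer); global pooling would destroy the position information
  that pin-point attribution relies on.
- **Learning rate**: 0.001 by default, exposed in `TrainConfig`;
  initialization is scaled-Gaussian fan-in (sd 1/√fan_in), biases zero,
  seed-controlled.
- No dropout, batch normalization, weight decay or early stopping.

Everything is float32 NumPy with hand-written backpropagation, which lets
the attribution stage read exact activations and gradients at any layer.
Gradients were verified against central finite differences.  AdaGrad's first
update moves every parameter by exactly ±lr (the accumulator equals the
squared first gradient), so over-large learning rates destabilize small
networks; step sizes of 0.005–0.02 are stable for the narrow presets.

A reduced preset (`REDUCED_ARCHITECTURE`, fully connected widths 256, 256,
2, same convolutional stack) and a scaled optimization config (`FAST_TRAIN`:
learning rate 0.01, no noise augmentation) exist for desk-scale studies; the
wide preset and the full augmented recipe remain the defaults.  The
scaled-down studies use learning rate 0.01 because with tens (not thousands)
of minibatch updates AdaGrad's √t step decay leaves 0.001-sized steps far
from convergence.

## Evaluation protocol

Subjects are split into five class-stratified random folds (stratification
guarantees both classes in every validation fold).  Per fold, `n_trials`
models (default 10) are trained on the remaining folds and one is kept —
by highest validation AUC, reproducing the reference protocol.  Selecting on
validation AUC reuses the validation fold and biases pooled estimates
optimistically; this circularity is preserved deliberately for fidelity, and
`selection="train_loss"` provides an unbiased alternative.  Validation
scores of the kept models are pooled so each subject is scored exactly once.

AUC is the Mann-Whitney statistic with ties counted ½.  Confidence intervals
and the two-sided paired test comparing matrix types use DeLong's
placement-value variance estimator (midrank formulation, O(mn)
implementation); comparisons across five matrix categories use a Bonferroni
threshold of 0.05/10 = 0.005.  Sensitivity, specificity and accuracy use a
patient-probability cutoff of 0.5 (score ≥ 0.5 predicts patient) and are
reported both as exact fractions and integer percents.

## Grad-CAM attribution

For a correctly classified validation patient, the channel weight of each
32-channel feature map at the 4th convolutional layer is the spatial mean of
the class-score gradient; the map is the rectified channel-weighted sum,
natively 60×60 because filters are size 1 and pooling is absent.  The
**class score** is the patient logit *minus* the control logit: with two
softmax outputs, class evidence is only defined relative to the alternative
(the softmax output's gradient equals this difference's gradient up to the
positive factor p(1−p)), and raw single-logit gradients contain a shared
component that carries no class information — empirically it can dominate
the spatial average and rectify entire maps to zero.  Cells whose input is
zero (absent connections, padding) are masked from the map: with size-1
filters their activations are input-independent constants, so heat there is
a bias artifact that can otherwise flood rankings with large tied values.
Per-patient maps are
divided by their own maximum (matching the max-normalization convention used
for inputs), reorganized to 84×84, and averaged across patients (summing is
available as an option); the dominant-side subanalysis pools left- or
right-dominant patients separately.  Ranking ties break by canonical atlas
order for reproducibility.

A structural caveat follows from the architecture: because every feature map
is a pointwise function of its input cell, a single map's heat is a scalar
function f of the cell value.  Attribution therefore localizes *value
ranges* the classifier associates with patients, and recovers a planted
circuit only when the trained f isolates the band where affected edges live.
Pooling across all correctly classified patients and across fold models
stabilizes this considerably, but individual cohorts can still fail to
surface planted edges when the classifier keys on other covarying features;
the recovery studies below quantify this.

## Scaled-down study conditions

The synthetic studies shipped with the package (acceptance tests and
`scripts/acceptance.py`) run on one CPU in minutes, with these sizes chosen
as the package's own desk-scale conditions:

- **Null study**: 50 subjects/group, no effect, reduced preset, stratified
  3-fold, two trials per fold, 40 unaugmented epochs at learning rate 0.01.
  Pooled AUC is expected in [0.35, 0.65].  Repeated trials serve their
  original purpose — absorbing the occasional failed training run (AdaGrad's
  large first step can leave a narrow network emitting a constant score) —
  while keeping the optimistic selection bias small; the bias is why the
  null band is checked.  40 epochs (≈200 updates) matter for calibration:
  at half that, fold models rank their validation subjects perfectly but
  emit scores in narrow model-specific bands, and pooling scores across
  folds then understates the AUC.
- **Separable study**: 50/group, effect size 3.0 on the default circuit,
  subject noise 0.1, same protocol; pooled AUC expected ≥ 0.9.
- **Recovery study**: 60/group, effect size 2.5, default noise 0.3,
  stratified 3-fold (3 instead of 5 folds keeps every patient pooled while
  training 40% fewer models), one trial per fold for budget (a degenerate
  fold model scores no patient confidently and contributes only zero maps),
  Grad-CAM pooled over all correctly classified validation patients,
  hit = any planted edge in the top 30 of 3486.

## Numerical choices and degenerate inputs

- Symmetry validation tolerance for matrices read from text: relative 1e−8;
  validated matrices are stored symmetrized.
- All-zero grids cannot be max-normalized and raise a degenerate-input
  error; an all-zero attribution map stays zero through pooling.
- Out-of-range compartment fractions, single-class score vectors, empty
  pools, and mismatched paired score lengths raise typed errors.
- Identical placements in the paired DeLong test (zero variance) return
  p = 1 when the AUC difference is 0.
- All randomness derives from one root seed through named SHA-256 child
  streams (`seeds.derive_seed`), so cohort draw, fold split, initialization
  and augmentation reproduce independently; identical seeds give
  bit-identical cohorts, training trajectories and result files.

## Known limitations

- Activation functions, learning rate and initialization of the reference
  recipe are unknowable from its description; absolute AUC values on real
  data are therefore not expected to reproduce, and none are asserted.
- The attribution stage inherits the pointwise-function caveat above;
  recovery claims hold for the synthetic conditions stated, not for real
  cohorts.
- The wide (4096-unit) preset is memory- and compute-heavy (~470M
  parameters); it is the configured default but the shipped studies use the
  reduced preset.
- No NIfTI/DICOM ingestion, tractography, voxelwise model fitting, external
  validation, calibration analysis, or multi-class differentiation.
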