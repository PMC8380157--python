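# Methods

## Problem and model

`fdgnet` implements a hybrid classifier for staging Alzheimer's disease from
single-channel 3D brain volumes (in practice, preprocessed ¹⁸F-FDG PET
cropped to 80 × 100 × 76 voxels).  The three-class problem NC / MCI / AD is
decomposed one-vs-one into three binary machines — AD vs NC, MCI vs NC,
AD vs MCI — each a 3D convolutional feature extractor feeding a
polynomial-kernel SVM, and their decisions are fused into one label.

### Backbone

The feature extractor is a six-convolution stack (all stride 1):

| stage | kernel | channels | notes |
|---|---|---|---|
| Conv1 | 1×1×1 | 32 | channel lift, no spatial mixing |
| Conv2 | 3×3×3 | 64 | same padding; 2×2×2 max-pool after |
| Conv3–Conv5 | 3×3×3 | 128/256/512 | same padding; channel attention, then 2×2×2 max-pool after each |
| Conv6 | 3×3×3 | 512 | no padding (each axis shrinks by 2) |

Every convolution is followed by normalization and ReLU; pooling uses floor
semantics (a trailing odd voxel is dropped), so 80×100×76 becomes 5×6×4
before Conv6 and 3×4×2 after it.  Global average pooling yields the 512-d
embedding.  A dropout (rate 0.5) + 2-unit fully connected head is attached
only for supervised pretraining; the embedding, not the head, is what the
SVM consumes.

Channel attention follows the CBAM recipe: spatial average- and max-pooled
per-channel descriptors pass through one shared MLP (one ReLU hidden layer,
reduction ratio 16 at full width) and the logistic of the summed scores
gates each channel, `W = σ(MLP(AvgPool F) + MLP(MaxPool F))`.

Normalization is per-sample instance norm by default (learned affine,
ε = 1e-5); batch norm is available as an ablation switch.  Instance norm
fits the batch-size-4 regime that 3D volumes force and makes gradient
accumulation exact (below).  Note one degenerate case: when a stage's
spatial output is a single voxel, instance norm maps it to the affine bias
exactly — architectures should keep at least a few voxels in front of GAP.

The backbone is implemented as a compact NumPy neural-network core
(`fdgnet.nn`) with explicit forward and backward passes per layer;
parameters are float32 (the im2col convolutions are memory-bandwidth
bound), while tests cast to float64 where finite-difference gradient
checks need the headroom.  Every gradient path — convolution, both norms,
attention (including the max-pool scatter), pooling, dropout, the dense
head — is verified against central finite differences.

### Training the backbone

Plain SGD (optional momentum) on label-smoothed cross-entropy (ε = 0.1
during pretraining only).  Gradients are accumulated over 4 mini-batches
of 4 samples and applied as their average; with instance norm this is
exactly one update computed from the concatenated 16-sample batch (no
cross-sample coupling), which the suite asserts to 1e-6.

### SVM head

The binary classifier on embeddings is a soft-margin SVM with the
inhomogeneous polynomial kernel K(x, z) = (x·z + 1)^q.  The dual is solved
by sequential minimal optimization (Platt's two-multiplier scheme with the
|E₁ − E₂| second-choice heuristic, deterministic given a seed); the bias is
recomputed at convergence as the mean KKT value over non-bound support
vectors.  Defaults C = 1, q = 2, tol = 1e-3, max 200 sweeps — the defaults
are logged with every model since no canonical values exist for this
architecture.  On random problems with n ≤ 12 the dual objective matches a
dense SLSQP quadratic-program oracle to 1e-4 relative.

For end-to-end training the sign decision is replaced by a two-way softmax
over (s, −s):

    y₀ = e^s / (e^s + e^−s) = 1 / (1 + e^−2s),

so cross-entropy on y₀ is differentiable in the embedding x through the
kernel expansion (ds/dx = Σᵢ αᵢyᵢ q (x·xᵢ + 1)^{q−1} xᵢ) while every SVM
parameter stays frozen.  sign(0) maps to +1, documented.

### Alternating end-to-end procedure

1. pretrain the backbone with its FC head on the training set;
2. fit the initial SVM (SMO) on the training-set embeddings;
3. repeat: fine-tune the backbone through the frozen softmax head
   (training + verification samples, as the protocol prescribes — a
   `use_verification_in_finetune=False` mode exists because the as-written
   protocol lets verification data influence the model), then refit the
   SVM on fresh training-set embeddings with the backbone frozen.

"Converged" is operationalized as relative fine-tuning-loss change below
`convergence_tol` (default 1e-3) or the round budget (default 3).  The
per-phase trace records SHA-256 checksums of both parameter sets before
and after every phase, making the phase-exclusivity contract (no step ever
moves backbone and SVM together) auditable after the fact.  Kernel
evaluations in the head are recomputed each forward pass; correctness over
speed at desk scale.

### Decision fusion

Each machine maps the severer class to +1 (AD over MCI over NC).  If two
or three binary decisions name the same class, it wins (6 of the 8
decision patterns).  Otherwise the machine with the largest |s| decides;
exact ties break by the fixed order AD_NC < MCI_NC < AD_MCI.  Raw margins
are compared without cross-machine calibration — the literal rule — with
an optional per-machine standardization (divide by training-score SD)
available but off by default.

### Evaluation

ACC, SEN, SPE from confusion counts (undefined denominators yield None,
never 0); AUC by the midrank Mann–Whitney statistic.  Cross-validation is
five-fold at subject granularity, stratified by class: the test part
rotates, the verification part is the next fold in rotation order, and no
subject's scans ever straddle two roles.  The three-class report gives
per-class recall (diagonal over row sum) and their unweighted macro mean —
the only reading under which per-class values and an average are all
well-defined from one confusion matrix; this is an interpretation, noted
as such.

## Synthetic phantom cohorts

Real FDG-PET for this task is access-restricted, so the package ships a
phantom generator that emulates exactly the structure the classifier
assumes and nothing more: a smooth ellipsoidal "brain" blob; an
ellipsoidal ROI in the anterior half standing in for AD-affected cortex,
where the mean signal drops by a class effect (defaults NC 0 ≤ MCI 1.0 ≤
AD 2.0, in template-intensity units where the blob peaks at 1); a
per-subject Gaussian random offset (SD 0.2) shared by all of a subject's
scans; and i.i.d. voxel noise (SD 0.25).  Randomness is hierarchical
(cohort → subject → scan seed streams), so enlarging a cohort never
perturbs earlier subjects.

What the phantoms do **not** model: anatomy, partial-volume and scanner
physics, intensity-normalization artifacts, multi-site effects, or
disease heterogeneity.  Passing tests on phantoms demonstrate that the
pipeline's machinery (feature extraction, SMO, the differentiable head,
alternation, grouped splitting, fusion) is correct and that the system
recovers a strong known signal; they say nothing about accuracy on
clinical PET.

One consequence of the between-subject random effect deserves emphasis:
a subject's true regional deficit is `effect(class) + offset` with
offset ~ N(0, 0.2²), so an MCI subject occasionally lands past the
AD/MCI midpoint (deficit 1.5) — about 0.6% of subjects per class, hence
roughly 5% of random 8-subject test splits contain one irreducibly
misclassified subject, capping that split's best possible pairwise
accuracy at 14/16.  The ROI mean is the exact sufficient statistic of
this generative model, so no classifier can beat the midpoint rule on
it.  The acceptance suite therefore checks two things: that held-out
accuracy clears a fixed bar on most seeds, and separately that on
*every* seed the trained system reaches this Bayes bound to within one
subject — the second being the property that holds unconditionally.

## Desk-scale study conditions

CPU-scale experiments run on a (32, 40, 30) grid with a narrowed backbone
(channels 4, 8, 16, 32, 32, 32; attention ratio 4; no dropout — a 0.5
rate on a 32-d embedding starves the small pretraining head, where on the
512-d full model it is ordinary regularization).  Width matters here:
halving these channels again makes AD-vs-MCI generalization collapse on
some seeds even when the training set is fit, so this is the narrowest
preset that learns all three pairwise tasks reliably.  Two
pooling-arithmetic consequences at this scale: Conv6 sees a (2, 2, 1)
grid, too small for a valid 3×3×3 convolution, so the desk preset pads
Conv6 (`conv6_padding="same"`); the full-scale architecture keeps the
unpadded Conv6 and its table of shapes.

The desk training schedule (`desk_schedule`) uses momentum-0.9 SGD at lr
1e-2, pretraining "until converged" — two consecutive epochs fitting the
training set (accuracy ≥ 0.98), at least 4 and at most 12 epochs — and lr
1e-3 for the fine-tuning epochs; the paired SVM settings
(`desk_svm_config`) use C = 10 because the compact desk embeddings need
the harder margin.  Library defaults stay at the conservative lr 1e-3 /
zero momentum / C = 1.

The reference phantom experiment (also what `scripts/acceptance.py`
reruns) uses 20 subjects per class, 2 scans per subject, effects
(0, 1.0, 2.0), noise SD 0.25, a 60/20/20 subject-stratified split, and 2
alternation rounds, then reports per-task held-out accuracy and AUC and
the fused three-way accuracy.

## Known limitations

- The NumPy backbone is single-threaded BLAS-bound; full-resolution
  (80×100×76, 512-channel) training is out of desk reach by design — the
  full architecture is validated structurally (shape table, parameter
  groups, gradient checks) rather than by training at scale.
- SMO is dense (O(n²) kernel matrix); intended for the small-cohort regime
  the method targets.
- The three machines' margin scales are uncalibrated where the fusion rule
  compares them; the optional standardization mitigates but was not needed
  on phantoms.
- Upstream PET preprocessing (registration, spatial/intensity
  normalization, smoothing) is out of scope; volumes are assumed
  registered and comparable, and the intensity-normalization scheme is
  deliberately left to the user.
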