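# Methods

`neurofuse` implements an explainable multimodal classifier for Autism
Spectrum Disorder (ASD) built from four trainable stages plus a synthetic
cohort generator that makes every stage testable without real data.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not show.

## Model

Each subject contributes a behavioral phenotype row and a 3-D structural
volume.  The pipeline is the composition

    y_hat = h( AE([ f_b , f_m ]) )

where `f_b` is the scalar output of the additive behavioral network, `f_m`
is the 128-d CNN–GNN volume embedding, `AE` is the fusion autoencoder's
32-d bottleneck code, and `h` is a per-subject MLP whose weights are
generated by a hypernetwork from the fused code.

### Behavioral branch: neural GAM with interactions

The ASD logit is an additive decomposition

    logit(p) = Σ_i f_i(x_i) + Σ_{(i,j)∈L} f_ij(x_i, x_j) + β0,

with one small MLP subnetwork (1 → 16 → 16 → 1, ReLU) per feature and per
selected pair.  The sigmoid link is used because the branch outputs a
probability and is trained with binary cross-entropy; a raw sum could not
satisfy both.  Fitting is three-stage:

1. **Main effects** are trained jointly (Adam, lr 1e-3, 30 epochs, batch
   64) with an L1 penalty (1e-4) on a per-effect output scale γ_i, so
   uninformative effects shrink.
2. **Interaction screening**: the working residual `y − sigmoid(main
   logit)` is regressed on each candidate pair with a depth-3 regression
   tree; pairs are ranked by training R² (variance of the residual
   explained) with lexicographic tie-break, and the top `k` (default 10)
   enter `L`.  Shallow trees are used because they capture any
   low-resolution bivariate structure without committing to a functional
   form.
3. **Interaction effects** are trained on the residual signal with the
   main effects frozen.

Effects whose training-set output variance falls below 1e-4 of the total
effect-output variance (or below an absolute floor of 1e-10) are pruned to
exactly zero — pruning is a hard mask, so a pruned effect contributes 0 for
every input.  Every surviving effect is mean-centered over the training
set, with the means absorbed into β0; centering makes the decomposition
identifiable, so importance scores (normalized contribution variance) and
partial-dependence curves are well defined.  Partial dependence of a
feature is exactly its subnetwork (no marginalization), a property of
additive models.

Inputs must lie in [0, 1]; the preprocessing stage guarantees this.

### Preprocessing

Fit/apply split with all statistics frozen at fit time: identifier columns
dropped; numeric missing values imputed with the training-split median;
categorical levels encoded alphabetically (unseen levels at apply time get
a reserved code equal to the map size rather than an error, for cross-site
robustness); min–max scaling to [0, 1] with out-of-range clipping and
constant columns mapped to 0.  Diagnosis codes follow the phenotype-table
convention 1 = Control → 0, 2 = ASD → 1.  Modalities are aligned by
sorted-id intersection: retaining only subjects present in both modalities
is strictly safer than positional truncation.  Fitting on the training
split only keeps cross-validation honest; nothing from a test split can
leak into imputation, encoding or scaling.

### MRI branch: CNN–GNN encoder

Two 3×3×3 convolution blocks (1 → 8 → 16 channels, stride 1, zero padding,
ReLU) preserve the spatial grid so the atlas mask stays aligned with the
feature maps.  Feature maps are pooled into one node per atlas region
(masked mean per channel; a raw-intensity pooling fallback is available via
`pool_raw_intensity`).  Nodes are connected when their regions share a
voxel face (6-connectivity), and two graph-convolution layers propagate
node features with the symmetric-normalized operator
`Â = D^{−1/2}(A + I)D^{−1/2}`.  Node embeddings are flattened in
ascending-label order (flattening makes the readout order-sensitive, so
the order is pinned) and mapped linearly to a 128-d embedding — the low end
of the admissible 128–256 range, chosen for desk-scale speed.  Training is
end-to-end with a temporary linear head and binary cross-entropy (Adam,
lr 1e-3, 30 epochs, minibatch 32); the head is discarded afterwards.
Dropout (rate 0.2) is applied to GNN activations during training only, so
inference is deterministic.

### Fusion autoencoder

The concatenation `[f_b, f_m]` (129-d by default) is standardized with
training-split z-scores — without this the 1-d behavioral scalar would be
negligible against the 128-d MRI block — and compressed 129 → 64 → 32 by
the encoder, with a mirrored decoder (ReLU on hidden layers, linear latent
and output, since post-embedding inputs are unbounded).  Training minimizes
mean squared reconstruction error (Adam, lr 1e-3, 30 epochs, batch 64).
Reconstruction error is reported on the original input scale.  An optional
behavioral-vector mode (used by the behavioral-only ablation arm) carries
the per-effect contribution vector alongside the scalar probability.

### Hypernetwork classifier

A shared network H (32 → 64 → 562, ReLU hidden, linear head) maps each
fused code z to that subject's classifier parameters
θ = (W1 ∈ R^{16×32}, b1 ∈ R^16, W2 ∈ R^{2×16}, b2 ∈ R^2), 562 scalars, and
the prediction is `softmax(W2 · ReLU(W1 z + b1) + b2)`.  H's own
architecture is the smallest plausible secondary network; its output head
is initialized at scale 1e-2 so that initial θ ≈ 0 and initial predictions
are near-uniform, which stabilizes training through the bilinear
(generated-weight) structure.  Training minimizes two-class cross-entropy
over the entire training set as a single batch (Adam, lr 1e-3, 30 epochs).
An exact probability tie is resolved to Control.  The fixed-weight
reference classifier for ablations is a single shared MLP with identical
target shapes trained under the same configuration.

Because every subject receives its own generated weights, the classifier
has very high effective capacity: on label noise it can memorize the
training set (training cross-entropy near zero) while held-out predictions
remain confident but uninformative.  Null calibration is therefore judged
on held-out accuracy (which stays at chance), not on held-out
cross-entropy.

### Evaluation

Confusion-matrix metrics treat ASD (label 1) as the positive class; ratios
with zero denominators are reported as NaN with a warning, never silently
zeroed.  AUC uses the rank (Mann–Whitney) statistic with midranks for
ties, which coincides with trapezoidal integration of the tie-aware ROC
curve to well below 1e-9.  The default split is stratified 80/20 with a
master seed (default 42) from which per-stage seeds are derived; stratified
k-fold construction keeps per-fold class proportions within one subject.
Permutation importance of a latent dimension is the mean held-out accuracy
drop over repeated within-column permutations.

### Ablation harness

Five variants under shared stratified 5-fold cross-validation, with the
behavioral model and MRI encoder fitted once per fold and reused:

* **full** — both branches, autoencoder fusion, hypernetwork;
* **no_autoencoder** — standardized concatenation fed directly to the
  hypernetwork (in-dimension 129 instead of 32);
* **no_gami** — MRI embedding only, still fused to 32-d;
* **no_cnn_gnn** — behavioral representation only (probability plus effect
  contributions, ~21-d); this already sits below the 32-d bottleneck, so it
  goes straight to the classifier rather than through an *expanding*
  autoencoder;
* **no_hypernetwork** — full fusion with the fixed-weight MLP.

Metrics are computed on pooled out-of-fold predictions; per-fold accuracies
are kept for paired seed-level comparisons.

## Synthetic cohorts

The generator emulates the weakest structure sufficient to exercise the
pipeline: behavioral features are standard normal with a mean shift of
`behavioral_effect` SDs on a chosen subset of features for ASD subjects;
volumes are unit-variance noise with a mean intensity shift of `roi_effect`
inside a chosen subset of atlas regions; missingness is completely at
random; classes are balanced to within one subject; the toy atlas is a
regular grid partition (so its face adjacency has a known closed form).
Everything is a deterministic function of the seed.

What passing tests show: the implementation recovers planted mean-shift
signals, calibrates to chance on null data, and the fused model is at
least as good as either single modality when signal is split across them.
What they do not show: performance on real cohorts — there is no site or
scanner heterogeneity, no covariate structure (age, sex), no realistic
anatomy, and no nonlinear or covariance-borne class signal.

## Problem sizes and defaults used in the shipped experiments

Signal-recovery runs use n = 400 subjects, 20 behavioral features (5
informative, shift 2.0 SD), 16³ volumes with a 16-region atlas (3
informative regions, shift 2.0), 5% missingness.  Null runs use n = 200
with both effects 0 on 8³ volumes.  The ablation study uses n = 200 with
moderate split signal (behavioral shift 1.0 on 3 features, ROI shift 1.0
on 2 of 8 regions, 8³ volumes) so that neither modality alone saturates.
Unit tests run miniature configurations of the same models; training
epochs in those miniatures are reduced via the stage configs, while the
defaults above remain the package defaults throughout.

## Known limitations

* The interaction-screening score is a training-set R² of a shallow tree;
  with very small samples it can prefer spurious pairs (the fit keeps at
  most `max_interactions` of them, and pruning can remove them later).
* The hypernetwork's memorization capacity means training-set metrics are
  not meaningful for model selection; use held-out folds.
* The CNN runs on whole volumes; per-region patch encoding is not
  implemented.
* No resampling: volumes and atlas must share one spatial grid.
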