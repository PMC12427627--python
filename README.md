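# neurofuse

Explainable multimodal classification of Autism Spectrum Disorder (ASD)
from behavioral phenotypes and structural brain MRI, for methods
researchers who want an interpretable, personalized fusion pipeline they
can test end to end on synthetic cohorts.

## The model

Four trainable stages compose into

    y_hat = h( AE([ f_b , f_m ]) )

* **f_b — additive behavioral network.** Each behavioral feature x_i gets
  its own subnetwork f_i, selected feature pairs get interaction
  subnetworks f_ij, and the ASD probability is
  `sigmoid( Σ_i f_i(x_i) + Σ_{(i,j)∈L} f_ij(x_i,x_j) + β0 )`.
  Per-subject effect contributions, variance-based importance rankings and
  partial-dependence curves are exact components of the model.
* **f_m — hybrid CNN–GNN volume encoder.** Shape-preserving 3×3×3
  convolutions, mean-pooling into one node per atlas region, graph
  convolutions over the region-adjacency graph
  (`Â = D^{−1/2}(A+I)D^{−1/2}`), and a linear readout to a 128-d embedding.
* **AE — fusion autoencoder.** Compresses the standardized concatenation
  `[f_b, f_m]` through 64 units to a shared 32-d latent code z.
* **h — hypernetwork-personalized classifier.** A shared network H maps
  each subject's z to that subject's own two-layer softmax MLP,
  θ = H(z) = (W1 ∈ R^{16×32}, b1, W2 ∈ R^{2×16}, b2) — 562 generated
  scalars — and predicts `softmax(W2·ReLU(W1 z + b1) + b2)`.

A synthetic cohort generator plants controllable mean-shift class effects
in both modalities (plus a toy grid atlas), so recovery, null calibration
and ablations are all reproducible without any data download.  All neural
components run on a small in-package numpy autodiff core; no GPU or deep
learning framework is required.

## Worked example

```python
import neurofuse as nf

cohort = nf.generate_cohort(
    n=400, n_features=20, behavioral_effect=2.0, n_informative_features=5,
    roi_effect=2.0, informative_rois=3, shape=(16, 16, 16), n_rois=16,
    missing_rate=0.05, seed=1,
)
result = nf.run_pipeline(cohort, nf.PipelineConfig(seed=1))
print(result.metrics.accuracy, result.metrics.auc)
print([name for name, _ in result.importance[:5]])
print(cohort.truth["informative_feature_names"])
```

prints

```
1.0 1.0
['feat_01*feat_17', 'feat_10', 'feat_06*feat_16', 'feat_06', 'feat_17']
['feat_01', 'feat_06', 'feat_10', 'feat_16', 'feat_17']
```

With a planted shift of 2 noise-SDs on 5 of 20 behavioral features and on
3 of 16 atlas regions, the 80-subject held-out split is classified
perfectly (accuracy 1.0, AUC 1.0), and the top-5 behavioral effects — main
effects and screened interactions — implicate exactly the five injected
features.  On a null cohort (both effects 0) held-out accuracy falls back
to chance.

The same flows are available from the shell:

```bash
neurofuse simulate --n 400 --behavioral-effect 2.0 --roi-effect 2.0 \
    --shape 16,16,16 --n-rois 16 --seed 1 --out cohort/
neurofuse train --cohort cohort/ --out run/
neurofuse ablate --cohort cohort/ --out ablation.json
```

`run/` receives `metrics.json`, `predictions.csv`, `roc.csv` and
`behavioral_importance.csv`.

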