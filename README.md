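# tepimage

Pathway-panel image classification of blood-platelet RNA-seq profiles.

Tumor-educated platelets (TEPs) carry an RNA cargo that shifts in the
presence of a tumor, which makes platelet RNA-seq from a blood draw a
candidate liquid-biopsy readout. `tepimage` turns each sample's
gene-level count profile into an image — one row per curated pathway
(cancer / signaling / metabolism blocks), one pixel per member gene, with
intensity encoding variance-stabilized expression — and trains a small
convolutional neural network to separate cancer cases from controls. The
pathway layout places co-acting genes next to each other, and a gene that
belongs to several pathways contributes one pixel per membership, so the
convolutional filters see biologically structured neighborhoods rather
than an arbitrary gene ordering.

The package is aimed at computational biologists evaluating
image-encoded transcriptome classifiers: it contains the full pipeline
(count filtering, median-of-ratios normalization, closed-form VST, GMT
panel handling, image construction, the CNN, and a stratified hold-out +
5-fold cross-validation harness with influence-curve cvAUC confidence
intervals), plus a negative-binomial cohort simulator so everything can
be exercised without access to patient data.

## The model in brief

Counts are normalized by median-of-ratios size factors and transformed
with the variance-stabilizing transformation for a negative-binomial
dispersion trend α(μ) = a0 + a1/μ:

    vst(u) = log2( (1 + a1 + 2·a0·u + 2·√(a0·u·(1 + a1 + a0·u))) / (4·a0) )

where u is the size-factor-normalized count. Each sample's panel image is
the global min–max rescaling of these values into [0, 1], arranged by
pathway; the classifier is a 10-layer network (two 3×3/4-filter tanh
convolutions, flatten, four decreasing ReLU dense layers with two
dropout layers, one sigmoid output) trained with class-weighted binary
cross-entropy (w_c = N/2n_c, with an optional extra positive-class
scale) under adadelta with per-epoch shuffling. The sigmoid output is
the TEP score: near 0 suggests a healthy donor, near 1 a cancer case,
reported per sample as the mean over the five fold models.

Details, defaults and design rationale are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Generate a synthetic cohort (30 cases / 30 controls, 2,000 genes, a
4-fold expression change in 2 of 12 pathways) and run the full study:

```sh
tepimage make-fixtures --workdir demo --seed 7 \
    --n-case 30 --n-control 30 --n-genes 2000 \
    --n-pathways 3 5 4 --n-signal 2 --log2-fc 2.0
printf 'epochs: 50\nn_folds: 5\n' > demo/config.yaml
tepimage train-eval --config demo/config.yaml \
    --counts demo/counts.tsv --annotation demo/annotation.tsv \
    --panel demo/panel.gmt --labels demo/labels.tsv \
    --workdir demo/run --seed 7
```

which prints the independent-test metrics averaged over the five fold
models:

```
{
  "sensitivity": 1.0,
  "specificity": 1.0,
  "balanced_accuracy": 1.0,
  "precision": 1.0,
  "recall": 1.0,
  "specificity_at_full_sensitivity": 1.0,
  "auc": 1.0
}
test cvAUC = 1.0000
```

A 4-fold pathway-level effect is strong, so the synthetic cohort is
separated perfectly: every held-out case scores above every held-out
control (AUC 1.0), and at the 0.5 threshold all calls are correct.
`demo/run/` also receives `metrics.json` (per-fold values, SDs, 95% CIs,
per-sample TEP scores), the split plan, ROC points and plots, and a
frozen model bundle (fold weights, intensity scaler, pruned panel,
dispersion trend) that `tepimage predict` applies to new cohorts without
refitting anything.

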