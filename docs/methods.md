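# Methods

## Overview

`tepimage` classifies blood-platelet RNA-seq profiles as cancer or
non-cancer by (1) normalizing a gene-level count matrix with a
variance-stabilizing transformation, (2) rendering each sample as a
pathway-panel image — one row per curated pathway, one pixel per member
gene — and (3) training a small convolutional network on those images
under a stratified hold-out / 5-fold cross-validation design. The target
application is tumor-educated platelet (TEP) diagnostics, where the
transcriptome shift induced by a tumor is distributed over many pathways
and the pathway layout gives the classifier a biologically structured
receptive field: genes that act together sit near each other, and a gene
in several pathways contributes several pixels.

## Preprocessing

Samples with fewer than 100,000 total reads are removed (strict
inequality; a sample at exactly the threshold is kept). Features are
collapsed to gene symbols using an annotation table (`source_id`,
`gene_name`, `status`, `level`): only status `known` survives, and when
several source ids share a gene name the smallest annotation level wins
(tier 1 is the highest-confidence tier), with equal-level ties broken
toward the larger total count.

Size factors follow the median-of-ratios convention: reference genes are
rows with no zero entry, and each sample's factor is the median over
reference genes of `count / geometric mean across samples`. The median is
taken in ratio space, so an even-sized reference set averages the two
middle ratios arithmetically — this is what makes the estimate agree
exactly with a brute-force implementation of the definition.

The variance-stabilizing transformation uses the closed form for a
negative-binomial model with a parametric dispersion-mean trend
`alpha(mu) = a0 + a1/mu`:

    vst(u) = log2( (1 + a1 + 2 a0 u + 2 sqrt(a0 u (1 + a1 + a0 u))) / (4 a0) )

with `u = count / size factor`. The transform is strictly increasing,
finite at `u = 0`, and adds one unit per doubling for large `u`. The
trend is fitted to per-gene method-of-moments dispersions
`max(0, (s^2 - mu)/mu^2)` by regressing on `1/mu` with iteratively
reweighted least squares (weights `1/fitted^2`, i.e. constant relative
error — the natural weighting for dispersion estimates whose sampling SD
scales with their magnitude), followed by a single exclusion of genes
more than 2 natural-log units off the fit and one refit. `a0` is floored
at 1e-4 so Poisson-like data yield a usable transform. These fitting
details (MoM start, 1/mu regression, 2-log-unit outlier rule, floor) are
this package's choices and are exposed as arguments.

By default the size-factor reference and the dispersion trend are
estimated on training samples only and applied to the whole cohort, so no
information flows from held-out samples into the transform
(`fit_on_training_only` switches this off).

## Panel images

The panel file is standard GMT (name, description, member genes) with the
category token — `cancer`, `signaling` or `metabolism` — in the
description field. Entries are ordered cancer block first, then
signaling, then metabolism, preserving file order within a block; gene
order within a pathway is taken from the file and treated as canonical.
Genes without expression data are pruned from each row; rows left empty
are dropped with a warning rather than kept as all-black rows.

Pixel intensity is a global min-max rescaling of the transformed
expression, with bounds fitted on training samples and clipped to [0, 1]
elsewhere. Global (rather than per-image) scaling is deliberate:
per-image scaling would erase between-sample level differences, which are
exactly what the classifier must see. Padding beyond a row's pathway
length is 0, rendering black like an absent transcript — the two are
indistinguishable by design, matching the black-equals-no-signal
semantics of the rendering. The network consumes the single-channel grid;
the black-to-red PNG export (`R = round(value * 255)`) is render-only,
since the colormap carries no extra information.

## Classifier

The network has 10 layers, 8 of them hidden: two valid-mode (unpadded)
2-D convolutions with four 3x3 filters and tanh activation, a flatten
layer, four ReLU dense layers with strictly decreasing widths (default
256, 64, 16, 4), dropout (rate 0.25) after the first two dense layers,
and one sigmoid output unit whose value in [0, 1] is the TEP score. No
pooling layers are used. The dense widths, dropout rates, epoch count
(50) and batch size (32) are this package's defaults, chosen to keep the
parameter count modest for desk-scale images; all are configuration
fields.

Training minimizes class-weighted binary cross-entropy. Class weights are
frequency-proportional, `w_c = N / (2 n_c)`, and the positive-class
weight can be multiplied by an extra sensitivity-pressure factor
(`positive_class_scale`; 1.06 reproduces the ovarian-cancer setting).
The optimizer is adadelta (decay `rho = 0.95`, `epsilon = 1e-6`, step
scale 1.0); training order is reshuffled each epoch from a seeded stream,
and dropout masks come from a second seeded stream, so a fixed seed gives
bit-identical histories in this single-threaded implementation. The
whole network — forward pass, backpropagation, optimizer — is implemented
in numpy with im2col convolutions; there is no framework dependency, and
model persistence is an `.npz` of weights plus a JSON architecture
sidecar.

A practical failure mode of this narrow architecture is ReLU collapse:
if the 4-unit layer dies, the output is constant and gradients vanish.
After the epoch loop, training therefore checks whether the model's
predictions on its own training set are constant (spread below 1e-6) and,
if so, restarts from a deterministically reseeded initialization (at most
twice); the restart count is recorded in the history. (See "Numerical
choices" below.)

## Validation design

The independent test set is a stratified 40% hold-out: per stratum,
`floor(0.40 * n)` samples are drawn without replacement from a seeded
stream. Strata carry class and control subtype (e.g. healthy vs benign),
so both are balanced; the floor rule reproduces an 11/12/81 test split
from 28/30/204 strata. The remaining 60% undergoes stratified 5-fold
cross-validation (delegated to scikit-learn's `StratifiedKFold` after
sorting ids, so plans are invariant to input order); each fold model uses
four subgroups for training and one as its validation set.

Metrics: sensitivity, specificity, balanced accuracy
(= (sensitivity + specificity)/2), precision (0 when no positive calls),
recall (= sensitivity), specificity at full sensitivity — the specificity
at the most permissive threshold that still calls every true case
positive — and Mann-Whitney AUC (concordant + half of tied pairs over all
case-control pairs). Class calls use a fixed 0.5 threshold, with a score
equal to the threshold counting as positive. Percentages are rounded half
away from zero.

Each fold model is evaluated on the fixed test set; per-metric aggregates
are the mean, sample SD and a normal-approximation 95% CI
(mean ± 1.96·SD/√K, clipped to [0, 1]) over the K fold models. The
per-sample TEP score is the arithmetic mean of the fold-model scores.
Cross-validated AUC is the mean of per-fold AUCs with an influence-curve
standard error: for a case, `IC = (F0(s) - AUC)/p1` where `F0` is the
control score CDF (ties at half weight); for a control,
`IC = (G1(s) - AUC)/p0` where `G1` is the case exceedance function; and
`SE^2 = K^-2 * sum_k var(IC_k)/n_k`. Folds containing a single class are
dropped with a warning. A fold-SD normal approximation is reported
alongside as `sd`.

## Synthetic cohorts

The generator emulates the count structure the preprocessing assumes:
negative-binomial counts with baseline means drawn log-normal(ln 50, 1),
dispersion trend `alpha(mu) = 0.05 + 2/mu`, and log-normal(0, 0.2)
library-size factors — enough spread to make size-factor estimation
non-trivial but stable. A class effect of `log2_fc` (default 1) is
applied to every gene of designated signal pathways in case samples, with
signs alternating along the sorted gene list so the image signal is a
texture rather than a brightness offset — a deliberately harder test of
the convolutional stage. The annotation table adds ~2% decoy rows
(duplicate names at level 2, unknown-status features) to exercise the
gene-mapping rules. Fixture panels draw pathway lengths uniformly from
[10, 80] and share a configurable fraction of genes across pathways to
exercise pixel multiplicity.

What the generator does not emulate: isoform-level structure, the
~40,000-feature scale of real platelet profiles, batch or flow-cell
effects, and biological correlation between genes beyond the shared class
effect. Passing the end-to-end tests therefore demonstrates that the
pipeline is wired correctly and can detect pathway-structured signal at
realistic depth and dispersion — not that it attains any particular
accuracy on real platelet cohorts.

## Numerical choices and degenerate inputs

- Empty cohorts (all samples filtered, no genes mappable, all pathways
  pruned) raise immediately with a description of the filter responsible.
- Size factors require at least one all-positive row; the pseudo-reference
  fallback is disabled by default and the error says so.
- A constant expression matrix cannot define an intensity scaler (error).
- Degenerate dispersion fits (non-finite coefficients) raise with
  diagnostics; `a0` is floored rather than allowed to reach 0.
- Scores are validated to [0, 1] everywhere; metric code rejects
  single-class inputs rather than returning NaN.
- Ties: a score equal to the decision threshold is a positive call; tied
  case-control score pairs count half in the AUC.
- The training-collapse restart triggers only when the prediction spread
  over the training set is below 1e-6 — with both classes present a
  constant output is never a valid fit; any genuine plateau with varying
  predictions is left alone. The restart offsets the
  weight-initialization seed deterministically, so runs stay reproducible.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline on
cohorts of 60 case / 60 control (signal, fold change 4 in 2 of 20
pathways) and 100/100 (null), with 2,000 genes and ~20-pathway panels;
dispersion-recovery checks use 2,000 genes by 100 samples. These sizes
were chosen as the smallest at which every stage (size factors, trend
fit, scaler, CNN, CV design) operates in its intended regime.

## Known limitations

- The dense widths and dropout rates are not claimed to match any
  previously tuned configuration; they are defaults, not reproductions.
- The CI convention (mean ± 1.96·SD/√K over fold models) is one of
  several reasonable readings of fold-aggregated reporting; unrounded
  values are always serialized next to rounded percentages.
- Per-gene dispersion shrinkage beyond the parametric trend is out of
  scope, as are batch correction and alternative normalizations.
- The classifier is strictly two-class (single sigmoid output).
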