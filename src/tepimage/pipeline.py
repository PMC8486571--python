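"""End-to-end study runner: preprocess -> images -> CV training -> metrics.

Ties the stages together under the study design: stratified 40% hold-out,
stratified 5-fold cross-validation on the remainder, one model per fold,
fold-averaged TEP scores and aggregated metrics on the independent test
set.  Normalization parameters (size-factor reference, dispersion trend)
and the intensity scaler are fitted on training samples only and applied
to all samples, so nothing leaks from the held-out set into the transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, network, panel as panel_mod, preprocess

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "preprocess_cohort", "run_study"]


@dataclass
class StudyConfig:
    min_total_reads: int = 100_000
    test_frac: float = 0.40
    n_folds: int = 5
    threshold: float = 0.5
    fit_on_training_only: bool = True
    network_spec: network.NetworkSpec = field(default_factory=network.NetworkSpec)
    train_config: network.TrainConfig = field(default_factory=network.TrainConfig)
    seed: int = 0


@dataclass
class StudyResult:
    report: evaluate.MetricsReport
    cv: dict  # cvAUC on the validation folds
    test_cv: dict  # cvAUC of fold models on the independent test set
    plan: evaluate.SplitPlan
    panel: panel_mod.PathwayPanel
    scaler: panel_mod.IntensityScaler
    trend: preprocess.DispersionTrend
    models: list[network.ConvNet]
    histories: list[dict]
    y_test: pd.Series


def preprocess_cohort(
    counts: preprocess.CountMatrix,
    annot: pd.DataFrame,
    min_total_reads: int = 100_000,
    train_ids: list[str] | None = None,
):
    """Filter, map and variance-stabilize a cohort.

    When ``train_ids`` is given, the size-factor reference (per-gene log
    geometric means) and dispersion trend are estimated on those samples
    only and applied to the full cohort.
    """
    filtered = preprocess.filter_samples(counts, min_total=min_total_reads)
    mapped = preprocess.map_genes(filtered, annot)
    if train_ids is not None:
        train_ids = [s for s in train_ids if s in mapped.sample_ids]
        ref = preprocess.CountMatrix(mapped.counts[train_ids])
    else:
        ref = mapped
    log_geomeans = preprocess.log_geometric_means(ref)
    sf_ref = preprocess.size_factors(ref, log_geomeans)
    trend = preprocess.fit_dispersion_trend(ref, sf_ref)
    sf_all = preprocess.size_factors(mapped, log_geomeans)
    normalized = preprocess.vst(mapped, sf_all, trend)
    return normalized, mapped, sf_all, trend


def run_study(
    counts: preprocess.CountMatrix,
    annot: pd.DataFrame,
    labels: pd.Series,
    strata: pd.Series,
    pathway_panel: panel_mod.PathwayPanel,
    cfg: StudyConfig | None = None,
) -> StudyResult:
    """Run the full classification study on a cohort."""
    cfg = cfg or StudyConfig()
    ss = np.random.SeedSequence(cfg.seed)
    seed_holdout, seed_kfold, *fold_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + cfg.n_folds)
    ]

    filtered = preprocess.filter_samples(counts, min_total=cfg.min_total_reads)
    ids = list(filtered.sample_ids)
    strata = strata.reindex(ids)
    labels = labels.reindex(ids)

    holdout = evaluate.stratified_holdout(
        ids, strata, test_frac=cfg.test_frac, seed=seed_holdout
    )
    test_ids = holdout.test_ids
    rest_ids = [s for s in ids if s not in set(test_ids)]

    train_ref = rest_ids if cfg.fit_on_training_only else None
    normalized, mapped, sf, trend = preprocess_cohort(
        filtered, annot, min_total_reads=cfg.min_total_reads, train_ids=train_ref
    )

    pruned = panel_mod.prune_panel(pathway_panel, set(normalized.index))
    panel_values = normalized.loc[
        sorted(pruned.gene_set), rest_ids if cfg.fit_on_training_only else ids
    ]
    scaler = panel_mod.fit_scaler(panel_values)
    images = {
        sid: panel_mod.build_image(normalized[sid], pruned, scaler).grid
        for sid in ids
    }

    kfold = evaluate.stratified_kfold(
        rest_ids, strata, k=cfg.n_folds, seed=seed_kfold
    )
    plan = evaluate.SplitPlan(
        test_ids=test_ids, folds=kfold.folds, strata=dict(strata)
    )

    x_test = np.stack([images[s] for s in test_ids])
    y_test = labels.loc[test_ids]

    models, histories, val_folds, test_scores = [], [], [], []
    for f, (train_ids_f, val_ids_f) in enumerate(plan.folds):
        x_tr = np.stack([images[s] for s in train_ids_f])
        y_tr = labels.loc[train_ids_f].to_numpy()
        x_va = np.stack([images[s] for s in val_ids_f])
        y_va = labels.loc[val_ids_f].to_numpy()

        spec = network.NetworkSpec(
            conv_filters=cfg.network_spec.conv_filters,
            kernel_size=cfg.network_spec.kernel_size,
            dense_units=cfg.network_spec.dense_units,
            dropout_rates=cfg.network_spec.dropout_rates,
            seed=fold_seeds[f],
        )
        tcfg = network.TrainConfig(
            epochs=cfg.train_config.epochs,
            batch_size=cfg.train_config.batch_size,
            learning_rate=cfg.train_config.learning_rate,
            rho=cfg.train_config.rho,
            epsilon=cfg.train_config.epsilon,
            positive_class_scale=cfg.train_config.positive_class_scale,
            shuffle_each_epoch=cfg.train_config.shuffle_each_epoch,
            seed=fold_seeds[f],
        )
        model = network.build_network(*x_tr.shape[1:3], spec)
        weights = network.class_weights(y_tr, tcfg.positive_class_scale)
        hist = network.train(
            model, x_tr, y_tr, weights, tcfg, validation=(x_va, y_va)
        )
        models.append(model)
        histories.append(hist)
        val_folds.append((y_va, network.predict_scores(model, x_va)))
        test_scores.append(network.predict_scores(model, x_test))
        logger.info(
            "fold %d: final loss %.4f, val loss %.4f",
            f, hist["loss"][-1], hist["val_loss"][-1],
        )

    cv = evaluate.cv_auc(val_folds)
    test_cv = evaluate.cv_auc([(y_test.to_numpy(), s) for s in test_scores])
    report = evaluate.aggregate_over_folds(
        y_test, test_scores, threshold=cfg.threshold
    )
    return StudyResult(
        report=report,
        cv=cv,
        test_cv=test_cv,
        plan=plan,
        panel=pruned,
        scaler=scaler,
        trend=trend,
        models=models,
        histories=histories,
        y_test=y_test,
    )
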