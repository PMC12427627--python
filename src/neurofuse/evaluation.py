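"""Metrics, cross-validation, pipeline orchestration and ablations.

Closed-form binary classification metrics from the confusion matrix
(positive class = ASD = 1), rank-based ROC/AUC with midrank tie handling,
stratified k-fold construction, the end-to-end train/evaluate pipeline
(preprocess -> additive behavioral model -> CNN-GNN encoder -> autoencoder
fusion -> hypernetwork classifier), a five-variant ablation harness under
shared folds, and permutation importance over fused latent dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import fusion as fusion_mod
from . import gami as gami_mod
from . import hypernet as hyper_mod
from . import mri as mri_mod
from .preprocess import (
    LabelVector,
    apply_preprocessor,
    encode_labels,
    fit_preprocessor,
)
from .synth import SyntheticCohort

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocCurve",
    "AblationReport",
    "PipelineConfig",
    "PipelineResult",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "stratified_kfold",
    "run_pipeline",
    "run_ablation",
    "permutation_importance",
    "ABLATION_VARIANTS",
]


# Metrics ---------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Counts with ASD (label 1) as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    n_correct: int
    auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "auc": self.auc,
            "n_correct": self.n_correct,
        }


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/TN/FP/FN for 0/1 label vectors."""
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if not (set(np.unique(y_true)) | set(np.unique(y_pred))) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return ConfusionMatrix(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Exact closed-form metrics; undefined ratios become NaN with a warning."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision = _safe_ratio(cm.TP, cm.TP + cm.FP, "precision")
    recall = _safe_ratio(cm.TP, cm.TP + cm.FN, "recall")
    specificity = _safe_ratio(cm.TN, cm.TN + cm.FP, "specificity")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan")
        if not (np.isnan(precision) or np.isnan(recall)):
            warnings.warn("f1 is undefined (zero denominator); reporting NaN")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=(cm.TP + cm.TN) / cm.total,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        n_correct=cm.TP + cm.TN,
    )


def roc_auc(y_true, scores) -> tuple[RocCurve, float]:
    """ROC curve via threshold sweep and AUC via the rank statistic.

    AUC uses the Mann-Whitney formulation with midranks for tied scores,
    which coincides with trapezoidal integration of the tie-aware curve.
    """
    y_true = np.asarray(y_true).astype(np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")

    # midranks without scipy: average rank over each tied block
    order = np.argsort(scores, kind="mergesort")
    sorted_s = scores[order]
    ranks = np.empty(len(scores))
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    auc = (ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for t, thr in enumerate(thresholds):
        pred = scores >= thr
        tpr[t] = np.sum(pred & (y_true == 1)) / n1
        fpr[t] = np.sum(pred & (y_true == 0)) / n0
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr), float(auc)


def stratified_kfold(y, k: int, seed: int = 0) -> list:
    """Disjoint, class-stratified fold index sets covering all subjects."""
    y = y.y if isinstance(y, LabelVector) else np.asarray(y)
    counts = np.bincount(y.astype(np.int64))
    if counts.min() < k:
        raise ValueError(f"each class needs at least {k} members for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


# Pipeline --------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Master configuration; per-stage seeds are derived from ``seed``."""

    test_fraction: float = 0.2
    seed: int = 42
    behavioral_vector: bool = False  # fuse per-effect contributions too
    gami: gami_mod.GAMIConfig = field(default_factory=gami_mod.GAMIConfig)
    encoder: mri_mod.EncoderConfig = field(default_factory=mri_mod.EncoderConfig)
    fusion: fusion_mod.FusionConfig = field(default_factory=fusion_mod.FusionConfig)
    hypernet: hyper_mod.HyperNetConfig = field(
        default_factory=hyper_mod.HyperNetConfig
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            test_fraction=d.get("test_fraction", 0.2),
            seed=d.get("seed", 42),
            behavioral_vector=d.get("behavioral_vector", False),
        )
        if "gami" in d:
            cfg.gami = gami_mod.GAMIConfig(**d["gami"])
        if "encoder" in d:
            cfg.encoder = mri_mod.EncoderConfig(**d["encoder"])
        if "fusion" in d:
            cfg.fusion = fusion_mod.FusionConfig(**d["fusion"])
        if "hypernet" in d:
            cfg.hypernet = hyper_mod.HyperNetConfig(**d["hypernet"])
        return cfg

    def stage_seed(self, offset: int) -> int:
        return (self.seed * 1009 + offset) % 2**31


@dataclass
class PipelineResult:
    metrics: MetricsReport
    confusion: ConfusionMatrix
    roc: RocCurve
    predictions: pd.DataFrame  # subject_id, y_true, p_control, p_asd, label
    importance: list  # behavioral effect importance ranking
    models: dict  # fitted stage models


@dataclass
class AblationReport:
    """Per-variant metrics under shared stratified folds."""

    variants: dict  # name -> MetricsReport (pooled out-of-fold predictions)
    fold_accuracies: dict  # name -> list of per-fold accuracies
    stages: dict  # name -> dict of stage flags

    def __post_init__(self):
        if set(self.variants) != set(ABLATION_VARIANTS):
            raise ValueError("ablation report must contain exactly the five variants")


def _replace_seed(cfg, seed: int):
    return type(cfg)(**{**cfg.__dict__, "seed": seed})


@dataclass
class _FittedStages:
    """Stage models fitted on one training split (shared across variants)."""

    gami_model: object
    encoder: object
    prob: np.ndarray  # behavioral probability, all subjects
    effects: np.ndarray  # behavioral effect contributions, all subjects
    emb: np.ndarray  # MRI embeddings, all subjects


def _fit_shared_stages(cohort: SyntheticCohort, train_idx, config: PipelineConfig
                       ) -> _FittedStages:
    labels = encode_labels(cohort.behavioral["DX_GROUP"])
    table = cohort.behavioral
    state = fit_preprocessor(table.iloc[train_idx])
    X_all = apply_preprocessor(state, table)

    gcfg = _replace_seed(config.gami, config.stage_seed(1))
    X_train = type(X_all)(
        values=X_all.values[train_idx],
        feature_names=X_all.feature_names,
        subject_ids=[X_all.subject_ids[i] for i in train_idx],
    )
    gmodel = gami_mod.fit_gami(X_train, labels.y[train_idx], gcfg)
    prob = gami_mod.gami_predict(gmodel, X_all).prob
    effects = gmodel.contributions(X_all.values)

    ecfg = _replace_seed(config.encoder, config.stage_seed(2))
    encoder = mri_mod.fit_mri_encoder(
        cohort.volumes[train_idx], cohort.atlas, labels.y[train_idx], ecfg
    )
    emb = encoder.embed(cohort.volumes)
    return _FittedStages(gami_model=gmodel, encoder=encoder, prob=prob,
                         effects=effects, emb=emb)


def _fuse_and_classify(stages: _FittedStages, y, train_idx, eval_idx,
                       config: PipelineConfig, use_autoencoder=True,
                       use_gami=True, use_mri=True, use_hypernet=True):
    """Train fusion + classifier on the training split; score ``eval_idx``.

    Returns (labels, probs, models) on the evaluation split.  Single-modality
    variants drop the other branch before fusion; without the autoencoder the
    standardized concatenation goes straight to the classifier; the
    non-personalized variant swaps the hypernetwork for the fixed MLP.
    Behavioral-only inputs (probability plus per-effect contributions) are
    already low-dimensional, so they skip the autoencoder as well.
    """
    if use_gami and use_mri:
        if config.behavioral_vector:
            F = np.concatenate(
                [stages.prob[:, None], stages.effects, stages.emb], axis=1
            )
        else:
            F = fusion_mod.concat_embeddings(stages.prob, stages.emb)
    elif use_mri:
        F = stages.emb
    elif use_gami:
        F = np.concatenate([stages.prob[:, None], stages.effects], axis=1)
        use_autoencoder = False
    else:
        raise ValueError("at least one modality must be enabled")

    models: dict = {}
    if use_autoencoder:
        fcfg = _replace_seed(config.fusion, config.stage_seed(3))
        ae = fusion_mod.fit_autoencoder(F[train_idx], fcfg)
        Z = fusion_mod.encode(ae, F)
        models["autoencoder"] = ae
    else:
        mu = F[train_idx].mean(axis=0)
        sd = np.maximum(F[train_idx].std(axis=0), 1e-8)
        Z = (F - mu) / sd

    hcfg = _replace_seed(config.hypernet, config.stage_seed(4))
    hcfg = hyper_mod.HyperNetConfig(**{**hcfg.__dict__, "latent_dim": Z.shape[1]})
    if use_hypernet:
        clf = hyper_mod.train_hypernet(Z[train_idx], y[train_idx], hcfg)
        labels_out, probs = hyper_mod.predict(clf, Z[eval_idx])
    else:
        clf = hyper_mod.train_fixed_mlp(Z[train_idx], y[train_idx], hcfg)
        labels_out, probs = hyper_mod.predict_fixed(clf, Z[eval_idx])
    models["classifier"] = clf
    models["Z"] = Z
    return labels_out, probs, models


def run_pipeline(cohort: SyntheticCohort, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Fit every stage on a stratified training split and score the held-out set.

    All stage models (preprocessing statistics included) are fitted on the
    training split only; metrics, the confusion matrix and the ROC curve are
    computed on the held-out split.
    """
    config = config or PipelineConfig()
    y = encode_labels(cohort.behavioral["DX_GROUP"]).y
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=y,
        random_state=config.seed % 2**31,
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)

    stages = _fit_shared_stages(cohort, train_idx, config)
    labels_out, probs, models = _fuse_and_classify(
        stages, y, train_idx, test_idx, config
    )

    cm = confusion(y[test_idx], labels_out)
    report = metrics_from_confusion(cm)
    curve, auc = roc_auc(y[test_idx], probs[:, 1])
    report.auc = auc
    sids = [cohort.subject_ids[i] for i in test_idx]
    preds = pd.DataFrame(
        {
            "subject_id": sids,
            "y_true": y[test_idx],
            "p_control": probs[:, 0],
            "p_asd": probs[:, 1],
            "label": labels_out,
        }
    )
    importance = gami_mod.gami_importance(
        stages.gami_model,
        apply_preprocessor(
            fit_preprocessor(cohort.behavioral.iloc[train_idx]),
            cohort.behavioral.iloc[train_idx],
        ),
    )
    return PipelineResult(
        metrics=report,
        confusion=cm,
        roc=curve,
        predictions=preds,
        importance=importance,
        models={"gami": stages.gami_model, "encoder": stages.encoder, **models},
    )


ABLATION_VARIANTS = {
    "full": dict(use_autoencoder=True, use_gami=True, use_mri=True,
                 use_hypernet=True),
    "no_autoencoder": dict(use_autoencoder=False, use_gami=True, use_mri=True,
                           use_hypernet=True),
    "no_gami": dict(use_autoencoder=True, use_gami=False, use_mri=True,
                    use_hypernet=True),
    "no_cnn_gnn": dict(use_autoencoder=True, use_gami=True, use_mri=False,
                       use_hypernet=True),
    "no_hypernetwork": dict(use_autoencoder=True, use_gami=True, use_mri=True,
                            use_hypernet=False),
}


def run_ablation(cohort: SyntheticCohort, config: PipelineConfig | None = None,
                 n_folds: int = 5) -> AblationReport:
    """Evaluate the five pipeline variants under shared stratified folds.

    Per fold, the behavioral model and the MRI encoder are fitted once on
    the training split and reused by every variant that needs them, so the
    variants differ only in the stages they ablate.  Metrics are computed on
    the pooled out-of-fold predictions; per-fold accuracies are kept for
    paired comparisons.
    """
    config = config or PipelineConfig()
    y = encode_labels(cohort.behavioral["DX_GROUP"]).y
    folds = stratified_kfold(y, n_folds, seed=config.seed % 2**31)
    all_idx = np.arange(len(y))

    pooled: dict = {name: {"true": [], "pred": [], "score": []}
                    for name in ABLATION_VARIANTS}
    fold_acc: dict = {name: [] for name in ABLATION_VARIANTS}
    for fold in folds:
        test_idx = np.sort(fold)
        train_idx = np.setdiff1d(all_idx, test_idx)
        stages = _fit_shared_stages(cohort, train_idx, config)
        for name, flags in ABLATION_VARIANTS.items():
            labels_out, probs, _ = _fuse_and_classify(
                stages, y, train_idx, test_idx, config, **flags
            )
            pooled[name]["true"].append(y[test_idx])
            pooled[name]["pred"].append(labels_out)
            pooled[name]["score"].append(probs[:, 1])
            fold_acc[name].append(float(np.mean(labels_out == y[test_idx])))

    variants = {}
    for name, d in pooled.items():
        yt = np.concatenate(d["true"])
        yp = np.concatenate(d["pred"])
        report = metrics_from_confusion(confusion(yt, yp))
        _, auc = roc_auc(yt, np.concatenate(d["score"]))
        report.auc = auc
        variants[name] = report
    return AblationReport(
        variants=variants,
        fold_accuracies=fold_acc,
        stages={name: dict(flags) for name, flags in ABLATION_VARIANTS.items()},
    )


def permutation_importance(predict_fn, Z, y, n_repeats: int = 10, seed: int = 0
                           ) -> pd.DataFrame:
    """Accuracy drop when each latent dimension is permuted.

    ``predict_fn(Z) -> labels``.  The importance of dimension d is the mean
    accuracy drop over ``n_repeats`` independent within-column permutations;
    a dimension the classifier never reads scores exactly 0.
    """
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    baseline = float(np.mean(predict_fn(Z) == y))
    rows = []
    for d in range(Z.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Zp = Z.copy()
            Zp[:, d] = Zp[rng.permutation(len(Z)), d]
            drops.append(baseline - float(np.mean(predict_fn(Zp) == y)))
        rows.append({"dimension": d, "importance": float(np.mean(drops))})
    table = pd.DataFrame(rows).sort_values(
        ["importance", "dimension"], ascending=[False, True]
    )
    return table.reset_index(drop=True)
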