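"""Performance metrics, repeated stratified cross-validation, independent tests.

Seven metrics are reported per evaluation: ACC = (TP+TN)/(TP+TN+FP+FN),
TPR = TP/(TP+FN), TNR = TN/(TN+FP), PPV = TP/(TP+FP),
F1 = 2·TPR·PPV/(TPR+PPV),
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), and the rank-based
AUC of the ROC.  A metric whose denominator is zero is reported as 0 with a
flag, which keeps aggregation across folds stable.

Cross-validation is stratified five-fold, repeated (default 10 times) with
repeat-indexed seeds; results are aggregated as mean ± sd both over all
fold measurements and over the per-repeat means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import InteractionModel, ModelConfig, build_model, predict, train

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "tpr", "tnr", "ppv", "f1", "mcc", "auc")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise EvaluationError("confusion counts must total at least 1")


@dataclass
class MetricsReport:
    acc: float
    tpr: float
    tnr: float
    ppv: float
    f1: float
    mcc: float
    auc: Optional[float] = None
    zero_denominator: Tuple[str, ...] = ()

    def as_dict(self) -> Dict[str, float]:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        return {k: v for k, v in d.items() if v is not None}


def confusion(labels: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; a score >= threshold predicts positive."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise EvaluationError("empty input")
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores lengths differ")
    if not set(np.unique(labels)) <= {0, 1}:
        raise EvaluationError("labels must be binary")
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


def _ratio(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Evaluate the six confusion-matrix metrics exactly; AUC is left unset."""
    flags: List[str] = []
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = _ratio(tp + tn, tp + tn + fp + fn, "acc", flags)
    tpr = _ratio(tp, tp + fn, "tpr", flags)
    tnr = _ratio(tn, tn + fp, "tnr", flags)
    ppv = _ratio(tp, tp + fp, "ppv", flags)
    f1 = _ratio(2 * tpr * ppv, tpr + ppv, "f1", flags)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    if flags:
        logger.info("zero-denominator metric(s) reported as 0: %s", flags)
    return MetricsReport(acc=acc, tpr=tpr, tnr=tnr, ppv=ppv, f1=f1, mcc=mcc,
                         zero_denominator=tuple(flags))


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 1/2."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold metrics plus AUC."""
    report = metrics_from_counts(confusion(labels, scores, threshold))
    report.auc = auc_score(labels, scores)
    return report


@dataclass
class CVResult:
    fold_reports: List[MetricsReport]
    repeat_means: List[Dict[str, float]]
    mean: Dict[str, float]
    sd_over_folds: Dict[str, float]
    sd_over_repeats: Dict[str, float]

    def as_dict(self) -> Dict:
        return {
            "mean": self.mean,
            "sd_over_folds": self.sd_over_folds,
            "sd_over_repeats": self.sd_over_repeats,
            "folds": [r.as_dict() for r in self.fold_reports],
        }


TrainFn = Callable[[np.ndarray, np.ndarray, np.ndarray, int], InteractionModel]


def _default_train_fn(cfg: ModelConfig) -> TrainFn:
    def fit(rna_X, prot_X, y, seed):
        fold_cfg = ModelConfig.from_dict({**cfg.to_dict(), "seed": seed})
        model = build_model(fold_cfg)
        return train(model, rna_X, prot_X, y)
    return fit


def cross_validate(
    rna_X: np.ndarray,
    prot_X: np.ndarray,
    y: np.ndarray,
    model_config: Optional[ModelConfig] = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    train_fn: Optional[TrainFn] = None,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the classifier.

    Fold assignment is stratified and re-drawn per repeat from
    repeat-indexed seeds; the model is trained on k-1 folds and scored on
    the held-out fold (the encoder is stateless, so features are computed
    once up front).  Deterministic for a fixed seed.
    """
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise EvaluationError(
            f"each class needs >= {folds} members, got {counts.tolist()}"
        )
    cfg = model_config or ModelConfig()
    fit = train_fn or _default_train_fn(cfg)
    fold_reports: List[MetricsReport] = []
    repeat_means: List[Dict[str, float]] = []
    for rep in range(repeats):
        rep_seed = (seed + 1000003 * rep) % (2 ** 31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        rep_reports = []
        for fold_i, (idx_train, idx_test) in enumerate(skf.split(rna_X, y)):
            model = fit(rna_X[idx_train], prot_X[idx_train], y[idx_train],
                        (rep_seed + fold_i) % (2 ** 31))
            scores = predict(model, rna_X[idx_test], prot_X[idx_test])
            rep_reports.append(evaluate_predictions(y[idx_test], scores))
        fold_reports.extend(rep_reports)
        repeat_means.append({
            name: float(np.mean([r.as_dict()[name] for r in rep_reports]))
            for name in METRIC_NAMES
        })
    mean = {name: float(np.mean([r.as_dict()[name] for r in fold_reports]))
            for name in METRIC_NAMES}
    sd_folds = {name: float(np.std([r.as_dict()[name] for r in fold_reports]))
                for name in METRIC_NAMES}
    sd_repeats = {name: float(np.std([m[name] for m in repeat_means]))
                  for name in METRIC_NAMES}
    return CVResult(fold_reports, repeat_means, mean, sd_folds, sd_repeats)


def independent_test(
    model: InteractionModel,
    rna_X: np.ndarray,
    prot_X: np.ndarray,
    y: np.ndarray,
    groups: Optional[Sequence[str]] = None,
    train_pair_keys: Optional[set] = None,
    test_pair_keys: Optional[Sequence[Tuple[str, str]]] = None,
    threshold: float = 0.5,
) -> Dict[str, Dict[str, float]]:
    """Evaluate a trained model on an independent set, optionally per group.

    Returns ``{group: {"n": ..., "n_correct": ..., "acc": ...}, ...,
    "total": {...}}``.  If both pair-key arguments are given, overlap
    between training and test pairs is checked and logged as a warning.
    """
    y = np.asarray(y, dtype=int)
    if train_pair_keys is not None and test_pair_keys is not None:
        overlap = set(test_pair_keys) & set(train_pair_keys)
        if overlap:
            logger.warning("%d test pair(s) overlap the training set", len(overlap))
    scores = predict(model, rna_X, prot_X)
    correct = (scores >= threshold).astype(int) == y
    if groups is None:
        groups = ["all"] * len(y)
    groups = list(groups)
    if len(groups) != len(y):
        raise EvaluationError("groups length differs from labels")
    out: Dict[str, Dict[str, float]] = {}
    for g in dict.fromkeys(groups):  # preserve first-seen order
        mask = np.array([grp == g for grp in groups])
        out[g] = {
            "n": int(mask.sum()),
            "n_correct": int(correct[mask].sum()),
            "acc": float(correct[mask].mean()),
        }
    out["total"] = {
        "n": int(len(y)),
        "n_correct": int(correct.sum()),
        "acc": float(correct.mean()),
    }
    return out
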