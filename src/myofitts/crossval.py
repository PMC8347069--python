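"""Cross-validated evaluation of gesture classifiers.

Implements 10-fold cross-validation with an overall 80/10/10
train/validation/test split: the test set is the k-th fold, the validation
set is a seeded stratified 1/9 of the remaining rows (used for early
stopping), and the rest trains the network.  Reports per-fold accuracies,
their mean and sample standard deviation, and a confusion matrix pooled
over the test folds with per-class precision/recall margins.

By default the PCA reduction is fitted once on the full feature table
before the folds are formed.  That mirrors the usual pattern-recognition
practice of preparing the feature matrix first, but lets the test folds
influence the projection; a leakage-free per-fold mode is available via
``pca_per_fold=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold, train_test_split

from .features import FeatureTable
from .network import NetConfig, fit_pca, train_network, transform, forward

__all__ = [
    "CvPlan",
    "FoldAssignment",
    "CvResult",
    "make_folds",
    "cross_validate",
    "confusion_stats",
    "pooled_model_eval",
]


@dataclass(frozen=True)
class CvPlan:
    """Fold-construction parameters."""

    n_folds: int = 10
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    stratified: bool = True
    grouped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("train/validation/test fractions must sum to 1")
        if abs(self.n_folds * self.fractions[2] - 1.0) > 1e-9:
            raise ValueError("test fraction must equal 1 / n_folds")


@dataclass
class FoldAssignment:
    """Disjoint train/validation/test row indices for one fold."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def make_folds(table: FeatureTable, plan: CvPlan | None = None) -> list[FoldAssignment]:
    """Partition table rows into ``n_folds`` train/validation/test splits.

    Test folds are disjoint and cover every row; stratification by gesture
    label is the default.  With ``grouped=True`` whole repetitions
    (session/event groups) are kept within a single test fold instead.
    Deterministic for a fixed seed.
    """
    plan = plan or CvPlan()
    y = table.labels
    n = len(y)
    if plan.stratified and not plan.grouped:
        unique, counts = np.unique(y, return_counts=True)
        lacking = unique[counts < plan.n_folds]
        if lacking.size:
            raise ValueError(
                f"class {lacking[0]!r} has fewer than {plan.n_folds} rows; "
                "cannot stratify"
            )
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed % (2**32)
        )
        split_iter = splitter.split(np.zeros(n), y)
    elif plan.grouped:
        splitter = GroupKFold(n_splits=plan.n_folds)
        split_iter = splitter.split(np.zeros(n), y, groups=table.groups)
    else:
        splitter = KFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed % (2**32)
        )
        split_iter = splitter.split(np.zeros(n))

    val_share = plan.fractions[1] / (plan.fractions[0] + plan.fractions[1])
    folds = []
    for k, (rest_idx, test_idx) in enumerate(split_iter):
        stratify = y[rest_idx] if plan.stratified else None
        train_idx, val_idx = train_test_split(
            rest_idx,
            test_size=val_share,
            stratify=stratify,
            random_state=(plan.seed + 7919 * (k + 1)) % (2**32),
        )
        folds.append(
            FoldAssignment(
                train=np.sort(train_idx),
                validation=np.sort(val_idx),
                test=np.sort(test_idx),
            )
        )
    return folds


@dataclass
class CvResult:
    """Cross-validation summary.

    ``confusion`` pools counts over all test folds; rows are true classes,
    columns predicted, both in ``labels`` order.
    """

    per_fold_accuracy: list[float]
    confusion: np.ndarray
    labels: list[str]
    n_rows: int = 0
    fold_logs: list[int] = field(default_factory=list)  # epochs trained per fold

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold_accuracy, ddof=1))

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean": self.mean,
            "sd": self.sd,
            "confusion": self.confusion.astype(int).tolist(),
            "labels": list(self.labels),
            "n_rows": int(self.n_rows),
            "epochs_per_fold": [int(e) for e in self.fold_logs],
        }


def cross_validate(
    table: FeatureTable,
    plan: CvPlan | None = None,
    netcfg: NetConfig | None = None,
    pca_threshold: float = 0.95,
    pca_per_fold: bool = False,
) -> CvResult:
    """Train one network per fold and evaluate on the held-out fold.

    Each fold gets a fresh seeded weight initialisation (seed offset by the
    fold index).  Accuracy is correct/total on the test fold; the reported
    spread is the sample standard deviation over folds.
    """
    plan = plan or CvPlan()
    netcfg = netcfg or NetConfig()
    labels = table.label_order
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    y = table.labels
    X = table.matrix

    folds = make_folds(table, plan)
    if not pca_per_fold:
        pca = fit_pca(table, threshold=pca_threshold)
        Z_all = transform(pca, X)

    K = len(labels)
    confusion = np.zeros((K, K), dtype=int)
    accuracies: list[float] = []
    epochs: list[int] = []
    for k, fold in enumerate(folds):
        if pca_per_fold:
            pca = fit_pca(X[fold.train], threshold=pca_threshold)
            Z_all = transform(pca, X)
        cfg_k = NetConfig(**{**netcfg.__dict__, "seed": netcfg.seed + k})
        try:
            w, labels_out, log = train_network(
                Z_all[fold.train], y[fold.train],
                Z_all[fold.validation], y[fold.validation],
                cfg_k, labels=labels,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed on fold {k}: {exc}") from exc
        _, probs = forward(w, Z_all[fold.test])
        pred = probs.argmax(axis=1)
        true = np.array([lab_idx[v] for v in y[fold.test]])
        accuracies.append(float(np.mean(pred == true)))
        np.add.at(confusion, (true, pred), 1)
        epochs.append(len(log))

    return CvResult(
        per_fold_accuracy=accuracies,
        confusion=confusion,
        labels=labels,
        n_rows=len(y),
        fold_logs=epochs,
    )


def confusion_stats(confusion: np.ndarray) -> dict:
    """Per-class recall/precision and overall accuracy of a count matrix.

    ``recall[c] = diag[c] / row_sum[c]``, ``precision[c] = diag[c] /
    col_sum[c]``; entries with a zero denominator are NaN (undefined).
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0):
        raise ValueError("confusion matrix must be non-negative")
    diag = np.diag(C)
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
    total = C.sum()
    accuracy = float(diag.sum() / total) if total > 0 else float("nan")
    return {"precision": precision, "recall": recall, "accuracy": accuracy}


def pooled_model_eval(
    tables: list[FeatureTable],
    plan: CvPlan | None = None,
    netcfg: NetConfig | None = None,
    pca_threshold: float = 0.95,
) -> CvResult:
    """Concatenate subject tables and cross-validate the pooled "general" model.

    All tables must share the feature-column schema and label set;
    provenance (session/event) columns are preserved through the pooling.
    """
    import pandas as pd

    if not tables:
        raise ValueError("need at least one table to pool")
    ref = tables[0]
    for t in tables[1:]:
        if t.feature_columns != ref.feature_columns:
            raise ValueError("feature-column schema mismatch between tables")
        if set(t.label_order) != set(ref.label_order):
            raise ValueError("label-set mismatch between tables")
    pooled = FeatureTable(
        data=pd.concat([t.data for t in tables], ignore_index=True),
        windowing=ref.windowing,
        features=ref.features,
    )
    return cross_validate(pooled, plan, netcfg, pca_threshold=pca_threshold)
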