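"""Performance metrics and evaluation schemes.

Metrics follow the standard confusion-table definitions: sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/total and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

with a zero denominator factor giving MCC = 0 (flagged in the report).
AUC is computed by the Mann-Whitney rank statistic (ties counted 1/2),
which equals the trapezoidal area under the threshold-swept ROC curve.

Schemes: jackknife (leave-one-out), stratified seeded k-fold, independent
train/test, and a positive:negative ratio sweep on a held-out set.  In
every scheme the feature scaling and the SVM are refit on the training
portion only; hyperparameters (c, g) are fixed inputs, selected once
beforehand (e.g. by :func:`psfmkit.model.grid_search`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .model import ModelError, ProfileSVMResults, train
from .profile_io import LabeledDataset
from .transforms import DEFAULT_D, feature_matrix


class EvaluationError(ValueError):
    """Raised for evaluation requests the data cannot support."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, list[str]]:
    """(SN, SP, ACC, MCC, flags) from a confusion table.

    SN (SP) is NaN, with a flag, when the positive (negative) class is
    absent; MCC is 0, with a flag, when any denominator factor vanishes.
    """
    if counts.total == 0:
        raise EvaluationError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn = float("nan")
        flags.append("SN undefined: no positive samples")
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp = float("nan")
        flags.append("SP undefined: no negative samples")
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        flags.append("MCC denominator zero, reported as 0")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, acc, mcc, flags


def roc_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points and AUC from binary labels and decision values.

    Returns
    -------
    roc_points : list of (threshold, FPR, TPR)
        Swept over unique decision values, descending; the curve starts at
        (0, 0) and ends at (1, 1).
    auc : float
        Mann-Whitney rank AUC (ties counted 1/2); equals the trapezoidal
        area under the returned curve.
    """
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC/AUC require both classes")
    ranks = rankdata(s)  # average ranks handle ties as 1/2 wins
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    points = [(float(t), float(f), float(p)) for t, f, p in zip(thr, fpr, tpr)]
    return points, float(auc)


@dataclass
class MetricsReport:
    """Pooled evaluation outcome for one scheme."""

    scheme: str
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc: list[tuple[float, float, float]] = field(repr=False)
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_predictions(
        cls, scheme: str, y_true, y_pred, scores
    ) -> "MetricsReport":
        counts = confusion(y_true, y_pred)
        sn, sp, acc, mcc, flags = metrics(counts)
        roc, auc = roc_auc(y_true, scores)
        return cls(scheme, counts, sn, sp, acc, mcc, auc, roc, flags)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "counts": {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            },
            "SN": self.sn,
            "SP": self.sp,
            "ACC": self.acc,
            "MCC": self.mcc,
            "AUC": self.auc,
            "flags": self.flags,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def summary(self) -> str:
        c = self.counts
        return (
            f"[{self.scheme}] N={c.total} TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}  "
            f"SN={self.sn:.4f} SP={self.sp:.4f} ACC={self.acc:.4f} "
            f"MCC={self.mcc:.4f} AUC={self.auc:.4f}"
        )


# ---------------------------------------------------------------------------
# Schemes
# ---------------------------------------------------------------------------

def _features(dataset: LabeledDataset, method: str, D: int | None):
    if D is None:
        D = DEFAULT_D.get(method)
    X, y, ids = feature_matrix(dataset, method, D)
    return X, y, ids, D


def jackknife(
    dataset: LabeledDataset,
    method: str = "dbt",
    D: int | None = None,
    c: float = 1.0,
    g: float = 1.0,
) -> MetricsReport:
    """Leave-one-out: each sample predicted by a machine trained (with its
    own scaling) on the other N-1; metrics pooled over all N predictions."""
    X, y, _, D = _features(dataset, method, D)
    n = len(y)
    if n < 3:
        raise EvaluationError("jackknife requires at least 3 samples")
    if len(np.unique(y)) < 2:
        raise EvaluationError("jackknife requires both classes")
    preds = np.empty(n, int)
    scores = np.empty(n, float)
    for i in range(n):
        mask = np.arange(n) != i
        res = train(X[mask], y[mask], c=c, g=g, method=method, D=D)
        lab, dec = res.predict(X[i : i + 1])
        preds[i], scores[i] = lab[0], dec[0]
    return MetricsReport.from_predictions("jackknife", y, preds, scores)


def kfold(
    dataset: LabeledDataset,
    k: int = 5,
    seed: int = 0,
    method: str = "dbt",
    D: int | None = None,
    c: float = 1.0,
    g: float = 1.0,
) -> MetricsReport:
    """Stratified seeded k-fold with pooled out-of-fold predictions."""
    X, y, _, D = _features(dataset, method, D)
    n = len(y)
    if k > n:
        raise EvaluationError(f"k={k} exceeds dataset size {n}")
    if k < 2:
        raise EvaluationError("kfold requires k >= 2")
    if k == n:
        # k = N is leave-one-out; stratification is vacuous.
        idx = np.arange(n)
        splits = [(idx[idx != i], idx[i : i + 1]) for i in range(n)]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    preds = np.empty(n, int)
    scores = np.empty(n, float)
    for tr, va in splits:
        res = train(X[tr], y[tr], c=c, g=g, method=method, D=D)
        lab, dec = res.predict(X[va])
        preds[va], scores[va] = lab, dec
    return MetricsReport.from_predictions(f"kfold(k={k}, seed={seed})", y, preds, scores)


def independent_test(
    train_dataset: LabeledDataset,
    test_dataset: LabeledDataset,
    method: str = "dbt",
    D: int | None = None,
    c: float = 1.0,
    g: float = 1.0,
) -> tuple[MetricsReport, ProfileSVMResults]:
    """Train once on the full training set, evaluate on a disjoint test set.

    Overlapping ids between the two sets are rejected: at the identifier
    level this guards against evaluating on training proteins.
    """
    overlap = sorted(set(train_dataset.ids) & set(test_dataset.ids))
    if overlap:
        raise EvaluationError(f"train/test ids overlap: {overlap}")
    Xtr, ytr, _, D = _features(train_dataset, method, D)
    Xte, yte, _, _ = _features(test_dataset, method, D)
    res = train(Xtr, ytr, c=c, g=g, method=method, D=D)
    lab, dec = res.predict(Xte)
    return MetricsReport.from_predictions("independent", yte, lab, dec), res


def ratio_sweep(
    test_dataset: LabeledDataset,
    results: ProfileSVMResults,
    ratios: list[float],
    seed: int = 0,
    repetitions: int = 10,
    method: str | None = None,
    D: int | None = None,
) -> list[tuple[float, float]]:
    """Mean accuracy on seeded subsamples at given positive:negative ratios.

    A ratio r uses n_neg = min(available negatives, floor(P / r)) negatives
    and round(r * n_neg) positives; each repetition redraws the subsample.
    """
    method = method or results.method
    D = D if D is not None else results.D
    X, y, _, _ = _features(test_dataset, method, D)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float]] = []
    for r in ratios:
        if r <= 0:
            raise EvaluationError(f"ratio must be positive, got {r}")
        n_neg = min(len(neg), int(len(pos) / r))
        n_pos = min(len(pos), int(round(r * n_neg)))
        if n_pos == 0 or n_neg == 0:
            raise EvaluationError(
                f"ratio {r} unrealizable with {len(pos)} positives and "
                f"{len(neg)} negatives"
            )
        accs = []
        for _ in range(repetitions):
            take = np.concatenate(
                [
                    rng.choice(pos, size=n_pos, replace=False),
                    rng.choice(neg, size=n_neg, replace=False),
                ]
            )
            lab, _ = results.predict(X[take])
            accs.append(float((lab == y[take]).mean()))
        out.append((r, float(np.mean(accs))))
    return out
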