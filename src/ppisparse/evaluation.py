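"""Evaluation criteria (ACC / SN / PE / MCC, ROC / AUC) and stratified
k-fold cross-validation of the sparse classifier.

All four scalar criteria are reported as percentages.  A metric whose
denominator vanishes is reported as undefined (``None``) with an
explanation, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import DataValidationError
from .features import PairSample, samples_to_matrix
from .sparse_classifier import (
    DEFAULT_EPSILON,
    DEFAULT_SIGMA,
    SparseRepresentationClassifier,
)

METRIC_NAMES = ("ACC", "SN", "PE", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / TN / FP / FN tallies of a binary evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls, y_true: Sequence[int], y_pred: Sequence[int], positive: int = 1
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true).ravel()
        yp = np.asarray(y_pred).ravel()
        if yt.size != yp.size:
            raise DataValidationError("y_true and y_pred differ in length")
        pos_t, pos_p = yt == positive, yp == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass(frozen=True)
class MetricsResult:
    """ACC / SN / PE / MCC as percentages; ``None`` marks an undefined metric."""

    acc: float | None
    sn: float | None
    pe: float | None
    mcc: float | None
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.acc, "SN": self.sn, "PE": self.pe, "MCC": self.mcc}


def metrics(counts: ConfusionCounts) -> MetricsResult:
    """Accuracy, sensitivity, precision and Matthews correlation coefficient.

    ACC = (TP+TN)/(TP+FP+TN+FN), SN = TP/(TP+FN), PE = TP/(TP+FP),
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),
    each multiplied by 100.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: dict[str, str] = {}

    def ratio(num: float, den: float, name: str, reason: str) -> float | None:
        if den == 0:
            undefined[name] = reason
            return None
        return 100.0 * num / den

    acc = ratio(tp + tn, counts.total, "ACC", "no evaluated samples")
    sn = ratio(tp, tp + fn, "SN", "no positive samples (TP+FN=0)")
    pe = ratio(tp, tp + fp, "PE", "no positive predictions (TP+FP=0)")

    mcc_den_sq = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if mcc_den_sq == 0:
        undefined["MCC"] = "a row or column of the confusion table is empty"
        mcc = None
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / sqrt(mcc_den_sq)

    return MetricsResult(acc=acc, sn=sn, pe=pe, mcc=mcc, undefined=undefined)


@dataclass(frozen=True)
class RocData:
    """ROC curve points and area under the curve.

    ``points`` has columns FPR, TPR sorted by FPR; AUC is the trapezoidal
    area.  Score convention: higher score means more likely positive.
    """

    scores: np.ndarray
    labels: np.ndarray
    points: pd.DataFrame
    auc: float

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocData:
    """Threshold-sweep ROC curve and trapezoidal AUC.

    Ties in the scores are handled by sklearn's threshold sweep (tied
    scores enter the curve at a single operating point); constant scores
    therefore give the chance diagonal and AUC 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise DataValidationError("scores and labels differ in length")
    if np.unique(labels).size != 2:
        raise DataValidationError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"FPR": fpr, "TPR": tpr})
    return RocData(scores=scores, labels=labels, points=points, auc=auc)


@dataclass
class CrossValidationResult:
    """Per-fold and aggregate results of a stratified k-fold run."""

    fold_metrics: pd.DataFrame  # one row per fold: ACC SN PE MCC (+ counts)
    mean: pd.Series
    std: pd.Series
    roc: RocData
    config: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_of: np.ndarray

    def summary(self) -> str:
        """Human-readable report of per-fold and mean +/- sd metrics."""
        cfg = self.config
        lines = [
            f"{cfg['mode'].upper()} {cfg['k']}-fold cross-validation "
            f"(sigma={cfg['sigma']:g}, epsilon={cfg['epsilon']:g}, "
            f"seed={cfg['seed']}, n={self.y_true.size})",
            "",
            self.fold_metrics.to_string(
                float_format=lambda v: f"{v:.2f}", index=False
            ),
            "",
        ]
        for m in METRIC_NAMES:
            if np.isnan(self.mean[m]):
                lines.append(f"mean {m}: undefined in every fold")
            else:
                lines.append(
                    f"mean {m}: {self.mean[m]:.2f} +/- {self.std[m]:.2f} %"
                )
        lines.append(f"pooled AUC: {self.roc.auc:.5f}")
        return "\n".join(lines)


def cross_validate(
    samples: Sequence[PairSample] | np.ndarray,
    y: np.ndarray | None = None,
    k: int = 5,
    mode: str = "wsrc",
    sigma: float = DEFAULT_SIGMA,
    epsilon: float = DEFAULT_EPSILON,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the sparse classifier.

    Parameters
    ----------
    samples : list of PairSample, or ndarray (n_samples, d)
        Labeled pair samples, or a design matrix (then ``y`` is required).
    k : int
        Number of folds (default 5).
    mode, sigma, epsilon :
        Classifier configuration, see
        :class:`~ppisparse.sparse_classifier.SparseRepresentationClassifier`.
    seed : int
        Controls the shuffled stratified partition; the same seed gives
        identical folds and metrics.

    Returns
    -------
    CrossValidationResult
        Per-fold ACC/SN/PE/MCC, their mean and sd across folds, and the
        ROC over the pooled out-of-fold residual-margin scores.
    """
    if y is None:
        X, y = samples_to_matrix(samples)  # type: ignore[arg-type]
    else:
        X = np.asarray(samples, dtype=np.float64)
        y = np.asarray(y).ravel()
    if k < 2:
        raise DataValidationError(f"need at least 2 folds, got {k}")
    class_counts = np.unique(y, return_counts=True)[1]
    if class_counts.size != 2:
        raise DataValidationError("cross-validation requires a binary dataset")
    if class_counts.min() < k:
        raise DataValidationError(
            f"smallest class has {class_counts.min()} samples < k={k} folds; "
            "reduce k or enlarge the dataset"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(y.size)
    fold_of = np.empty(y.size, dtype=np.int64)

    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = SparseRepresentationClassifier(
            mode=mode, sigma=sigma, epsilon=epsilon
        ).fit(X[tr], y[tr])
        for i in te:
            code = clf.classify_one(X[i])
            y_pred[i] = code.predicted_class
            scores[i] = code.residuals[0] - code.residuals[1]
        fold_of[te] = fold
        counts = ConfusionCounts.from_labels(y[te], y_pred[te])
        res = metrics(counts)
        rows.append(
            {
                "fold": fold,
                **{m: (np.nan if v is None else v) for m, v in res.as_dict().items()},
                "TP": counts.tp,
                "TN": counts.tn,
                "FP": counts.fp,
                "FN": counts.fn,
            }
        )

    fold_metrics = pd.DataFrame(rows)
    mean = fold_metrics[list(METRIC_NAMES)].mean()
    std = fold_metrics[list(METRIC_NAMES)].std()
    roc = roc_auc(scores, y)
    config = {"k": k, "mode": mode, "sigma": sigma, "epsilon": epsilon, "seed": seed}
    return CrossValidationResult(
        fold_metrics=fold_metrics,
        mean=mean,
        std=std,
        roc=roc,
        config=config,
        y_true=y.copy(),
        y_pred=y_pred,
        scores=scores,
        fold_of=fold_of,
    )
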