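"""Classification metrics and percentile-bootstrap 95% confidence intervals.

Point metrics (AUROC, precision/recall/F1, AUPRC, confusion matrix) are
computed with scikit-learn. Uncertainty follows the benchmark protocol: the
test set is resampled with replacement K times at its own size, the metric
is computed on each resample, and the 95% CI is the 2.5th/97.5th percentile
of the K replicates; the point estimate is the metric on the un-resampled
test set. Resamples on which the metric is undefined (e.g. a rare positive
class vanishing) are redrawn a bounded number of times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from ._seeds import derive_seed

__all__ = [
    "UndefinedMetricError",
    "MetricReport",
    "BootstrapResult",
    "auroc",
    "auprc",
    "prf_confusion",
    "evaluate",
    "bootstrap_ci",
    "bootstrap_report",
    "write_report",
]


class UndefinedMetricError(ValueError):
    """The metric is not defined on the given labels (e.g. one class only)."""


def _as_arrays(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if len(labels) == 0:
        raise ValueError("empty input")
    return scores, labels


def auroc(scores, labels, average: str = "macro") -> float:
    """Area under the ROC curve.

    Binary scores (1-D, or the positive-class column of a 2-column matrix)
    give the usual pairwise-concordance AUROC (ties count 1/2). A (n, k)
    probability matrix gives one-vs-rest AUROC averaged per ``average``
    (macro by default; micro also supported).
    """
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs at least two classes present")
    if scores.ndim == 1 or scores.shape[1] == 2:
        pos = scores if scores.ndim == 1 else scores[:, 1]
        return float(skm.roc_auc_score(labels, pos))
    if len(np.unique(labels)) < scores.shape[1]:
        # one-vs-rest AUROC is undefined for an absent class; callers
        # (the bootstrap) redraw such degenerate samples
        raise UndefinedMetricError("AUROC needs every class present in labels")
    return float(
        skm.roc_auc_score(
            labels,
            scores / scores.sum(axis=1, keepdims=True),
            multi_class="ovr",
            average=average,
            labels=np.arange(scores.shape[1]),
        )
    )


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise integration
    (average precision) for a binary task."""
    scores, labels = _as_arrays(scores, labels)
    if scores.ndim == 2:
        scores = scores[:, 1]
    if not np.any(labels == 1):
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(skm.average_precision_score(labels, scores))


def prf_confusion(predicted, labels, n_classes: int | None = None) -> dict:
    """Confusion matrix plus per-class and averaged precision/recall/F1."""
    predicted, labels = _as_arrays(predicted, labels)
    predicted = predicted.astype(int)
    k = n_classes or int(max(predicted.max(), labels.max())) + 1
    cls = np.arange(k)
    confusion = skm.confusion_matrix(labels, predicted, labels=cls)
    prec, rec, f1, support = skm.precision_recall_fscore_support(
        labels, predicted, labels=cls, zero_division=0
    )
    out = {
        "confusion_matrix": confusion,
        "per_class": pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1, "support": support},
            index=pd.Index(cls, name="class"),
        ),
    }
    for avg in ("macro", "weighted"):
        p, r, f, _ = skm.precision_recall_fscore_support(
            labels, predicted, labels=cls, average=avg, zero_division=0
        )
        out[f"{avg}_precision"], out[f"{avg}_recall"], out[f"{avg}_f1"] = (
            float(p),
            float(r),
            float(f),
        )
    return out


@dataclass
class MetricReport:
    """Point metrics of one model on one test set."""

    n_test: int
    n_classes: int
    accuracy: float
    auroc_macro: float
    auroc_micro: float
    macro_f1: float
    weighted_f1: float
    macro_precision: float
    macro_recall: float
    confusion_matrix: np.ndarray
    per_class: pd.DataFrame
    auprc: float | None = None  # binary tasks only

    def to_dict(self) -> dict:
        d = {
            "n_test": self.n_test,
            "n_classes": self.n_classes,
            "accuracy": self.accuracy,
            "auroc_macro": self.auroc_macro,
            "auroc_micro": self.auroc_micro,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "confusion_matrix": self.confusion_matrix.tolist(),
        }
        if self.auprc is not None:
            d["auprc"] = self.auprc
        return d


def evaluate(scores, labels, n_classes: int | None = None) -> MetricReport:
    """Full metric report from a per-class probability matrix."""
    scores, labels = _as_arrays(scores, labels)
    if scores.ndim != 2:
        raise ValueError("evaluate expects an (n, k) score matrix")
    k = n_classes or scores.shape[1]
    pred = scores.argmax(axis=1)
    prf = prf_confusion(pred, labels, n_classes=k)
    binary = k == 2
    return MetricReport(
        n_test=len(labels),
        n_classes=k,
        accuracy=float((pred == labels).mean()),
        auroc_macro=auroc(scores if k > 2 else scores[:, 1], labels),
        auroc_micro=(
            auroc(scores, labels, average="micro") if k > 2 else auroc(scores[:, 1], labels)
        ),
        macro_f1=prf["macro_f1"],
        weighted_f1=prf["weighted_f1"],
        macro_precision=prf["macro_precision"],
        macro_recall=prf["macro_recall"],
        confusion_matrix=prf["confusion_matrix"],
        per_class=prf["per_class"],
        auprc=auprc(scores[:, 1], labels) if binary else None,
    )


@dataclass
class BootstrapResult:
    """Point estimate plus percentile 95% CI from K test-set resamples."""

    metric: str
    K: int
    point: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False, default=None)

    def __str__(self) -> str:
        return f"{self.metric}: {self.point:.3f} ({self.ci_low:.3f}-{self.ci_high:.3f})"


def bootstrap_ci(
    metric_fn: Callable,
    scores,
    labels,
    K: int,
    seed: int = 0,
    metric_name: str = "metric",
    max_retries: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap: K same-size with-replacement resamples.

    ``metric_fn(scores_subset, labels_subset)`` may raise
    :class:`UndefinedMetricError` on a degenerate resample (e.g. the rare
    positive class missing); such resamples are redrawn up to ``max_retries``
    times each before the whole computation fails.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    scores, labels = _as_arrays(scores, labels)
    n = len(labels)
    point = float(metric_fn(scores, labels))
    rng = np.random.default_rng(derive_seed(seed, "bootstrap", metric_name))
    reps = np.empty(K)
    for k in range(K):
        for _attempt in range(max_retries):
            idx = rng.integers(0, n, size=n)
            try:
                reps[k] = float(metric_fn(scores[idx], labels[idx]))
                break
            except UndefinedMetricError:
                continue
        else:
            raise UndefinedMetricError(
                f"{metric_name}: metric undefined on {max_retries} consecutive resamples"
            )
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(metric_name, K, point, float(lo), float(hi), reps)


def _accuracy(scores, labels):
    pred = np.asarray(scores).argmax(axis=1)
    return float((pred == np.asarray(labels)).mean())


def _macro_f1(scores, labels):
    pred = np.asarray(scores).argmax(axis=1)
    return prf_confusion(pred, labels, n_classes=np.asarray(scores).shape[1])["macro_f1"]


def bootstrap_report(
    scores, labels, K: int, seed: int = 0, n_classes: int | None = None
) -> dict[str, BootstrapResult]:
    """Bootstrap the headline metrics (AUROC, macro-F1, accuracy, and AUPRC
    on binary tasks) with one shared resampling budget K."""
    scores, labels = _as_arrays(scores, labels)
    k = n_classes or scores.shape[1]

    def _auroc(s, l):
        return auroc(s if k > 2 else s[:, 1], l)

    fns: dict[str, Callable] = {
        "auroc": _auroc,
        "macro_f1": _macro_f1,
        "accuracy": _accuracy,
    }
    if k == 2:
        fns["auprc"] = lambda s, l: auprc(s[:, 1], l)
    return {
        name: bootstrap_ci(fn, scores, labels, K, seed=seed, metric_name=name)
        for name, fn in fns.items()
    }


def write_report(
    directory: str | Path,
    report: MetricReport,
    bootstraps: dict[str, BootstrapResult] | None = None,
) -> None:
    """Write metrics as JSON + CSV tables (point, ci_low, ci_high per metric)
    and the confusion matrix as CSV, mirroring the benchmark table layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = report.to_dict()
    rows = []
    if bootstraps:
        doc["bootstrap"] = {}
        for name, b in bootstraps.items():
            doc["bootstrap"][name] = {
                "K": b.K,
                "point": b.point,
                "ci_low": b.ci_low,
                "ci_high": b.ci_high,
            }
            rows.append(
                {"metric": name, "point": b.point, "ci_low": b.ci_low, "ci_high": b.ci_high}
            )
    (directory / "metrics.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
    if rows:
        pd.DataFrame(rows).to_csv(directory / "metrics.csv", index=False)
    pd.DataFrame(report.confusion_matrix).to_csv(directory / "confusion_matrix.csv")
    report.per_class.to_csv(directory / "per_class.csv")
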