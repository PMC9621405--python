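"""Labeler evaluation: confusion counts, precision/recall/F1, percentile
bootstrap confidence intervals, multilabel stratified splitting and
prevalence bookkeeping.

The labeler is scored against human ground truth per class with the usual
binary metrics

.. math::

    P = \\frac{TP}{TP+FP}, \\qquad R = \\frac{TP}{TP+FN}, \\qquad
    F_1 = \\frac{2PR}{P+R},

macro-averaged (unweighted mean) across classes.  When a denominator is
zero the metric defaults to 1.0 and the result is flagged ``degenerate``
("no predictions, no mistakes"); pass ``zero_division=0.0`` for the
pessimistic convention.  Confidence intervals are nonparametric percentile
bootstrap: rows are resampled with replacement (3,000 replicates by
default), the statistic recomputed per replicate, and the 2.5/97.5
percentiles reported.

The train/validation split is a 7/3 greedy iterative stratification over
the five labels so that each class's prevalence in both folds approximates
the full-dataset prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .labeler import LABEL_COLUMNS

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "confusion",
    "metrics",
    "macro_average",
    "bootstrap_ci",
    "stratified_split",
    "prevalence_summary",
    "metrics_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (display convention for tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class binary confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ClassMetrics:
    """Precision/recall/F1 for one class, optionally with a bootstrap CI."""

    precision: float
    recall: float
    f1: float
    ci_low: float | None = None
    ci_high: float | None = None
    degenerate: bool = False


def _align(pred: pd.DataFrame, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if len(pred) != len(truth):
        raise ValueError(
            f"pred has {len(pred)} rows but truth has {len(truth)}"
        )
    for name, df in (("pred", pred), ("truth", truth)):
        if "status" in df.columns and (df["status"] == "manual_pending").any():
            raise ValueError(f"{name} contains manual_pending rows")
    if "study_id" in pred.columns and "study_id" in truth.columns:
        if set(pred["study_id"]) != set(truth["study_id"]):
            raise ValueError("pred and truth study_id sets differ")
        pred = pred.sort_values("study_id").reset_index(drop=True)
        truth = truth.sort_values("study_id").reset_index(drop=True)
    return pred, truth


def confusion(
    pred: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, ConfusionCounts]:
    """Per-class confusion counts from aligned prediction and ground-truth
    label tables (matched on ``study_id`` when present)."""
    pred, truth = _align(pred, truth)
    out: dict[str, ConfusionCounts] = {}
    for cls in LABEL_COLUMNS:
        p = pred[cls].to_numpy(dtype=bool)
        t = truth[cls].to_numpy(dtype=bool)
        out[cls] = ConfusionCounts(
            tp=int(np.sum(p & t)),
            fp=int(np.sum(p & ~t)),
            tn=int(np.sum(~p & ~t)),
            fn=int(np.sum(~p & t)),
        )
    return out


def metrics(counts: ConfusionCounts, zero_division: float = 1.0) -> ClassMetrics:
    """Precision, recall and F1 from confusion counts.

    A zero denominator yields ``zero_division`` (default 1.0) and sets the
    ``degenerate`` flag.  Values are carried at full precision; round for
    display with :func:`round_half_up`.
    """
    degenerate = False
    if counts.tp + counts.fp == 0:
        precision, degenerate = zero_division, True
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, degenerate = zero_division, True
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(
        precision=precision, recall=recall, f1=f1, degenerate=degenerate
    )


def macro_average(per_class: Mapping[str, ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean of each metric over classes."""
    if not per_class:
        raise ValueError("empty metrics map")
    ms = list(per_class.values())
    return ClassMetrics(
        precision=float(np.mean([m.precision for m in ms])),
        recall=float(np.mean([m.recall for m in ms])),
        f1=float(np.mean([m.f1 for m in ms])),
        degenerate=any(m.degenerate for m in ms),
    )


_STATS = ("precision", "recall", "f1")


def bootstrap_ci(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    statistic: str,
    class_name: str,
    n_replicates: int = 3000,
    seed: int = 0,
    levels: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for one per-class metric.

    Rows are resampled with replacement (same n) ``n_replicates`` times and
    the named statistic recomputed on each replicate; the interval is the
    ``levels`` percentiles of the replicate distribution.  Reproducible for
    a fixed seed.  If the statistic's denominator is degenerate on more
    than half the replicates the fixture is too small to bootstrap and an
    error is raised.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}; one of {_STATS}")
    if class_name not in LABEL_COLUMNS:
        raise ValueError(f"unknown class {class_name!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    pred, truth = _align(pred, truth)
    p = pred[class_name].to_numpy(dtype=bool)
    t = truth[class_name].to_numpy(dtype=bool)
    n = len(p)
    rng = np.random.default_rng(seed)
    values = np.empty(n_replicates)
    n_degenerate = 0
    for i in range(n_replicates):
        idx = rng.integers(0, n, n)
        pi, ti = p[idx], t[idx]
        c = ConfusionCounts(
            tp=int(np.sum(pi & ti)),
            fp=int(np.sum(pi & ~ti)),
            tn=int(np.sum(~pi & ~ti)),
            fn=int(np.sum(~pi & ti)),
        )
        m = metrics(c)
        if m.degenerate:
            n_degenerate += 1
        values[i] = getattr(m, statistic)
    if n_degenerate > n_replicates / 2:
        raise ValueError(
            f"{statistic} undefined on {n_degenerate}/{n_replicates} "
            "replicates; use a larger evaluation fixture"
        )
    low, high = np.percentile(values, levels)
    return float(low), float(high)


def stratified_split(
    manifest: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a label table into train/validation folds preserving per-class
    prevalence (greedy iterative stratification, rarest label first).

    Rows must be fully annotated (no ``manual_pending``).  Classes without
    positives are ignored for stratification with a warning; an all-negative
    manifest degenerates to a plain random split.  Deterministic for a
    fixed seed; the folds are disjoint and cover the manifest, with
    ``round(train_fraction · n)`` rows in train.
    """
    import logging

    logger = logging.getLogger(__name__)
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    if "status" in manifest.columns and (
        manifest["status"] == "manual_pending"
    ).any():
        raise ValueError("manifest contains manual_pending rows")
    n = len(manifest)
    if n == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(seed)

    labels = manifest[list(LABEL_COLUMNS)].to_numpy(dtype=int)
    class_totals = labels.sum(axis=0)
    active = [i for i, tot in enumerate(class_totals) if tot > 0]
    for i, tot in enumerate(class_totals):
        if tot == 0:
            logger.warning(
                "class %r has no positives; ignored for stratification",
                LABEL_COLUMNS[i],
            )

    n_train = int(math.floor(train_fraction * n + 0.5))
    capacity = np.array([n_train, n - n_train], dtype=float)
    fractions = np.array([train_fraction, 1.0 - train_fraction])
    # desired positives per (fold, class)
    desired = np.outer(fractions, class_totals).astype(float)

    order = rng.permutation(n)
    assigned = np.full(n, -1, dtype=int)
    remaining = set(range(n))

    def _assign(row: int, fold: int) -> None:
        assigned[row] = fold
        capacity[fold] -= 1
        desired[fold] -= labels[row]
        remaining.discard(row)

    while True:
        counts = {
            c: sum(1 for r in remaining if labels[r, c]) for c in active
        }
        counts = {c: k for c, k in counts.items() if k > 0}
        if not counts:
            break
        # rarest remaining label first; deterministic tie-break by index
        cls = min(counts, key=lambda c: (counts[c], c))
        for row in order:
            if row not in remaining or not labels[row, cls]:
                continue
            open_folds = [f for f in (0, 1) if capacity[f] > 0]
            if not open_folds:
                open_folds = [0, 1]
            best = max(
                open_folds,
                key=lambda f: (desired[f, cls], capacity[f], rng.random()),
            )
            _assign(row, best)

    for row in order:
        if row in remaining:
            open_folds = [f for f in (0, 1) if capacity[f] > 0]
            if not open_folds:
                open_folds = [0, 1]
            best = max(open_folds, key=lambda f: (capacity[f], rng.random()))
            _assign(row, best)

    train = manifest.iloc[assigned == 0]
    validation = manifest.iloc[assigned == 1]
    return train, validation


def prevalence_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-class positive/negative counts and percent positive
    (``100·pos/(pos+neg)``, two-decimal display rounding)."""
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rows = []
    for cls in LABEL_COLUMNS:
        pos = int(manifest[cls].sum())
        neg = int(len(manifest) - pos)
        rows.append(
            {
                "class": cls,
                "positives": pos,
                "negatives": neg,
                "percent_positive": round_half_up(100.0 * pos / (pos + neg), 2),
            }
        )
    return pd.DataFrame(rows)


def metrics_table(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    n_replicates: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Full evaluation table: counts + metrics per class plus macro row.

    Columns: ``class,tp,fp,tn,fn,precision,recall,f1,ci_low,ci_high``
    (metrics display-rounded to 4 decimals).  With ``n_replicates > 0`` a
    bootstrap CI for F1 is added per class.
    """
    counts = confusion(pred, truth)
    rows = []
    per_class: dict[str, ClassMetrics] = {}
    for cls in LABEL_COLUMNS:
        m = metrics(counts[cls])
        if n_replicates > 0:
            m.ci_low, m.ci_high = bootstrap_ci(
                pred, truth, "f1", cls, n_replicates=n_replicates, seed=seed
            )
        per_class[cls] = m
        c = counts[cls]
        rows.append(
            {
                "class": cls,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "precision": round_half_up(m.precision, 4),
                "recall": round_half_up(m.recall, 4),
                "f1": round_half_up(m.f1, 4),
                "ci_low": None if m.ci_low is None else round_half_up(m.ci_low, 4),
                "ci_high": None
                if m.ci_high is None
                else round_half_up(m.ci_high, 4),
            }
        )
    mac = macro_average(per_class)
    rows.append(
        {
            "class": "macro_average",
            "tp": None,
            "fp": None,
            "tn": None,
            "fn": None,
            "precision": round_half_up(mac.precision, 4),
            "recall": round_half_up(mac.recall, 4),
            "f1": round_half_up(mac.f1, 4),
            "ci_low": None,
            "ci_high": None,
        }
    )
    return pd.DataFrame(rows)
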