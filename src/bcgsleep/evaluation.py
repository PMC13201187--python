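"""Leave-one-subject-out evaluation of predicted hypnograms.

One fold per subject; all of a subject's sessions travel together, so no
epoch of a held-out subject ever influences training-fold statistics.
Scores follow the standard confusion-matrix definitions: one-vs-rest
sensitivity, specificity, precision and F1 per stage, overall accuracy
(trace over total) and Cohen's kappa; fold metrics are aggregated as
mean +/- sample SD across folds, with per-stage metrics undefined (and
excluded from averaging, not zero-filled) when a stage is absent from a
fold.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bcgsleep.signal_io import Hypnogram, STAGES, STAGES_3CLASS

_RELABEL = {"W": "W", "N1": "NREM", "N2": "NREM", "N3": "NREM",
            "REM": "REM", "NREM": "NREM"}


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    held_out: str
    training: tuple[str, ...]


@dataclasses.dataclass
class StageMetrics:
    sensitivity: float
    specificity: float
    precision: float
    f1: float


@dataclasses.dataclass
class MetricReport:
    classes: tuple[str, ...]
    confusion: np.ndarray                 # rows = reference, cols = predicted
    accuracy: float
    kappa: float
    per_stage: dict[str, StageMetrics]


def loso_folds(subjects: Sequence[str]) -> list[FoldPlan]:
    """One fold per subject; held-out sets partition the subject list."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    return [FoldPlan(i, s, tuple(x for x in subjects if x != s))
            for i, s in enumerate(subjects)]


def relabel_3class(h: Hypnogram) -> Hypnogram:
    """W stays W, the three non-REM depths merge into NREM, REM stays REM.
    Idempotent on already-relabeled input."""
    return Hypnogram(tuple(_RELABEL[s] for s in h.stages))


def confusion_matrix(ref: Sequence[str], pred: Sequence[str],
                     classes: Sequence[str]) -> np.ndarray:
    if len(ref) != len(pred):
        raise ValueError("reference and prediction lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for r, p in zip(ref, pred):
        cm[index[r], index[p]] += 1
    return cm


def confusion_and_metrics(ref: Sequence[str], pred: Sequence[str],
                          classes: Optional[Sequence[str]] = None
                          ) -> MetricReport:
    """Accuracy, kappa and one-vs-rest per-stage rates from label sequences.

    Stages absent from both reference and prediction get NaN metrics
    (flagged undefined), never silent zeros.
    """
    if classes is None:
        present = set(ref) | set(pred)
        classes = STAGES if present <= set(STAGES) else STAGES_3CLASS
    cm = confusion_matrix(ref, pred, classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else np.nan
    kappa = cohens_kappa_from_matrix(cm)
    per_stage = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn + fp == 0:
            per_stage[c] = StageMetrics(np.nan, np.nan, np.nan, np.nan)
            continue
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        f1 = (2 * prec * sens / (prec + sens)
              if np.isfinite(prec) and np.isfinite(sens) and prec + sens > 0
              else np.nan)
        per_stage[c] = StageMetrics(float(sens), float(spec), float(prec),
                                    float(f1) if f1 == f1 else np.nan)
    return MetricReport(tuple(classes), cm, accuracy, float(kappa), per_stage)


def cohens_kappa_from_matrix(cm: np.ndarray) -> float:
    total = cm.sum()
    if total == 0:
        return float("nan")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if pe == 1.0:
        # both raters constant and identical; agreement is perfect by
        # convention though chance correction is undefined
        return 1.0
    return float((po - pe) / (1.0 - pe))


def cohens_kappa(ref: Sequence[str], pred: Sequence[str]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e)/(1 - p_e)."""
    if len(ref) != len(pred) or len(ref) == 0:
        raise ValueError("need equal-length, non-empty label sequences")
    classes = sorted(set(ref) | set(pred))
    return cohens_kappa_from_matrix(confusion_matrix(ref, pred, classes))


@dataclasses.dataclass
class AggregateReport:
    classes: tuple[str, ...]
    pooled_confusion: np.ndarray
    fold_accuracy: np.ndarray
    fold_kappa: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    kappa_mean: float
    kappa_sd: float
    pooled_accuracy: float
    pooled_kappa: float
    per_stage: pd.DataFrame   # tidy: stage, metric, mean, sd, n_folds


def aggregate_folds(reports: Sequence[MetricReport]) -> AggregateReport:
    """Mean +/- sample SD across folds, plus the pooled confusion matrix.

    The fold-mean accuracy is the headline number; pooled-over-epochs
    figures are also reported.  Per-stage metrics undefined in a fold are
    excluded from that stage's average.
    """
    if not reports:
        raise ValueError("need at least one fold report")
    classes = reports[0].classes
    pooled = np.sum([r.confusion for r in reports], axis=0)
    acc = np.array([r.accuracy for r in reports])
    kap = np.array([r.kappa for r in reports])

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    rows = []
    for c in classes:
        for metric in ("sensitivity", "specificity", "precision", "f1"):
            vals = np.array([getattr(r.per_stage[c], metric) for r in reports])
            vals = vals[np.isfinite(vals)]
            rows.append({
                "stage": c, "metric": metric,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": sd(vals) if vals.size else np.nan,
                "n_folds": int(vals.size),
            })
    return AggregateReport(
        classes=classes,
        pooled_confusion=pooled,
        fold_accuracy=acc,
        fold_kappa=kap,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=sd(acc),
        kappa_mean=float(kap.mean()),
        kappa_sd=sd(kap),
        pooled_accuracy=float(np.trace(pooled) / pooled.sum()),
        pooled_kappa=cohens_kappa_from_matrix(pooled),
        per_stage=pd.DataFrame(rows),
    )
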