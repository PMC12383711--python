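"""Balanced accuracy and per-class F-scores for prediction streams.

Each 59-sample block is one classification event.  Balanced accuracy is
the mean of the two per-class recalls; the per-class F-score is the
F1 measure (beta configurable) treating that class as positive, with the
zero-division convention that an undefined precision/recall/F collapses
to 0.  The numeric work is delegated to scikit-learn; the wrappers add the
validation and conventions used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

__all__ = ["balanced_accuracy", "f_score", "confusion", "MetricReport",
           "session_report"]


def _as_arrays(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    return y_true, y_pred


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the per-class recalls over the two classes present in
    y_true; raises if the truth is single-class (the metric is undefined)."""
    y_true, y_pred = _as_arrays(y_true, y_pred)
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValueError(f"balanced accuracy undefined: truth contains "
                         f"only class {classes[0]!r}")
    return float(skm.balanced_accuracy_score(y_true, y_pred))


def f_score(y_true, y_pred, positive_class, beta: float = 1.0) -> float:
    """Per-class F-score, 0 by convention when precision+recall vanish."""
    y_true, y_pred = _as_arrays(y_true, y_pred)
    return float(skm.fbeta_score(y_true, y_pred, beta=beta,
                                 labels=[positive_class],
                                 average=None, zero_division=0)[0])


def confusion(y_true, y_pred, positive_class) -> dict:
    """TP/FP/FN/TN counts with the given positive class."""
    y_true, y_pred = _as_arrays(y_true, y_pred)
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass
class MetricReport:
    session_id: int
    mode_tags: dict
    mcd_balanced_accuracy: float | None = None
    mcd_f_walk: float | None = None
    mcd_f_idle: float | None = None
    mcd_confusion: dict | None = None
    mcd_feedback_balanced_accuracy: float | None = None
    mcd_feedback_f_walk: float | None = None
    mcd_feedback_f_idle: float | None = None
    nrd_balanced_accuracy: float | None = None
    nrd_f_satis0: float | None = None
    nrd_f_satis1: float | None = None
    nrd_confusion: dict | None = None
    rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def session_report(results, mode_tags: dict | None = None,
                   session_id: int = 0) -> MetricReport:
    """Per-session metrics from a list of decoder BlockResult objects.

    Reports MCD metrics against the desired action (and, when feedback was
    applied, for the post-feedback action too) and NRD metrics against the
    satisfaction label.  A tidy row list (session, approach, experiment,
    feedback, metric, class, value) is attached for CSV export.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to report")
    tags = dict(mode_tags or {})
    rep = MetricReport(session_id=session_id, mode_tags=tags)
    base = {"session": session_id,
            "approach": tags.get("approach", ""),
            "experiment": tags.get("experiment", "")}

    def add_row(feedback, metric, cls, value):
        rep.rows.append({**base, "feedback": feedback, "metric": metric,
                         "class": cls, "value": value})

    action_true = np.array([r.action_desired for r in results], dtype=object)
    if not any(a is None for a in action_true):
        pred = np.array([r.action_predicted for r in results], dtype=object)
        rep.mcd_balanced_accuracy = balanced_accuracy(action_true, pred)
        rep.mcd_f_walk = f_score(action_true, pred, "walk")
        rep.mcd_f_idle = f_score(action_true, pred, "idle")
        rep.mcd_confusion = confusion(action_true, pred, "walk")
        add_row("NO", "balanced_accuracy", "", rep.mcd_balanced_accuracy)
        add_row("NO", "f_score", "walk", rep.mcd_f_walk)
        add_row("NO", "f_score", "idle", rep.mcd_f_idle)
        if any(getattr(r, "feedback_applied", False) for r in results):
            post = np.array([r.action_after_feedback for r in results],
                            dtype=object)
            rep.mcd_feedback_balanced_accuracy = balanced_accuracy(
                action_true, post)
            rep.mcd_feedback_f_walk = f_score(action_true, post, "walk")
            rep.mcd_feedback_f_idle = f_score(action_true, post, "idle")
            add_row("YES", "balanced_accuracy", "",
                    rep.mcd_feedback_balanced_accuracy)
            add_row("YES", "f_score", "walk", rep.mcd_feedback_f_walk)
            add_row("YES", "f_score", "idle", rep.mcd_feedback_f_idle)

    satis_true = np.array([r.satis_label for r in results])
    if not any(s is None for s in satis_true):
        satis_true = satis_true.astype(int)
        spred = np.array([r.satis_predicted for r in results], dtype=int)
        if len(np.unique(satis_true)) > 1:
            rep.nrd_balanced_accuracy = balanced_accuracy(satis_true, spred)
            add_row("NO", "nrd_balanced_accuracy", "",
                    rep.nrd_balanced_accuracy)
        rep.nrd_f_satis0 = f_score(satis_true, spred, 0)
        rep.nrd_f_satis1 = f_score(satis_true, spred, 1)
        rep.nrd_confusion = confusion(satis_true, spred, 0)
        add_row("NO", "nrd_f_score", "SATIS=0", rep.nrd_f_satis0)
        add_row("NO", "nrd_f_score", "SATIS=1", rep.nrd_f_satis1)
    return rep
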