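"""Ground-truth validation of classified maps: buffers, confusion, ROC/AUC.

The protocol mirrors the field validation design: random ground-truth points
(about 100 per ecosystem), each assessed within a fixed-radius buffer
(default 300 m). For every point the worst degradation class and the highest
aggregate score among the features intersecting its buffer become the model
prediction; points whose buffer touches no feature are flagged and excluded.
Accuracy is summarized as a 2x2 confusion matrix of the binary
degraded / not-degraded reduction and as the ROC curve with its AUC, where
the ranking variable is the continuous aggregate score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import AlignmentError, EmptyValidationError, UndefinedAUCError
from .features import CLASS_ORDER, DEGRADED, NATURAL, worst_class

log = logging.getLogger(__name__)

DEFAULT_BUFFER_M = 300.0
STRONG_MODEL_AUC = 0.800  # verdict threshold separating strong/moderate models


@dataclass
class RocCurve:
    """ROC curve points (starting at (0,0), ending at (1,1)) and its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def extract_model_at_points(points, features, radius: float = DEFAULT_BUFFER_M) -> pd.DataFrame:
    """Model score/class at each validation point via a fixed-radius buffer.

    ``points`` is an iterable of (x, y) pairs or shapely Points. Returns a
    DataFrame with columns x, y, model_score, model_class, in_buffer; points
    with an empty buffer have in_buffer=False and NaN score. Raises
    :class:`EmptyValidationError` if every buffer is empty.
    """
    feats = list(features)
    pts = [p if isinstance(p, Point) else Point(p) for p in points]
    geoms = [f.geometry for f in feats]
    tree = STRtree(geoms) if geoms else None
    rows = []
    for p in pts:
        hit_scores, hit_classes = [], []
        if tree is not None:
            for idx in tree.query(p.buffer(radius)):
                f = feats[idx]
                if f.geometry.dwithin(p, radius):
                    hit_scores.append(f.score)
                    hit_classes.append(f.degradation_class)
        if hit_classes:
            rows.append((p.x, p.y, float(np.nanmax(hit_scores)), worst_class(hit_classes), True))
        else:
            rows.append((p.x, p.y, np.nan, None, False))
    df = pd.DataFrame(rows, columns=["x", "y", "model_score", "model_class", "in_buffer"])
    if not df["in_buffer"].any():
        raise EmptyValidationError("no validation point buffer intersects any feature")
    n_out = int((~df["in_buffer"]).sum())
    if n_out:
        log.warning("extract_model_at_points: %d of %d points had empty buffers",
                    n_out, len(df))
    return df


def binarize_classes(classes, degraded_only: bool = True) -> np.ndarray:
    """Binary reduction of 3-way classes: degraded=1 (optionally semi too)."""
    cut = CLASS_ORDER[DEGRADED] if degraded_only else CLASS_ORDER[NATURAL] + 1
    return np.array([int(CLASS_ORDER[c] >= cut) for c in classes])


def confusion_matrix(truth, predicted) -> dict:
    """2x2 binary confusion counts {tp, tn, fp, fn}; counts sum to n."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise AlignmentError(f"label length mismatch: {t.shape} vs {p.shape}")
    return {
        "tp": int(np.sum((t == 1) & (p == 1))),
        "tn": int(np.sum((t == 0) & (p == 0))),
        "fp": int(np.sum((t == 0) & (p == 1))),
        "fn": int(np.sum((t == 1) & (p == 0))),
    }


def roc_auc(truth, scores) -> RocCurve:
    """ROC curve and trapezoidal AUC, ranking by continuous score.

    Equal scores are grouped into a single threshold step, so the AUC equals
    the normalized Mann-Whitney U statistic with ties counted half.
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise AlignmentError(f"truth and scores length mismatch: {t.shape} vs {s.shape}")
    if len(np.unique(t)) < 2:
        raise UndefinedAUCError("ROC/AUC undefined: only one class present in truth")
    fpr, tpr, thr = _roc_curve(t, s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


def validation_report(truth, scores, classes, ecosystem: str = "") -> dict:
    """Confusion counts, AUC and a strong/moderate verdict for one ecosystem."""
    pred = binarize_classes(classes)
    cm = confusion_matrix(truth, pred)
    roc = roc_auc(truth, scores)
    return {
        "ecosystem": ecosystem,
        **cm,
        "n": int(len(np.asarray(truth))),
        "auc": roc.auc,
        "verdict": "strong" if roc.auc >= STRONG_MODEL_AUC else "moderate-or-weak",
    }
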