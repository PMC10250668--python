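"""Empirical ROC analysis: AUC, significance, and optimal cutoffs.

The AUC is the probability that a randomly chosen positive patient
outscores a randomly chosen negative one (ties count one half), i.e. the
trapezoidal area under the empirical ROC curve.  Significance against
AUC = 0.5 uses the Hanley-McNeil standard error.  Optimal cutoffs are
selected over midpoint candidates by the Youden index J = sens + spec - 1
with the decision rule "positive if score >= cutoff" (direction-aware),
which reproduces the half-step cutoff style of clinical ROC tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import norm_sf, round_half_up
from .rules import ConfusionMatrix, metrics as cm_metrics


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sens: float
    spec: float
    ppv: float
    npv: float
    youden: float
    accuracy: float
    cm: ConfusionMatrix


@dataclass(frozen=True)
class ROCSummary:
    predictor: str
    auc: float
    auc_se: float
    auc_p: float
    direction: str
    candidate_cutoffs: tuple[float, ...] = field(repr=False)
    best_cutoff: float = math.nan
    sens: float = math.nan
    spec: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    degenerate: bool = False


def _check_xy(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; drop them first")
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    return s, y


def candidate_cutoffs(scores) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus two sentinels.

    The sentinels (one below the minimum, one above the maximum) give the
    rule "positive if score >= cutoff" its trivial endpoints: everyone
    positive (sens 100 / spec 0) and everyone negative.  All-identical
    scores yield the sentinels only.
    """
    s = np.unique(np.asarray(scores, dtype=float))
    if s.size < 1:
        raise ValueError("need at least one score")
    mids = (s[:-1] + s[1:]) / 2.0
    return np.concatenate([[s[0] - 1.0], mids, [s[-1] + 1.0]])


def auc(scores, labels, direction: str = "higher") -> float:
    """Empirical AUC: P(score_pos > score_neg) + 0.5 * P(tie).

    ``direction="lower"`` means lower scores indicate the positive class;
    the scores are negated internally.
    """
    s, y = _check_xy(scores, labels)
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if direction == "lower":
        s = -s
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    i = 0
    s_sorted = s[order]
    while i < len(s):
        j = i
        while j + 1 < len(s) and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_test(auc_value: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley-McNeil SE of the AUC and two-sided p against AUC = 0.5."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class counts must be positive")
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    se = math.sqrt(max(var, 0.0))
    if se == 0.0:
        return 0.0, (1.0 if a == 0.5 else 0.0)
    z = abs(a - 0.5) / se
    return se, min(1.0, 2.0 * norm_sf(z))


def _confusion_at(s: np.ndarray, y: np.ndarray, cutoff: float, direction: str) -> ConfusionMatrix:
    pred = s >= cutoff if direction == "higher" else s <= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def best_cutoff(
    scores, labels, criterion: str = "youden", direction: str = "higher"
) -> CutoffResult:
    """Optimal cutoff over the midpoint candidates.

    ``criterion`` is ``"youden"`` (J = sens + spec - 1) or ``"accuracy"``.
    Ties are broken by higher specificity, then by lower cutoff.  Reported
    percentages are rounded half-up to one decimal; the confusion matrix
    carries the exact counts.
    """
    s, y = _check_xy(scores, labels)
    if criterion not in ("youden", "accuracy"):
        raise ValueError("criterion must be 'youden' or 'accuracy'")
    best = None
    for cut in candidate_cutoffs(s):
        cm = _confusion_at(s, y, cut, direction)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        obj = sens + spec - 1.0 if criterion == "youden" else (cm.tp + cm.tn) / len(y)
        key = (obj, spec, -cut)
        if best is None or key > best[0]:
            best = (key, cut, cm, sens, spec)
    _, cut, cm, sens, spec = best
    m = cm_metrics(cm)
    return CutoffResult(
        cutoff=float(cut),
        sens=m["sens"],
        spec=m["spec"],
        ppv=m["ppv"],
        npv=m["npv"],
        youden=sens + spec - 1.0,
        accuracy=m["accuracy"],
        cm=cm,
    )


def roc_curve_points(scores, labels, direction: str = "higher") -> pd.DataFrame:
    """(cutoff, sensitivity, 1-specificity) at every candidate cutoff."""
    s, y = _check_xy(scores, labels)
    rows = []
    for cut in candidate_cutoffs(s):
        cm = _confusion_at(s, y, cut, direction)
        rows.append(
            {
                "cutoff": float(cut),
                "sens": cm.tp / (cm.tp + cm.fn),
                "fpr": cm.fp / (cm.fp + cm.tn),
            }
        )
    return pd.DataFrame(rows)


def roc_table(
    predictors: pd.DataFrame,
    labels,
    directions: dict[str, str] | None = None,
    criterion: str = "youden",
) -> pd.DataFrame:
    """One ROC summary row per predictor column.

    Rows with missing predictor values are dropped per predictor.  A
    constant predictor is flagged degenerate rather than raising, so one
    uninformative column does not abort a whole report.
    """
    directions = directions or {}
    y_all = np.asarray(labels).astype(int)
    rows = []
    for name in predictors.columns:
        direction = directions.get(name, "higher")
        col = predictors[name].to_numpy(dtype=float)
        keep = ~np.isnan(col)
        s, y = col[keep], y_all[keep]
        if np.unique(s).size < 2 or np.unique(y).size < 2:
            rows.append(
                ROCSummary(
                    predictor=name,
                    auc=math.nan,
                    auc_se=math.nan,
                    auc_p=math.nan,
                    direction=direction,
                    candidate_cutoffs=(),
                    degenerate=True,
                )
            )
            continue
        a = auc(s, y, direction)
        se, p = auc_test(a, int(y.sum()), int(len(y) - y.sum()))
        bc = best_cutoff(s, y, criterion=criterion, direction=direction)
        rows.append(
            ROCSummary(
                predictor=name,
                auc=round_half_up(a, 2),
                auc_se=se,
                auc_p=p,
                direction=direction,
                candidate_cutoffs=tuple(candidate_cutoffs(s)),
                best_cutoff=bc.cutoff,
                sens=bc.sens,
                spec=bc.spec,
                ppv=bc.ppv,
                npv=bc.npv,
            )
        )
    out = pd.DataFrame(
        [
            {
                "predictor": r.predictor,
                "auc": r.auc,
                "auc_se": r.auc_se,
                "auc_p": r.auc_p,
                "best_cutoff": r.best_cutoff,
                "sens": r.sens,
                "spec": r.spec,
                "ppv": r.ppv,
                "npv": r.npv,
                "direction": r.direction,
                "degenerate": r.degenerate,
            }
            for r in rows
        ]
    ).set_index("predictor")
    return out
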