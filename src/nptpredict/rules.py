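"""Confusion-matrix algebra and the combined "activity OR VAS" rule.

The diagnostic algorithm calls a patient NPT-positive when the combined
IgE-specific activity for Phl p 5 + Cyn d 1 is >= 7.25% OR the
retrospective VAS for rhinitis severity in the past pollen season is
>= 7 (both comparisons inclusive).  This module also reconstructs
confusion matrices from published sensitivity/specificity and class
sizes, which lets printed PPV/NPV columns be checked exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import round_half_up


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class RuleSpec:
    """Combined decision rule: activity and VAS cutoffs joined by OR/AND."""

    activity_cutoff: float = 7.25
    vas_cutoff: float = 7.0
    combinator: str = "OR"

    def __post_init__(self) -> None:
        # cutoffs above the score range are allowed: they disable a criterion
        if self.activity_cutoff < 0.0:
            raise ValueError("activity cutoff cannot be negative")
        if self.vas_cutoff < 0.0:
            raise ValueError("VAS cutoff cannot be negative")
        if self.combinator not in ("OR", "AND"):
            raise ValueError("combinator must be 'OR' or 'AND'")


def confusion_from_rates(
    n_pos: int, n_neg: int, sens: float, spec: float
) -> ConfusionMatrix:
    """Rebuild integer counts from class sizes and printed sens/spec (%).

    tp = half-up(sens/100 * n_pos), tn = half-up(spec/100 * n_neg); fn and
    fp by complement.  Rounding half-up is the convention that makes the
    published percentage columns internally consistent.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be positive")
    if not (0.0 <= sens <= 100.0 and 0.0 <= spec <= 100.0):
        raise ValueError("sens and spec must be percentages in [0, 100]")
    tp = int(round_half_up(sens / 100.0 * n_pos))
    tn = int(round_half_up(spec / 100.0 * n_neg))
    if tp > n_pos:
        warnings.warn("rounded tp exceeded n_pos; clamped", stacklevel=2)
        tp = n_pos
    if tn > n_neg:
        warnings.warn("rounded tn exceeded n_neg; clamped", stacklevel=2)
        tn = n_neg
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)


def metrics(cm: ConfusionMatrix, ndigits: int = 1) -> dict[str, float]:
    """Sens, spec, PPV, NPV and accuracy in percent, rounded half-up.

    Ratios with a zero denominator are reported as NaN (e.g. PPV when the
    rule never calls anyone positive).
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")

    def pct(num: int, den: int) -> float:
        return round_half_up(100.0 * num / den, ndigits) if den else math.nan

    return {
        "sens": pct(cm.tp, cm.tp + cm.fn),
        "spec": pct(cm.tn, cm.tn + cm.fp),
        "ppv": pct(cm.tp, cm.tp + cm.fp),
        "npv": pct(cm.tn, cm.tn + cm.fn),
        "accuracy": pct(cm.tp + cm.tn, cm.n),
    }


def rule_predict(activity: float | None, vas: float | None, rule: RuleSpec | None = None):
    """Apply the combined rule to one patient.

    Returns True/False, or None when both inputs are missing.  With one
    input missing the decision falls to the observed criterion alone
    (callers may count such decisions via :func:`evaluate_rule`).
    """
    rule = rule or RuleSpec()
    a_missing = activity is None or (isinstance(activity, float) and math.isnan(activity))
    v_missing = vas is None or (isinstance(vas, float) and math.isnan(vas))
    if a_missing and v_missing:
        return None
    if a_missing:
        return bool(vas >= rule.vas_cutoff)
    if v_missing:
        return bool(activity >= rule.activity_cutoff)
    hits = (activity >= rule.activity_cutoff, vas >= rule.vas_cutoff)
    return bool(any(hits) if rule.combinator == "OR" else all(hits))


def evaluate_rule(
    activity, vas, labels, rule: RuleSpec | None = None
) -> tuple[ConfusionMatrix, dict[str, float]]:
    """Apply the rule to a cohort and aggregate to a confusion matrix.

    Patients with both inputs missing are excluded; the returned metrics
    dict carries ``n_excluded`` and ``n_single_criterion`` (patients
    decided on one observed criterion) alongside the percentages.
    """
    rule = rule or RuleSpec()
    a = np.asarray(activity, dtype=float)
    v = np.asarray(vas, dtype=float)
    y = np.asarray(labels).astype(int)
    if not (len(a) == len(v) == len(y)):
        raise ValueError("activity, vas and labels must be aligned")
    if len(y) == 0:
        raise ValueError("empty cohort")
    tp = fn = fp = tn = 0
    n_excluded = 0
    n_single = 0
    for ai, vi, yi in zip(a, v, y):
        pred = rule_predict(ai, vi, rule)
        if pred is None:
            n_excluded += 1
            continue
        if math.isnan(ai) or math.isnan(vi):
            n_single += 1
        if pred and yi:
            tp += 1
        elif pred and not yi:
            fp += 1
        elif not pred and yi:
            fn += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
    m = metrics(cm)
    m["n_excluded"] = n_excluded
    m["n_single_criterion"] = n_single
    return cm, m
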