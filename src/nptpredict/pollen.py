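"""Pollen-day classification and season windowing.

Daily airborne grass-pollen concentrations (grains/m^3) drive both the
exposure window of the analysis and the selection of "high" days over
which e-diary scores are summarized.  Days are classed with the central
Italian aerobiological cut-offs: low (<10), medium (10-30), high (>30).
Season windows come either from a configurable run rule (R consecutive
days at or above a threshold) or from an explicit fixed override, since
published studies typically apply precomputed station-specific dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAY_CLASSES = ("low", "medium", "high")

#: fixed 2016 windows for the Rome station (whole and peak grass season)
ROME_2016_WHOLE = ("2016-04-13", "2016-07-28")
ROME_2016_PEAK = ("2016-05-04", "2016-06-28")


@dataclass(frozen=True)
class SeasonWindows:
    """Whole/peak season date ranges plus a per-day concentration class.

    Either window may be ``None`` when no qualifying run exists.
    ``day_class`` is indexed by the series dates and takes values in
    ``DAY_CLASSES``.
    """

    whole_season: tuple[pd.Timestamp, pd.Timestamp] | None
    peak_season: tuple[pd.Timestamp, pd.Timestamp] | None
    day_class: pd.Series

    def __post_init__(self) -> None:
        if self.whole_season is not None and self.peak_season is not None:
            ws, we = self.whole_season
            ps, pe = self.peak_season
            if ps < ws or pe > we:
                raise ValueError("peak season must lie within the whole season")


def _as_series(series: pd.Series) -> pd.Series:
    if not isinstance(series, pd.Series):
        raise TypeError("pollen series must be a pandas Series indexed by date")
    if len(series) == 0:
        raise ValueError("pollen series is empty")
    out = series.copy()
    out.index = pd.DatetimeIndex(out.index)
    if not out.index.is_monotonic_increasing or out.index.has_duplicates:
        raise ValueError("pollen dates must be strictly increasing")
    if (out.to_numpy(dtype=float) < 0).any():
        raise ValueError("pollen concentrations must be non-negative")
    return out


def classify_day(concentration, thresholds: tuple[float, float] = (10.0, 30.0)):
    """Class a daily concentration as ``low``/``medium``/``high``.

    Low is strictly below ``thresholds[0]``; medium is the closed interval
    between the two thresholds; high is strictly above ``thresholds[1]``.
    Accepts a scalar or an array; negative input is an error.
    """
    lo, hi = thresholds
    if not 0 <= lo <= hi:
        raise ValueError("thresholds must satisfy 0 <= low <= high")
    arr = np.asarray(concentration, dtype=float)
    if (arr < 0).any():
        raise ValueError("pollen concentration cannot be negative")
    out = np.where(arr < lo, "low", np.where(arr > hi, "high", "medium"))
    if np.isscalar(concentration) or arr.ndim == 0:
        return str(out)
    return out


def _runs_at_least(mask: np.ndarray, run_length: int) -> list[tuple[int, int]]:
    """Start/end index pairs (inclusive) of runs of True of length >= R."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= run_length:
                runs.append((start, i - 1))
            start = None
    return runs


def detect_season(
    series: pd.Series,
    run_length: int = 3,
    start_threshold: float = 10.0,
    peak_threshold: float = 30.0,
    whole_override: tuple | None = None,
    peak_override: tuple | None = None,
) -> SeasonWindows:
    """Derive whole-season and peak-season windows from a daily series.

    The default rule: the season starts on the first day of the first run
    of ``run_length`` consecutive days each at or above ``start_threshold``
    and ends on the last day of the last such run; the peak season applies
    the same rule at ``peak_threshold``.  Fixed overrides (start, end) are
    returned verbatim, which is how precomputed station calendars are used.
    """
    s = _as_series(series)
    day_class = pd.Series(classify_day(s.to_numpy(dtype=float)), index=s.index)

    def _window(threshold: float) -> tuple[pd.Timestamp, pd.Timestamp] | None:
        runs = _runs_at_least(s.to_numpy(dtype=float) >= threshold, run_length)
        if not runs:
            return None
        return (s.index[runs[0][0]], s.index[runs[-1][1]])

    def _coerce(win: tuple | None):
        if win is None:
            return None
        a, b = pd.Timestamp(win[0]), pd.Timestamp(win[1])
        if a > b:
            raise ValueError("window start is after window end")
        return (a, b)

    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    whole = _coerce(whole_override) if whole_override is not None else _window(start_threshold)
    peak = _coerce(peak_override) if peak_override is not None else _window(peak_threshold)
    return SeasonWindows(whole_season=whole, peak_season=peak, day_class=day_class)


def high_day_mask(
    series: pd.Series, window: tuple | None, threshold: float = 30.0
) -> pd.Series:
    """Boolean mask over the window dates: True where concentration > threshold.

    The comparison is strict, matching the ">30/m^3" definition of a high
    pollen day.  ``window`` is an inclusive (start, end) pair that must lie
    within the series dates; an empty window yields an empty mask.
    """
    s = _as_series(series)
    if window is None:
        return pd.Series(dtype=bool)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        return pd.Series(dtype=bool)
    if start < s.index[0] or end > s.index[-1]:
        raise ValueError("window lies outside the pollen series")
    sub = s.loc[start:end]
    return sub > threshold
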