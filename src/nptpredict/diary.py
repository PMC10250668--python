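"""E-diary summaries over high-pollen days.

Each patient's daily RTSS (0-18), CSMS (0-6) and VAS (0-10) records are
reduced, over the days with high airborne grass-pollen concentration, to
two statistics: the maximum and the coefficient of variation
CV = 100 * SD / mean (sample SD, n-1 denominator).  Missing diary days
are dropped, not imputed: a day the patient did not fill in is not a
symptom-free day.  A CV needs at least two observed high days; with
fewer the summary is missing.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

SCORES = ("rtss", "csms", "vas")
SCORE_RANGES = {"rtss": (0, 18), "csms": (0.0, 6.0), "vas": (0, 10)}


def cv_percent(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent: 100 * SD / mean.

    Uses the sample SD by default.  All-zero input returns 0.0 (the 0/0
    convention: no symptoms, no variability).  Fewer than two non-missing
    values yield NaN rather than an error, since that is a data-sparsity
    condition, not a caller bug.  Negative scores are invalid.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if (arr < 0).any():
        raise ValueError("diary scores cannot be negative")
    if arr.size < 2:
        return math.nan
    if np.all(arr == 0):
        return 0.0
    return 100.0 * arr.std(ddof=ddof) / arr.mean()


def max_score(values) -> float:
    """Maximum of the non-missing values; NaN when nothing was observed."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return math.nan
    return float(arr.max())


def summarize_diaries(
    diary: pd.DataFrame, high_mask: pd.Series, min_days_for_cv: int = 2
) -> pd.DataFrame:
    """Per-patient max and CV of each score over masked (high-pollen) days.

    ``diary`` is long-format with columns patient_id, date and the score
    columns; ``high_mask`` is a boolean Series indexed by date (as produced
    by :func:`nptpredict.pollen.high_day_mask`).  Returns one row per
    patient with ``<score>_max``, ``<score>_cv`` and ``<score>_n`` columns;
    patients with no diary entry on a high day get NaN summaries and n=0.
    """
    required = {"patient_id", "date", *SCORES}
    missing = required - set(diary.columns)
    if missing:
        raise ValueError(f"diary table is missing columns: {sorted(missing)}")
    if len(high_mask) == 0:
        high_dates = pd.DatetimeIndex([])
    else:
        high_dates = pd.DatetimeIndex(high_mask.index[high_mask.astype(bool)])

    dates = pd.DatetimeIndex(pd.to_datetime(diary["date"]))
    on_high = diary.loc[dates.isin(high_dates)]

    rows = []
    for pid in pd.unique(diary["patient_id"]):
        sub = on_high[on_high["patient_id"] == pid]
        row: dict[str, object] = {"patient_id": pid}
        for score in SCORES:
            vals = sub[score].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            row[f"{score}_n"] = int(vals.size)
            row[f"{score}_max"] = max_score(vals) if vals.size else math.nan
            row[f"{score}_cv"] = (
                cv_percent(vals) if vals.size >= min_days_for_cv else math.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("patient_id")
    return out
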