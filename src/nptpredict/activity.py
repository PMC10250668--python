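"""IgE sensitization flags and IgE-specific activity indices.

The specific activity of an IgE response is its share of the total IgE
pool, (specific IgE / total IgE) * 100, in percent.  For combinations of
analytes (e.g. Phl p 5 + Cyn d 1) the specific IgE concentrations are
summed before dividing, so the combined activity equals the sum of the
component activities.  In poly-sensitized patients this normalization is
a better proxy of the biologically dominant sensitization than the raw
kU/L level.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: assay positivity threshold for specific IgE, kU/L (strictly greater than)
SIGE_POSITIVITY_THRESHOLD = 0.35
#: semi-quantitative assay floor, kU/L; undetectable responses are coded here
ASSAY_FLOOR = 0.1

#: analyte combinations analysed by default: grass extracts, the major
#: species-specific molecules, and their combined indices
DEFAULT_ANALYTE_SETS: dict[str, tuple[str, ...]] = {
    "timothy": ("timothy",),
    "bermuda": ("bermuda",),
    "timothy+bermuda": ("timothy", "bermuda"),
    "phl_p_1": ("phl_p_1",),
    "phl_p_5": ("phl_p_5",),
    "cyn_d_1": ("cyn_d_1",),
    "phl_p_5+cyn_d_1": ("phl_p_5", "cyn_d_1"),
}


def is_sensitized(sige: float, threshold: float = SIGE_POSITIVITY_THRESHOLD) -> bool:
    """True when the specific IgE level is strictly above the assay threshold."""
    if sige < 0:
        raise ValueError("specific IgE cannot be negative")
    return bool(sige > threshold)


def specific_activity(sige: float, total_ige: float) -> float:
    """Specific activity in percent: 100 * sige / total_ige.

    ``total_ige`` must be positive and ``sige`` must not exceed it (a
    specific IgE above total IgE is a data inconsistency, not a value to
    silently clip).
    """
    if total_ige <= 0:
        raise ValueError("total IgE must be positive")
    if sige < 0:
        raise ValueError("specific IgE cannot be negative")
    if sige > total_ige:
        raise ValueError(
            f"specific IgE ({sige}) exceeds total IgE ({total_ige}): inconsistent record"
        )
    return 100.0 * sige / total_ige


def combined_activity(sige_values: Sequence[float], total_ige: float) -> float:
    """Combined specific activity of several analytes: 100 * sum(sige) / total."""
    return specific_activity(float(np.sum(np.asarray(sige_values, dtype=float))), total_ige)


def _cohort_frame(cohort) -> pd.DataFrame:
    """Accept a cohort as a DataFrame or a sequence of PatientRecord."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    from .io import cohort_to_frame  # local import to avoid a cycle

    return cohort_to_frame(cohort)


def build_activity_table(
    cohort,
    analyte_sets: Mapping[str, Iterable[str]] | None = None,
    below_lod: str = "floor",
    floor: float = ASSAY_FLOOR,
) -> pd.DataFrame:
    """Per-patient activity table, one column per analyte or combination.

    ``below_lod`` controls how undetectable responses (coded at the assay
    floor) enter the formula: ``"floor"`` keeps them at the floor value,
    ``"zero"`` substitutes 0 before computing activities.
    """
    if analyte_sets is None:
        analyte_sets = DEFAULT_ANALYTE_SETS
    if below_lod not in ("floor", "zero"):
        raise ValueError("below_lod must be 'floor' or 'zero'")
    df = _cohort_frame(cohort)
    if len(df) == 0:
        return pd.DataFrame(columns=list(analyte_sets), index=pd.Index([], name="patient_id"))

    needed = sorted({a for comps in analyte_sets.values() for a in comps})
    for analyte in needed:
        if f"sige_{analyte}" not in df.columns:
            raise KeyError(f"cohort is missing specific IgE for analyte '{analyte}'")

    sige = df[[f"sige_{a}" for a in needed]].to_numpy(dtype=float)
    if below_lod == "zero":
        sige = np.where(sige <= floor, 0.0, sige)
    total = df["total_ige"].to_numpy(dtype=float)
    col_of = {a: i for i, a in enumerate(needed)}

    out = {}
    for name, comps in analyte_sets.items():
        summed = sige[:, [col_of[a] for a in comps]].sum(axis=1)
        if (total <= 0).any():
            raise ValueError("total IgE must be positive for every patient")
        if (summed > total).any():
            bad = df.index[summed > total][0]
            raise ValueError(f"summed specific IgE exceeds total IgE for patient {bad!r}")
        out[name] = 100.0 * summed / total
    table = pd.DataFrame(out, index=df["patient_id"] if "patient_id" in df else df.index)
    table.index.name = "patient_id"
    return table
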