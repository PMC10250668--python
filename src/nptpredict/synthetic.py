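"""Synthetic cohorts, pollen series and e-diaries.

The study population this generator emulates — poly-sensitized pediatric
patients with seasonal allergic rhinitis undergoing a grass-pollen nasal
provocation test (NPT) — is not publicly deposited, so every downstream
stage of the pipeline is exercised on simulated data with the same
statistical structure: ~85% NPT-positive prevalence; lognormal total IgE
(median ~421 kU/L, IQR ~199-737); specific IgE per analyte drawn, for
sensitized patients, from group-specific lognormals clipped to the
semi-quantitative assay range [0.1, 100] kU/L, with non-sensitized
patients coded exactly at the 0.1 floor; sensitization rates that differ
by NPT outcome (64% vs 18% for Phl p 5); retrospective VAS medians 7
(NPT-positive) vs 5 (negative); and daily diaries that rise with
log(1 + pollen) plus a per-patient severity latent that is larger in the
NPT-positive group.

One integer seed governs the whole simulation; each stage (cohort,
pollen, diary) draws from a named substream so stages can be regenerated
independently without disturbing one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGE_KEYS = {"cohort": 1, "pollen": 2, "diary": 3}


class ConfigError(ValueError):
    """Invalid generator configuration."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: one master seed, independent streams per stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


@dataclass(frozen=True)
class AnalyteModel:
    """Per-analyte sensitization rates and level medians by NPT group.

    ``rate_neg``/``rate_pos``: probability a patient in the NPT-negative /
    NPT-positive group is sensitized.  ``median_neg``/``median_pos``: the
    lognormal median (kU/L) of the specific IgE level among sensitized
    patients of each group.  ``sigma`` is the lognormal shape (log-scale
    SD); serum IgE levels span decades, hence the wide default.
    """

    rate_neg: float
    rate_pos: float
    median_neg: float
    median_pos: float
    sigma: float = 1.5


def _default_analytes() -> dict[str, AnalyteModel]:
    # rates/medians chosen to mirror the observed group contrasts:
    # nearly universal timothy/Phl p 1 sensitization, strong group
    # separation for Phl p 5 and Cyn d 1, rare Phl p 7 / Phl p 12.
    return {
        "timothy": AnalyteModel(0.90, 0.98, 65.0, 95.0),
        "bermuda": AnalyteModel(0.60, 0.85, 1.7, 29.0),
        "phl_p_1": AnalyteModel(0.90, 0.97, 72.0, 91.0),
        "phl_p_4": AnalyteModel(0.80, 0.90, 56.0, 57.0),
        "phl_p_5": AnalyteModel(0.182, 0.64, 5.0, 40.0),
        "phl_p_7": AnalyteModel(0.05, 0.08, 1.0, 1.0),
        "phl_p_12": AnalyteModel(0.05, 0.08, 1.0, 1.0),
        "cyn_d_1": AnalyteModel(0.55, 0.80, 8.0, 45.0),
    }


def _default_spt() -> dict[str, tuple[float, float, float]]:
    # allergen -> (median wheal mm NPT-negative, NPT-positive, SD)
    return {"timothy": (6.0, 8.0, 2.0), "bermuda": (4.5, 6.0, 1.8)}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters (defaults are the study conditions)."""

    n_patients: int = 72
    prevalence_positive: float = 0.847
    total_ige_log_median: float = 421.0  # kU/L
    total_ige_log_sigma: float = 0.97  # matches the reported IQR on log scale
    analytes: dict[str, AnalyteModel] = field(default_factory=_default_analytes)
    spt: dict[str, tuple[float, float, float]] = field(default_factory=_default_spt)
    assay_floor: float = 0.1  # kU/L
    assay_cap: float = 100.0  # kU/L
    vas_severity_median: tuple[float, float] = (5.0, 7.0)  # (neg, pos)
    vas_drug_median: tuple[float, float] = (7.0, 8.0)
    vas_sd: float = 2.0
    age_mean: float = 14.3
    age_sd: float = 2.8
    male_fraction: float = 46 / 72
    diary_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        probs = [self.prevalence_positive, self.male_fraction] + [
            r for m in self.analytes.values() for r in (m.rate_neg, m.rate_pos)
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not self.assay_floor < self.assay_cap:
            raise ConfigError("assay_floor must be below assay_cap")
        medians = [self.total_ige_log_median] + [
            v for m in self.analytes.values() for v in (m.median_neg, m.median_pos)
        ]
        if any(v <= 0 for v in medians):
            raise ConfigError("level medians must be positive")
        if any(not 0.0 <= v <= 10.0 for v in self.vas_severity_median + self.vas_drug_median):
            raise ConfigError("VAS medians must lie in [0, 10]")
        if self.diary_noise_sd < 0 or self.vas_sd < 0:
            raise ConfigError("noise SDs must be non-negative")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str
    npt_positive: int
    spt_wheal: dict[str, float]
    total_ige: float
    specific_ige: dict[str, float]
    vas_severity_retro: int
    vas_drug_efficacy: int


def _trunc_round_vas(rng: np.random.Generator, median: float, sd: float, size: int) -> np.ndarray:
    return np.clip(np.round(rng.normal(median, sd, size)), 0, 10).astype(int)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a cohort of :class:`PatientRecord` (deterministic given seed).

    NPT outcome is Bernoulli(prevalence).  Per analyte, sensitization is
    Bernoulli with the group rate; sensitized patients get a lognormal
    level (group median, shape sigma) clipped to [floor, cap] and to the
    patient's total IgE, non-sensitized patients sit exactly at the floor.
    VAS scores are rounded truncated normals around the group medians.
    """
    rng = stage_rng(config.seed, "cohort")
    n = config.n_patients
    if n == 0:
        return []
    npt = (rng.random(n) < config.prevalence_positive).astype(int)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 4.0, 18.0).round(1)
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    total = np.exp(rng.normal(math.log(config.total_ige_log_median), config.total_ige_log_sigma, n))
    total = np.maximum(total, 2.0).round(1)  # physiological lower bound, kU/L

    sige: dict[str, np.ndarray] = {}
    for name, model in config.analytes.items():
        rate = np.where(npt == 1, model.rate_pos, model.rate_neg)
        sens = rng.random(n) < rate
        med = np.where(npt == 1, model.median_pos, model.median_neg)
        levels = np.exp(rng.normal(np.log(med), model.sigma))
        levels = np.clip(levels, config.assay_floor, config.assay_cap)
        levels = np.where(sens, levels, config.assay_floor)
        sige[name] = np.minimum(levels, total)

    # allergen-specific IgE is drawn from the total pool: keep the sum over
    # all analytes below total so every combined activity stays <= 100%
    names = list(sige)
    mat = np.vstack([sige[k] for k in names])
    rowsum = mat.sum(axis=0)
    over = rowsum > 0.9 * total
    if over.any():
        mat[:, over] *= (0.9 * total[over]) / rowsum[over]
        mat = np.maximum(mat, config.assay_floor)
    for i, k in enumerate(names):
        sige[k] = mat[i].round(2)

    spt: dict[str, np.ndarray] = {}
    for allergen, (m_neg, m_pos, sd) in config.spt.items():
        med = np.where(npt == 1, m_pos, m_neg)
        # wheal diameters read to the half millimetre
        spt[allergen] = np.maximum(np.round(rng.normal(med, sd) * 2) / 2, 0.0)

    vas_sev = np.where(
        npt == 1,
        _trunc_round_vas(rng, config.vas_severity_median[1], config.vas_sd, n),
        _trunc_round_vas(rng, config.vas_severity_median[0], config.vas_sd, n),
    )
    vas_drug = np.where(
        npt == 1,
        _trunc_round_vas(rng, config.vas_drug_median[1], config.vas_sd, n),
        _trunc_round_vas(rng, config.vas_drug_median[0], config.vas_sd, n),
    )

    width = max(4, len(str(n)))
    return [
        PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            age=float(age[i]),
            sex=str(sex[i]),
            npt_positive=int(npt[i]),
            spt_wheal={k: float(v[i]) for k, v in spt.items()},
            total_ige=float(total[i]),
            specific_ige={k: float(v[i]) for k, v in sige.items()},
            vas_severity_retro=int(vas_sev[i]),
            vas_drug_efficacy=int(vas_drug[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class PollenShape:
    """Unimodal seasonal hump: Gaussian in time with multiplicative noise."""

    peak_day: float = 65.0  # days after start_date
    width_days: float = 22.0
    peak_height: float = 120.0  # grains/m^3 before noise
    noise_sigma: float = 0.35  # lognormal shape of day-to-day noise
    cap: float = 199.0  # grains/m^3, maximum recorded concentration

    def __post_init__(self) -> None:
        if self.width_days <= 0 or self.peak_height < 0 or self.cap <= 0:
            raise ConfigError("invalid pollen shape parameters")


def generate_pollen_series(
    start_date="2016-04-01",
    n_days: int = 150,
    shape: PollenShape | None = None,
    seed: int = 0,
) -> pd.Series:
    """Daily grass-pollen concentrations with a unimodal seasonal hump.

    Counts are integers in [0, cap]; a zero peak height gives an all-zero
    series; identical seeds give identical series.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    shape = shape or PollenShape()
    rng = stage_rng(seed, "pollen")
    t = np.arange(n_days, dtype=float)
    base = shape.peak_height * np.exp(-0.5 * ((t - shape.peak_day) / shape.width_days) ** 2)
    noisy = base * np.exp(rng.normal(0.0, shape.noise_sigma, n_days))
    values = np.clip(np.round(noisy), 0.0, shape.cap)
    index = pd.date_range(pd.Timestamp(start_date), periods=n_days, freq="D")
    return pd.Series(values, index=index, name="grains_m3")


@dataclass(frozen=True)
class DiaryConfig:
    """Daily-score model: baseline + slope * log1p(pollen) + latent + noise.

    ``latent_gap`` is the mean shift of the per-patient severity latent in
    the NPT-positive group; ``scale`` maps the shared latent onto each
    score's range.  Scores are rounded and clipped to their instruments'
    ranges (RTSS 0-18, CSMS 0-6, VAS 0-10).
    """

    baseline: dict[str, float] = field(
        default_factory=lambda: {"rtss": 0.5, "csms": 0.2, "vas": 0.5}
    )
    exposure_coef: dict[str, float] = field(
        default_factory=lambda: {"rtss": 1.6, "csms": 0.5, "vas": 0.9}
    )
    scale: dict[str, float] = field(
        default_factory=lambda: {"rtss": 2.0, "csms": 0.5, "vas": 1.0}
    )
    latent_gap: float = 1.2
    latent_sd: float = 0.8
    noise_sd: float = 1.0


_RANGES = {"rtss": (0, 18), "csms": (0.0, 6.0), "vas": (0, 10)}


def generate_diary(
    cohort: list[PatientRecord],
    pollen: pd.Series,
    config: DiaryConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format daily diary rows for every patient over the pollen dates.

    Scores increase stochastically with log(1 + pollen) and with a
    per-patient severity latent that is larger for NPT-positive patients;
    everything is clipped to the instrument ranges.  Medication intake is
    Bernoulli with probability rising in the day's VAS.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not isinstance(pollen, pd.Series) or len(pollen) == 0:
        raise ValueError("pollen series must be a non-empty Series")
    config = config or DiaryConfig()
    rng = stage_rng(seed, "diary")
    log_exposure = np.log1p(pollen.to_numpy(dtype=float))
    dates = pd.DatetimeIndex(pollen.index)
    n_days = len(dates)

    frames = []
    for patient in cohort:
        latent = rng.normal(config.latent_gap * patient.npt_positive, config.latent_sd)
        row: dict[str, object] = {
            "patient_id": np.repeat(patient.patient_id, n_days),
            "date": dates,
        }
        for score, (lo, hi) in _RANGES.items():
            raw = (
                config.baseline[score]
                + config.exposure_coef[score] * log_exposure
                + config.scale[score] * latent
                + rng.normal(0.0, config.noise_sd, n_days)
            )
            if score == "csms":
                vals = np.clip(np.round(raw * 2) / 2, lo, hi)  # half-point scale
            else:
                vals = np.clip(np.round(raw), lo, hi).astype(int)
            row[score] = vals
        p_med = 1.0 / (1.0 + np.exp(-(np.asarray(row["vas"], dtype=float) - 4.0)))
        row["medication_taken"] = (rng.random(n_days) < p_med).astype(int)
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)
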