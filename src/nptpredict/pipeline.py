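"""End-to-end orchestration of the NPT-outcome prediction analysis.

Load (or simulate) a cohort, its e-diaries and the daily pollen series;
window the season and select high-pollen days; compute IgE-specific
activity indices and diary summaries; compare NPT-positive and
NPT-negative groups; run the ROC/cutoff analysis for every candidate
predictor; fit the two-predictor logistic model; and evaluate the
combined "activity OR VAS" decision rule.  Everything is written out as
CSV/JSON plus a Markdown report with a provenance block (config hash,
seed, version), so each report can be regenerated from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .activity import DEFAULT_ANALYTE_SETS, build_activity_table
from .diary import summarize_diaries
from .logit import LogisticFit, accuracy_at_half, add_intercept, box_tidwell, fit_logistic
from .pollen import detect_season, high_day_mask
from .roc import roc_table
from .rules import RuleSpec, evaluate_rule
from .stats import chi2_yates_2x2, fisher_exact_2x2, mann_whitney, min_expected_cell
from .synthetic import CohortConfig, generate_cohort, generate_diary, generate_pollen_series

__version__ = "0.1.0"

#: predictors entering the logistic model (the "enter method" pair)
LOGISTIC_PREDICTORS = ("vas_severity_retro", "phl_p_5+cyn_d_1")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # or "load"
    n_patients: int = 72
    seed: int = 0
    cohort_path: str | None = None
    diary_path: str | None = None
    pollen_path: str | None = None
    high_threshold: float = 30.0  # grains/m^3, strict
    season_run_length: int = 3
    season_start_threshold: float = 10.0
    season_peak_threshold: float = 30.0
    whole_season: tuple | None = None  # fixed override (start, end)
    peak_season: tuple | None = None
    rule: RuleSpec = field(default_factory=RuleSpec)
    out_dir: str = "npt_report"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.high_threshold <= 0:
            raise ValueError("high_threshold must be positive")
        if self.mode == "load":
            for name in ("cohort_path", "diary_path", "pollen_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point to an existing file in load mode")

    def to_json(self) -> str:
        d = asdict(self)
        d["rule"] = asdict(self.rule)
        return json.dumps(d, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "rule" in d and isinstance(d["rule"], dict):
            d["rule"] = RuleSpec(**d["rule"])
        if d.get("whole_season"):
            d["whole_season"] = tuple(d["whole_season"])
        if d.get("peak_season"):
            d["peak_season"] = tuple(d["peak_season"])
        return cls(**d)


@dataclass
class ReportBundle:
    group_comparison: pd.DataFrame
    activity_table: pd.DataFrame
    diary_summary: pd.DataFrame
    roc_table: pd.DataFrame
    logistic: LogisticFit | None
    logistic_table: pd.DataFrame | None
    box_tidwell_p: pd.Series | None
    rule_cm: object
    rule_metrics: dict
    season: dict
    provenance: dict


def load_cohort(cohort_path, diary_path, pollen_path):
    """Load and validate the three input tables."""
    cohort = _io.read_cohort_csv(cohort_path)
    diary = _io.read_diary_csv(diary_path)
    pollen = _io.read_pollen_csv(pollen_path)
    unknown = set(diary["patient_id"]) - set(cohort["patient_id"])
    if unknown:
        raise _io.SchemaError(f"diary rows for patients absent from cohort: {sorted(unknown)[:5]}")
    return cohort, diary, pollen


def _quantiles(values: np.ndarray) -> tuple[float, float, float]:
    med, q1, q3 = np.percentile(values, [50, 25, 75])  # linear interpolation
    return float(med), float(q1), float(q3)


def group_compare(
    cohort: pd.DataFrame, variables: list[str], label_col: str = "npt_positive"
) -> pd.DataFrame:
    """Median (IQR) per NPT group with the appropriate two-group test.

    Continuous variables get Mann-Whitney; binary 0/1 variables get a 2x2
    test — Fisher exact when any expected cell is below 5 (Cochran's
    rule), Yates-corrected chi-square otherwise.  Constant variables are
    reported without a test.
    """
    y = cohort[label_col].to_numpy(dtype=int)
    rows = []
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"unknown variable '{var}'")
        col = cohort[var].to_numpy(dtype=float)
        keep = ~np.isnan(col)
        v, g = col[keep], y[keep]
        neg, pos = v[g == 0], v[g == 1]
        row: dict[str, object] = {"variable": var, "n_neg": len(neg), "n_pos": len(pos)}
        if np.unique(v).size <= 1:
            row.update(p_value=math.nan, test="skipped (constant)")
        elif set(np.unique(v)) <= {0.0, 1.0}:
            a, b = int(pos.sum()), int(len(pos) - pos.sum())
            c, d = int(neg.sum()), int(len(neg) - neg.sum())
            if min_expected_cell(a, b, c, d) < 5:
                res = fisher_exact_2x2(a, b, c, d)
            else:
                res = chi2_yates_2x2(a, b, c, d)
            row.update(
                pos_summary=f"{a}/{a + b}",
                neg_summary=f"{c}/{c + d}",
                p_value=res.p_value,
                test=res.method,
            )
        else:
            m_n, q1_n, q3_n = _quantiles(neg) if len(neg) else (math.nan,) * 3
            m_p, q1_p, q3_p = _quantiles(pos) if len(pos) else (math.nan,) * 3
            res = mann_whitney(neg, pos) if len(neg) and len(pos) else None
            row.update(
                neg_summary=f"{m_n:.2f} ({q1_n:.2f}-{q3_n:.2f})",
                pos_summary=f"{m_p:.2f} ({q1_p:.2f}-{q3_p:.2f})",
                p_value=res.p_value if res else math.nan,
                test=res.method if res else "skipped (empty group)",
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _obtain_data(config: PipelineConfig):
    if config.mode == "load":
        return load_cohort(config.cohort_path, config.diary_path, config.pollen_path)
    cc = CohortConfig(n_patients=config.n_patients, seed=config.seed)
    cohort = generate_cohort(cc)
    pollen = generate_pollen_series(seed=config.seed)
    diary = generate_diary(cohort, pollen, seed=config.seed)
    return _io.cohort_to_frame(cohort), diary, pollen


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute every stage and (optionally) write the report artifacts."""
    cohort, diary, pollen = _stage("load", _obtain_data, config)

    def _season():
        return detect_season(
            pollen,
            run_length=config.season_run_length,
            start_threshold=config.season_start_threshold,
            peak_threshold=config.season_peak_threshold,
            whole_override=config.whole_season,
            peak_override=config.peak_season,
        )

    windows = _stage("season", _season)
    window = windows.peak_season or windows.whole_season
    mask = high_day_mask(pollen, window, threshold=config.high_threshold)

    activity = _stage("activity", build_activity_table, cohort)
    summaries = _stage("diary", summarize_diaries, diary, mask)

    merged = cohort.set_index("patient_id").join(activity).join(summaries)
    labels = merged["npt_positive"].to_numpy(dtype=int)

    compare_vars = (
        [c for c in cohort.columns if c.startswith("spt_")]
        + ["total_ige"]
        + [c for c in cohort.columns if c.startswith("sige_")]
        + ["vas_severity_retro", "vas_drug_efficacy"]
        + list(DEFAULT_ANALYTE_SETS)
        + ["rtss_max", "rtss_cv", "csms_max", "csms_cv", "vas_max", "vas_cv"]
    )
    comparison = _stage("compare", group_compare, merged.reset_index(), compare_vars)

    roc_predictors = merged[
        [c for c in cohort.columns if c.startswith("spt_")]
        + [c for c in cohort.columns if c.startswith("sige_")]
        + list(DEFAULT_ANALYTE_SETS)
        + ["vas_severity_retro", "vas_max", "vas_cv"]
    ]
    roc = _stage("roc", roc_table, roc_predictors, labels)

    def _logistic():
        x = add_intercept(merged[list(LOGISTIC_PREDICTORS)])
        fit = fit_logistic(x, labels)
        table = pd.DataFrame(
            {
                "B": fit.params,
                "SE": fit.se,
                "Wald": fit.wald,
                "df": 1,
                "p": fit.p,
                "exp_B": fit.exp_b,
                "ci95_lower": fit.ci95["lower"],
                "ci95_upper": fit.ci95["upper"],
            }
        )
        bt = box_tidwell(x, labels, [c for c in LOGISTIC_PREDICTORS], zero_shift=0.01)
        acc = accuracy_at_half(fit, x, labels)
        return fit, table, bt, acc

    # separation is a data property (few negatives can be perfectly split),
    # not a pipeline defect: report the stage as not estimable and carry on
    try:
        fit, logistic_table, bt_p, acc = _stage("logistic", _logistic)
    except RuntimeError as exc:
        if "converge" not in str(exc) and "separat" not in str(exc):
            raise
        fit, logistic_table, bt_p, acc = None, None, None, math.nan

    def _rule():
        return evaluate_rule(
            merged["phl_p_5+cyn_d_1"], merged["vas_severity_retro"], labels, config.rule
        )

    rule_cm, rule_m = _stage("rule", _rule)

    season_info = {
        "whole_season": [str(d.date()) for d in windows.whole_season] if windows.whole_season else None,
        "peak_season": [str(d.date()) for d in windows.peak_season] if windows.peak_season else None,
        "n_high_days": int(mask.sum()) if len(mask) else 0,
        "high_threshold": config.high_threshold,
    }
    # hash the analysis-relevant config only: the output location does not
    # change what was computed
    cfg_dict = json.loads(config.to_json())
    cfg_dict.pop("out_dir", None)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_patients": int(len(cohort)),
        "n_diary_rows": int(len(diary)),
        "n_pollen_days": int(len(pollen)),
    }
    bundle = ReportBundle(
        group_comparison=comparison,
        activity_table=activity,
        diary_summary=summaries,
        roc_table=roc,
        logistic=fit,
        logistic_table=logistic_table,
        box_tidwell_p=bt_p,
        rule_cm=rule_cm,
        rule_metrics={**rule_m, "accuracy_at_half": acc},
        season=season_info,
        provenance=provenance,
    )
    if write:
        _write_bundle(bundle, config, cohort, diary, pollen)
    return bundle


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def _write_bundle(bundle, config, cohort, diary, pollen) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_cohort_csv(cohort, out / "cohort.csv")
    _io.write_diary_csv(diary, out / "diary.csv")
    _io.write_pollen_csv(pollen, out / "pollen.csv")
    bundle.group_comparison.to_csv(out / "group_comparison.csv")
    bundle.activity_table.round(6).to_csv(out / "activity_table.csv")
    bundle.diary_summary.round(6).to_csv(out / "diary_summary.csv")
    bundle.roc_table.drop(columns=["degenerate"]).round(6).to_csv(out / "roc_table.csv")
    if bundle.logistic_table is not None:
        bundle.logistic_table.round(6).to_csv(out / "logistic_table.csv")
    report = {
        "season": bundle.season,
        "rule": asdict(config.rule),
        "rule_confusion": {
            "tp": bundle.rule_cm.tp,
            "fn": bundle.rule_cm.fn,
            "fp": bundle.rule_cm.fp,
            "tn": bundle.rule_cm.tn,
        },
        "rule_metrics": bundle.rule_metrics,
        "logistic": {
            "model_chi2": bundle.logistic.model_chi2,
            "model_df": bundle.logistic.model_df,
            "model_p": bundle.logistic.model_p,
            "nagelkerke_r2": bundle.logistic.nagelkerke_r2,
            "n_iter": bundle.logistic.n_iter,
        }
        if bundle.logistic
        else None,
        "box_tidwell_p": bundle.box_tidwell_p.to_dict() if bundle.box_tidwell_p is not None else None,
        "provenance": bundle.provenance,
    }
    _io.write_json(report, out / "report.json")
    (out / "report.md").write_text(_render_markdown(bundle, config))


def _render_markdown(bundle: ReportBundle, config: PipelineConfig) -> str:
    m = bundle.rule_metrics
    lines = [
        "# NPT-outcome prediction report",
        "",
        f"Seed {bundle.provenance['seed']}, config {bundle.provenance['config_sha256'][:12]}, "
        f"nptpredict {bundle.provenance['version']}",
        "",
        f"Patients: {bundle.provenance['n_patients']}; "
        f"high pollen days (> {config.high_threshold:g}/m3): {bundle.season['n_high_days']}",
        "",
        "## Group comparison (NPT-negative vs NPT-positive)",
        "",
        bundle.group_comparison.to_markdown(),
        "",
        "## ROC analysis",
        "",
        bundle.roc_table.drop(columns=["candidate_cutoffs"], errors="ignore").to_markdown(),
        "",
        "## Logistic model",
        "",
        bundle.logistic_table.to_markdown() if bundle.logistic_table is not None else "(not fitted)",
        "",
        f"Model chi2 = {bundle.logistic.model_chi2:.2f} (df {bundle.logistic.model_df}, "
        f"p = {bundle.logistic.model_p:.4g}); Nagelkerke R2 = {bundle.logistic.nagelkerke_r2:.2f}; "
        f"correctly classified {m['accuracy_at_half']:.1f}% at p >= 0.5"
        if bundle.logistic
        else "",
        "",
        "## Combined rule "
        f"(activity >= {config.rule.activity_cutoff:g}% {config.rule.combinator} "
        f"VAS >= {config.rule.vas_cutoff:g})",
        "",
        f"tp={bundle.rule_cm.tp} fn={bundle.rule_cm.fn} fp={bundle.rule_cm.fp} tn={bundle.rule_cm.tn}: "
        f"sens {m['sens']:.1f}%, spec {m['spec']:.1f}%, PPV {m['ppv']:.1f}%, NPV {m['npv']:.1f}%",
        "",
    ]
    return "\n".join(lines)
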