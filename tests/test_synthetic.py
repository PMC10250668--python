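"""Synthetic cohort / pollen / diary generators: ranges, calibration, determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from nptpredict.activity import build_activity_table
from nptpredict.io import cohort_to_frame, write_cohort_csv, write_diary_csv, write_pollen_csv
from nptpredict.roc import auc
from nptpredict.synthetic import (
    CohortConfig,
    ConfigError,
    DiaryConfig,
    PollenShape,
    _default_analytes,
    generate_cohort,
    generate_diary,
    generate_pollen_series,
)


class TestCohort:
    def test_degenerate_sizes(self):
        assert generate_cohort(CohortConfig(n_patients=0)) == []
        cohort = generate_cohort(CohortConfig(n_patients=50, prevalence_positive=1.0))
        assert all(p.npt_positive == 1 for p in cohort)

    def test_prevalence_calibration_at_large_n(self):
        """Positive fraction within 3 binomial SEs of 0.847 at n=10000."""
        cohort = generate_cohort(CohortConfig(n_patients=10_000, seed=11))
        frac = np.mean([p.npt_positive for p in cohort])
        se = np.sqrt(0.847 * 0.153 / 10_000)
        assert abs(frac - 0.847) < 3 * se

    def test_sensitization_rate_calibration(self, big_cohort_frame):
        """Per-group analyte positivity within 3 binomial SEs of the configured rates."""
        cfg = CohortConfig()
        for analyte in ("phl_p_5", "cyn_d_1", "timothy"):
            model = cfg.analytes[analyte]
            for group, rate in ((0, model.rate_neg), (1, model.rate_pos)):
                sub = big_cohort_frame[big_cohort_frame["npt_positive"] == group]
                observed = (sub[f"sige_{analyte}"] > cfg.assay_floor).mean()
                se = np.sqrt(max(rate * (1 - rate), 1e-6) / len(sub))
                assert abs(observed - rate) < 3 * se + 1e-9, (analyte, group)

    def test_row_invariants(self, default_cohort):
        cfg = CohortConfig()
        for p in default_cohort:
            assert p.total_ige > 0
            assert 0 <= p.vas_severity_retro <= 10 and 0 <= p.vas_drug_efficacy <= 10
            assert all(w >= 0 for w in p.spt_wheal.values())
            for level in p.specific_ige.values():
                assert cfg.assay_floor <= level <= cfg.assay_cap
                assert level <= p.total_ige
            assert sum(p.specific_ige.values()) <= p.total_ige + 1e-9

    def test_nonsensitized_sit_exactly_at_floor(self, big_cohort_frame):
        vals = big_cohort_frame["sige_phl_p_7"]
        assert (vals == 0.1).mean() > 0.8  # rarely sensitized analyte

    def test_reproducible_and_seed_sensitive(self):
        c1 = generate_cohort(CohortConfig(n_patients=30, seed=5))
        c2 = generate_cohort(CohortConfig(n_patients=30, seed=5))
        c3 = generate_cohort(CohortConfig(n_patients=30, seed=6))
        assert c1 == c2
        assert c1 != c3

    def test_byte_identical_csv_output(self, tmp_path):
        for i in (1, 2):
            cohort = generate_cohort(CohortConfig(n_patients=40, seed=3))
            pollen = generate_pollen_series(seed=3)
            diary = generate_diary(cohort, pollen, seed=3)
            write_cohort_csv(cohort, tmp_path / f"cohort{i}.csv")
            write_pollen_csv(pollen, tmp_path / f"pollen{i}.csv")
            write_diary_csv(diary, tmp_path / f"diary{i}.csv")
        for name in ("cohort", "pollen", "diary"):
            a = (tmp_path / f"{name}1.csv").read_bytes()
            b = (tmp_path / f"{name}2.csv").read_bytes()
            assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prevalence_positive": 1.5},
            {"n_patients": -1},
            {"assay_floor": 10.0, "assay_cap": 1.0},
            {"total_ige_log_median": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            CohortConfig(**kwargs)


class TestPollen:
    def test_zero_peak_gives_all_zero_series(self):
        s = generate_pollen_series(n_days=50, shape=PollenShape(peak_height=0.0), seed=0)
        assert (s == 0).all()

    def test_range_capped(self, pollen_series):
        assert pollen_series.min() >= 0
        assert pollen_series.max() <= 199

    def test_determinism(self):
        s1 = generate_pollen_series(seed=9)
        s2 = generate_pollen_series(seed=9)
        assert s1.equals(s2)

    def test_invalid_length(self):
        with pytest.raises(ConfigError):
            generate_pollen_series(n_days=0)

    def test_unimodal_hump_shape(self, pollen_series):
        """Mass concentrates around the configured peak day."""
        peak_window = pollen_series.iloc[45:86].sum()
        assert peak_window > 0.6 * pollen_series.sum()


class TestDiary:
    def test_zero_exposure_zero_noise_is_constant(self, default_cohort, pollen_series):
        cfg = DiaryConfig(
            exposure_coef={"rtss": 0.0, "csms": 0.0, "vas": 0.0},
            noise_sd=0.0,
        )
        diary = generate_diary(default_cohort[:5], pollen_series, cfg, seed=0)
        for _, sub in diary.groupby("patient_id"):
            for score in ("rtss", "csms", "vas"):
                assert sub[score].nunique() == 1

    def test_score_ranges(self, default_diary):
        assert default_diary["rtss"].between(0, 18).all()
        assert default_diary["csms"].between(0, 6).all()
        assert default_diary["vas"].between(0, 10).all()
        assert default_diary["medication_taken"].isin([0, 1]).all()

    def test_positive_group_has_worse_diary_vas(self, pollen_series):
        """NPT-positive mean diary VAS exceeds NPT-negative at ~5000 patient-days."""
        cohort = generate_cohort(CohortConfig(n_patients=40, prevalence_positive=0.5, seed=21))
        diary = generate_diary(cohort, pollen_series.iloc[:125], seed=21)
        status = {p.patient_id: p.npt_positive for p in cohort}
        diary["npt"] = diary["patient_id"].map(status)
        means = diary.groupby("npt")["vas"].mean()
        assert means[1] > means[0]

    def test_empty_cohort_rejected(self, pollen_series):
        with pytest.raises(ValueError):
            generate_diary([], pollen_series)

    def test_one_row_per_patient_day(self, default_diary, default_cohort, pollen_series):
        assert len(default_diary) == len(default_cohort) * len(pollen_series)
        assert not default_diary.duplicated(["patient_id", "date"]).any()


class TestDownstreamMonotonicity:
    def test_phl_p_5_separation_raises_combined_auc(self):
        """More Phl p 5 group separation cannot hurt the combined-activity AUC."""
        def auc_at(rate_pos: float, seed: int) -> float:
            analytes = _default_analytes()
            analytes["phl_p_5"] = replace(analytes["phl_p_5"], rate_pos=rate_pos)
            cfg = CohortConfig(n_patients=5000, seed=seed, analytes=analytes)
            df = cohort_to_frame(generate_cohort(cfg))
            table = build_activity_table(df)
            return auc(table["phl_p_5+cyn_d_1"].to_numpy(), df["npt_positive"].to_numpy())

        for seed in range(10):
            assert auc_at(0.9, seed) >= auc_at(0.3, seed)
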