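"""Cohort simulator: prevalence, calibration recovery, group comparisons."""

import numpy as np
import pytest
from scipy import stats

from ctcsfat.cohort import (
    CohortSpec,
    CovariateSpec,
    HazardSpec,
    cohort_to_frame,
    generate_cohort,
    generate_diameter_profiles,
    summarize_cohort,
)
from ctcsfat.remodeling import patient_label
from ctcsfat.survival import SurvivalInput, cox_fit


class TestGenerateCohort:
    def test_reproducible_under_seed(self):
        spec = CohortSpec(n_patients=100, seed=3)
        a = cohort_to_frame(generate_cohort(spec))
        b = cohort_to_frame(generate_cohort(spec))
        assert a.equals(b)

    def test_prevalence_within_three_binomial_ses(self):
        n = 20_000
        p = 0.324
        records = generate_cohort(CohortSpec(n_patients=n, pr_prevalence=p, seed=17))
        observed = np.mean([r.pr for r in records])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se

    def test_arm_means_recover_calibration(self):
        # default age calibration: 60.5 +/- 8.0 (PR+) vs 55.7 +/- 9.6 (PR-)
        records = generate_cohort(CohortSpec(n_patients=20_000, seed=23))
        age = np.array([r.clinical["age"] for r in records])
        pr = np.array([r.pr for r in records])
        assert age[pr].mean() == pytest.approx(60.5, abs=0.3)
        assert age[~pr].mean() == pytest.approx(55.7, abs=0.3)

    def test_agatston_features_internally_consistent(self):
        records = generate_cohort(CohortSpec(n_patients=200, seed=5))
        for r in records[:50]:
            vessels = [r.agatston[f"{a}_agatston"] for a in ("LM", "LAD", "LCX", "RCA")]
            assert r.agatston["total_agatston"] == pytest.approx(sum(vessels))
            assert r.agatston["log_total_agatston"] == pytest.approx(
                np.log10(r.agatston["total_agatston"] + 1.0)
            )
            assert r.agatston["high_cac"] == float(r.agatston["total_agatston"] > 1000)

    def test_null_hazard_recovers_unit_hr(self):
        cal_null = CohortSpec(
            n_patients=6000, seed=29,
            hazard=HazardSpec(baseline_rate_per_year=0.08, log_hr=0.0),
        )
        frame = cohort_to_frame(generate_cohort(cal_null))
        fit = cox_fit(
            SurvivalInput(
                time=frame["time_years"].to_numpy(),
                event=frame["event"].to_numpy().astype(bool),
                group=frame["pr"].to_numpy().astype(bool),
            )
        )
        assert fit.ci_low <= 1.0 <= fit.ci_high
        assert fit.hr == pytest.approx(1.0, abs=0.25)

    def test_missing_rate_introduces_nans_in_clinical_only(self):
        records = generate_cohort(CohortSpec(n_patients=500, seed=1, missing_rate=0.1))
        frame = cohort_to_frame(records)
        clin = frame.filter(like="clinical__")
        miss = clin.isna().to_numpy().mean()
        assert 0.05 < miss < 0.15
        assert not frame.filter(like="agatston__").isna().any().any()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_patients=0),
            dict(n_patients=10, pr_prevalence=1.0),
            dict(n_patients=10, missing_rate=1.0),
        ],
    )
    def test_degenerate_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortSpec(**bad)

    def test_degenerate_covariate_params_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            CovariateSpec(kind="continuous", pr_pos=(1.0, -1.0), pr_neg=(1.0, 1.0))
        with pytest.raises(ValueError, match="proportion"):
            CovariateSpec(kind="binary", pr_pos=1.2, pr_neg=0.5)


class TestSummarizeCohort:
    def test_null_pvalues_roughly_uniform(self):
        # identical distributions in both arms: ~5% of p-values below 0.05
        rng = np.random.default_rng(41)
        n_sims, alpha_hits = 100, 0
        null_cov = {
            "x": CovariateSpec(kind="continuous", pr_pos=(0.0, 1.0), pr_neg=(0.0, 1.0))
        }
        for s in range(n_sims):
            spec = CohortSpec(n_patients=200, seed=int(rng.integers(1 << 30)),
                              covariates=null_cov)
            p = summarize_cohort(generate_cohort(spec)).loc["x", "p_value"]
            alpha_hits += p < 0.05
        # binomial(100, 0.05): ~3 sd band around 5
        assert alpha_hits <= 12

    def test_constant_covariate_has_unit_pvalue(self):
        cov = {"c": CovariateSpec(kind="continuous", pr_pos=(5.0, 0.0), pr_neg=(5.0, 0.0))}
        records = generate_cohort(CohortSpec(n_patients=50, seed=2, covariates=cov))
        row = summarize_cohort(records).loc["c"]
        assert row["p_value"] == 1.0

    def test_reference_binary_counts_give_tiny_chisq_pvalue(self):
        # 316/429 vs 421/895 male split: chi-square p < 1e-5
        table = np.array([[316, 429 - 316], [421, 895 - 421]])
        p = stats.chi2_contingency(table, correction=False).pvalue
        assert p < 1e-5
        # and the summarizer reproduces that arithmetic on a matching cohort
        pr = np.array([True] * 429 + [False] * 895)
        male = np.array([1.0] * 316 + [0.0] * (429 - 316) + [1.0] * 421 + [0.0] * (895 - 421))
        from ctcsfat.cohort import CohortRecord

        records = [
            CohortRecord(patient_id=i, pr=bool(pr[i]), clinical={"male": male[i]},
                         agatston={}, fatomics={}, time_years=1.0, event=False)
            for i in range(len(pr))
        ]
        summary = summarize_cohort(records)
        assert summary.loc["male", "p_value"] == pytest.approx(p)
        assert summary.loc["male", "pr_pos"].startswith("316/429")

    def test_zero_margin_marked_not_applicable(self):
        from ctcsfat.cohort import CohortRecord

        records = [
            CohortRecord(patient_id=i, pr=i % 2 == 0, clinical={"b": 0.0},
                         agatston={}, fatomics={}, time_years=1.0, event=False)
            for i in range(20)
        ]
        row = summarize_cohort(records).loc["b"]
        assert np.isnan(row["p_value"])
        assert "not applicable" in row["note"]

    def test_single_arm_rejected(self):
        records = generate_cohort(CohortSpec(n_patients=30, seed=0))
        only_pos = [r for r in records if r.pr]
        with pytest.raises(ValueError, match="both PR arms"):
            summarize_cohort(only_pos)


class TestDiameterProfiles:
    def test_labels_match_requested_status(self):
        rng = np.random.default_rng(13)
        for want in (True, False, True, False, True):
            profiles = generate_diameter_profiles(want, rng)
            assert len(profiles) == 9
            assert patient_label(profiles).pr_patient == want
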