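import numpy as np
import pandas as pd
import pytest

from mlbpsp.synthetic_cohort import (
    DEFAULT_FEATURES,
    CohortConfig,
    PhenotypeArchetype,
    apply_missingness,
    default_archetypes,
    simulate_baseline_covariates,
    simulate_cohort,
)

from conftest import single_feature_archetype


def no_missing_config(**kw):
    defaults = dict(item_miss_rate=0.0, miss_visit_rates=(0.0, 0.0, 0.0, 0.0))
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        archs = [
            single_feature_archetype(label=1, weight=0.5),
            single_feature_archetype(label=2, weight=0.3),
        ]
        with pytest.raises(ValueError, match="weights"):
            simulate_cohort(no_missing_config(n_participants=10, seed=0), archs)

    def test_non_psd_cov_rejected(self):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            single_feature_archetype(cov=bad)

    def test_negative_residual_sd_rejected(self):
        with pytest.raises(ValueError, match="residual sd"):
            single_feature_archetype(sigma=-0.1)

    def test_visit_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            CohortConfig(visit_months=(0, 6, 6, 18))

    def test_rates_in_unit_interval(self):
        with pytest.raises(ValueError, match="rate"):
            CohortConfig(item_miss_rate=1.5)


class TestSimulateCohort:
    def test_archetype_counts_near_mixture_weights(self):
        # weights (0.456, 0.213, 0.192, 0.138) at n = 506 give expected
        # counts about (231, 108, 97, 70); allow 4 binomial SDs
        cfg = no_missing_config(n_participants=506, seed=3)
        panel = simulate_cohort(cfg, default_archetypes())
        counts = panel.truth.value_counts().sort_index()
        expected = {1: 231, 2: 108, 3: 97, 4: 70}
        for label, exp in expected.items():
            p = exp / 506
            sd = np.sqrt(506 * p * (1 - p))
            assert abs(counts[label] - exp) < 4 * sd

    def test_degenerate_zero_case(self):
        arch = single_feature_archetype(coeffs=(0.0, 0.0, 0.0), sigma=0.0)
        panel = simulate_cohort(no_missing_config(n_participants=5, seed=0), [arch])
        assert (panel.data["f"] == 0.0).all()

    def test_intercept_variance_moment_check(self):
        # G = diag(1,0,0), sigma = 0, mean 5: per-subject visit means have
        # variance ~1 across subjects and ~0 within subject
        arch = single_feature_archetype(
            coeffs=(5.0, 0.0, 0.0), cov=np.diag([1.0, 0.0, 0.0]), sigma=0.0
        )
        panel = simulate_cohort(no_missing_config(n_participants=2000, seed=1), [arch])
        sqrt_vals = np.sqrt(panel.data.set_index("pid")["f"])
        per_subject_mean = sqrt_vals.groupby("pid").mean()
        per_subject_var = sqrt_vals.groupby("pid").var(ddof=0)
        assert per_subject_mean.var(ddof=1) == pytest.approx(1.0, abs=0.12)
        assert per_subject_var.max() < 1e-20

    def test_panel_structure(self):
        cfg = no_missing_config(n_participants=20, seed=5)
        panel = simulate_cohort(cfg, default_archetypes())
        assert len(panel.data) == 20 * 4
        assert not panel.data.duplicated(["pid", "visit_month"]).any()
        assert (panel.data[list(DEFAULT_FEATURES)] >= 0).all().all()

    def test_reproducible(self):
        cfg = no_missing_config(n_participants=30, seed=9)
        a = simulate_cohort(cfg, default_archetypes())
        b = simulate_cohort(cfg, default_archetypes())
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_series_equal(a.truth, b.truth)

    def test_mixture_chi2_p_not_degenerate(self):
        # goodness-of-fit p over several seeds should not pile up near 0
        from scipy import stats

        weights = np.array([0.456, 0.213, 0.192, 0.138])
        ps = []
        for seed in range(10):
            cfg = no_missing_config(n_participants=506, seed=seed)
            panel = simulate_cohort(cfg, default_archetypes())
            counts = panel.truth.value_counts().reindex([1, 2, 3, 4], fill_value=0)
            exp = weights / weights.sum() * 506
            ps.append(stats.chisquare(counts, exp).pvalue)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.3

    def test_sqrt_transform_recovers_gaussian(self):
        # with means >= 3 sigma from 0 the Shapiro-Wilk rejection rate at
        # alpha = 0.05 stays near the nominal 5%
        from scipy import stats

        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            arch = single_feature_archetype(
                coeffs=(3.0, 0.0, 0.0), cov=np.zeros((3, 3)), sigma=0.3
            )
            cfg = no_missing_config(n_participants=50, seed=1000 + seed)
            panel = simulate_cohort(cfg, [arch])
            base = panel.data[panel.data["visit_month"] == 0]["f"]
            w = stats.shapiro(np.sqrt(base))
            rejections += w.pvalue < 0.05
        assert rejections / n_rep < 0.15


class TestApplyMissingness:
    def test_visit_deletion_rates(self):
        cfg = CohortConfig(
            n_participants=506,
            seed=7,
            miss_visit_rates=(0.0, 0.0, 0.083, 0.194),
            item_miss_rate=0.0,
        )
        panel = simulate_cohort(cfg, default_archetypes())
        out = apply_missingness(panel, cfg)
        n = 506
        n12 = n - (out.data["visit_month"] == 12).sum()
        n18 = n - (out.data["visit_month"] == 18).sum()
        assert abs(n12 - 42) < 4 * np.sqrt(n * 0.083 * 0.917)
        assert abs(n18 - 98) < 4 * np.sqrt(n * 0.194 * 0.806)

    def test_baseline_never_deleted(self):
        cfg = CohortConfig(
            n_participants=200, seed=2, miss_visit_rates=(0.9, 0.5, 0.5, 0.5),
            item_miss_rate=0.0,
        )
        panel = simulate_cohort(cfg, default_archetypes())
        out = apply_missingness(panel, cfg)
        assert set(out.data.loc[out.data["visit_month"] == 0, "pid"]) == set(out.participants)

    def test_identity_when_rates_zero(self):
        cfg = no_missing_config(n_participants=40, seed=4)
        panel = simulate_cohort(cfg, default_archetypes())
        out = apply_missingness(panel, cfg)
        pd.testing.assert_frame_equal(out.data, panel.data)
        assert out.n_removed == 0

    def test_item_rate_inversion_gives_28_percent_incomplete(self):
        # r solving 1-(1-r)^(17*4) = 0.283 should leave ~28.3% of
        # participants with at least one missing feature cell
        r = 1.0 - (1.0 - 0.283) ** (1.0 / 68.0)
        cfg = CohortConfig(
            n_participants=506, seed=13,
            miss_visit_rates=(0.0, 0.0, 0.0, 0.0), item_miss_rate=r,
        )
        panel = simulate_cohort(cfg, default_archetypes())
        out = apply_missingness(panel, cfg)
        incomplete = out.data.set_index("pid").isna().any(axis=1).groupby("pid").any()
        frac = incomplete.mean()
        assert abs(frac - 0.283) < 4 * np.sqrt(0.283 * 0.717 / 506)

    def test_participants_below_two_visits_removed(self):
        cfg = CohortConfig(
            n_participants=300, seed=8,
            miss_visit_rates=(0.0, 0.8, 0.8, 0.8), item_miss_rate=0.0,
        )
        panel = simulate_cohort(cfg, default_archetypes())
        out = apply_missingness(panel, cfg)
        counts = out.data.groupby("pid").size()
        assert (counts >= 2).all()
        assert out.n_removed == 300 - len(counts)
        assert out.n_removed > 0  # with these rates some must drop


class TestBaselineCovariates:
    def _panel_with_exact_truth(self, counts={1: 231, 2: 108, 3: 97, 4: 70}):
        labels = np.concatenate([[ph] * n for ph, n in counts.items()])
        pids = np.arange(1, len(labels) + 1)
        data = pd.DataFrame({"pid": np.repeat(pids, 2), "visit_month": [0, 6] * len(pids)})
        truth = pd.Series(labels, index=pd.Index(pids, name="pid"), name="phenotype")
        from mlbpsp.synthetic_cohort import CohortPanel

        return CohortPanel(data=data, truth=truth)

    def test_prevalence_counts_match_configuration(self):
        panel = self._panel_with_exact_truth()
        cfg = CohortConfig(seed=21)
        base = simulate_baseline_covariates(panel, cfg).set_index("pid")
        cpd = base["chronic_pulmonary_disease"].groupby(panel.truth).sum()
        expected = {1: 13, 2: 9, 3: 11, 4: 14}
        totals = {1: 231, 2: 108, 3: 97, 4: 70}
        for ph, exp in expected.items():
            p = exp / totals[ph]
            sd = np.sqrt(totals[ph] * p * (1 - p))
            assert abs(cpd[ph] - exp) < 4 * sd

    def test_zero_prevalence_gives_zero_column(self):
        panel = self._panel_with_exact_truth({1: 20, 2: 20, 3: 20, 4: 20})
        cfg = CohortConfig(
            seed=0, comorbidity_prevalence={"c": (0.0, 0.0, 0.0, 0.0)},
            count_rates={}, continuous_params={},
        )
        base = simulate_baseline_covariates(panel, cfg)
        assert (base["c"] == 0).all()

    def test_prevalence_one_equals_phenotype_indicator(self):
        panel = self._panel_with_exact_truth({1: 15, 2: 15, 3: 15, 4: 15})
        cfg = CohortConfig(
            seed=0, comorbidity_prevalence={"c": (0.0, 1.0, 0.0, 0.0)},
            count_rates={}, continuous_params={},
        )
        base = simulate_baseline_covariates(panel, cfg).set_index("pid")
        indicator = (panel.truth == 2).astype(int)
        pd.testing.assert_series_equal(base["c"], indicator, check_names=False)

    def test_missing_prevalence_entry_errors(self):
        panel = self._panel_with_exact_truth({1: 5, 2: 5, 3: 5, 4: 5})
        cfg = CohortConfig(
            seed=0, comorbidity_prevalence={"c": (0.1, 0.1)},
            count_rates={}, continuous_params={},
        )
        with pytest.raises(ValueError, match="missing prevalence"):
            simulate_baseline_covariates(panel, cfg)

    def test_requires_truth_labels(self):
        from mlbpsp.synthetic_cohort import CohortPanel

        panel = CohortPanel(
            data=pd.DataFrame({"pid": [1, 1], "visit_month": [0, 6]})
        )
        with pytest.raises(ValueError, match="truth"):
            simulate_baseline_covariates(panel, CohortConfig(seed=0))
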