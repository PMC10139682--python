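"""Descriptive layer: t tests, chi-square, alpha, Little's MCAR, subgroups."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcstrial.descriptives import (
    DegenerateInputError,
    TwoSampleSummary,
    chi_square_test,
    cronbach_alpha,
    describe,
    flag_covariates,
    little_mcar_test,
    pooled_t_test,
    subgroup_filter,
)


class TestPooledT:
    def test_published_risk_score_cell(self):
        # Baseline PDPI-R risk: control 11.44 (4.57) n=511 vs intervention
        # 11.28 (4.53) n=542 -> t = 0.57 on 1051 df.
        t, df, p = pooled_t_test(TwoSampleSummary(11.44, 4.57, 511, 11.28, 4.53, 542))
        assert round(t, 2) == 0.57
        assert df == 1051
        assert p == pytest.approx(0.57, abs=0.01)

    def test_dropout_risk_contrast_from_summaries(self):
        # Dropouts 12.14 (5.00) n=341 vs completers 10.99 (4.26) n=712.
        t, df, _ = pooled_t_test(TwoSampleSummary(12.14, 5.00, 341, 10.99, 4.26, 712))
        assert round(t, 2) == 3.87  # printed 3.88 from unrounded raw data
        assert df == 1051

    def test_equal_means_give_zero(self):
        t, _, p = pooled_t_test(TwoSampleSummary(5.0, 1.0, 30, 5.0, 2.5, 40))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5),
        s1=st.floats(0.5, 4), s2=st.floats(0.5, 4),
        n1=st.integers(5, 200), n2=st.integers(5, 200),
    )
    def test_antisymmetric_under_group_swap(self, m1, m2, s1, s2, n1, n2):
        t1, df1, p1 = pooled_t_test(TwoSampleSummary(m1, s1, n1, m2, s2, n2))
        t2, df2, p2 = pooled_t_test(TwoSampleSummary(m2, s2, n2, m1, s1, n1))
        assert t1 == pytest.approx(-t2)
        assert df1 == df2
        assert p1 == pytest.approx(p2)


class TestChiSquare:
    def test_published_residence_cell(self):
        # Urban residence 404/511 vs 434/542: chi2 = 0.17 (prints 0.2), df 1.
        chi2, df, p = chi_square_test([[404, 107], [434, 108]])
        assert chi2 == pytest.approx(0.17, abs=0.005)
        assert round(chi2, 1) == 0.2
        assert df == 1
        assert p == pytest.approx(0.68, abs=0.005)

    def test_parity_counts_recomputed(self):
        # The report prints 4.0; the printed counts give 4.11.
        chi2, df, p = chi_square_test([[296, 215], [347, 195]])
        assert chi2 == pytest.approx(4.11, abs=0.005)
        assert df == 1
        assert p < 0.05

    def test_proportional_table_gives_zero(self):
        chi2, _, p = chi_square_test([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_expected_counts(self):
        tab = np.array([[12.0, 5.0, 9.0], [7.0, 11.0, 4.0]])
        chi2, df, _ = chi_square_test(tab)
        exp = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        assert chi2 == pytest.approx(float(((tab - exp) ** 2 / exp).sum()))
        assert df == 2

    def test_invariant_under_permutation(self, rng):
        tab = rng.integers(1, 50, size=(3, 4)).astype(float)
        chi2, df, _ = chi_square_test(tab)
        perm = tab[rng.permutation(3)][:, rng.permutation(4)]
        chi2p, dfp, _ = chi_square_test(perm)
        assert chi2 == pytest.approx(chi2p)
        assert df == dfp

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_square_test([[0, 0], [3, 4]])


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 4))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_independent_items_give_near_zero(self, rng):
        x = rng.normal(size=(20_000, 2))
        assert abs(cronbach_alpha(x)) < 3 * 2 / np.sqrt(20_000)

    def test_small_fixture_matches_formula(self):
        x = np.array([[1, 2, 3], [2, 3, 4], [4, 4, 5], [3, 5, 6]], dtype=float)
        k = 3
        expected = k / (k - 1) * (1 - x.var(0, ddof=1).sum() / x.sum(1).var(ddof=1))
        assert cronbach_alpha(x) == pytest.approx(expected)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            cronbach_alpha(np.array([[1.0, -1.0]] * 5))


class TestLittleMcar:
    def test_complete_data_not_applicable(self, rng):
        with pytest.raises(DegenerateInputError):
            little_mcar_test(rng.normal(size=(30, 3)))

    def test_df_formula_two_patterns(self, rng):
        y = rng.normal(size=(200, 2))
        y[:60, 1] = np.nan
        _, df, _ = little_mcar_test(y)
        assert df == (2 + 1) - 2  # sum of pattern sizes minus p

    def test_statistic_zero_when_pattern_means_coincide(self):
        # Symmetric construction: both patterns share the same mean exactly.
        base = np.array([[1.0, 2.0], [3.0, 4.0], [1.0, 4.0], [3.0, 2.0]])
        y = np.vstack([base, base])
        y[4:, 1] = np.nan
        stat, _, p = little_mcar_test(y)
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_type_one_error_calibrated_under_mcar(self):
        # MCAR truth: rejection rate at alpha=.05 should sit near .05.
        reps, n = 250, 400
        rejections = 0
        rng = np.random.default_rng(606)
        for _ in range(reps):
            y = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
            y[rng.random(n) < 0.3, 1] = np.nan
            _, _, p = little_mcar_test(y)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_detects_mean_shifted_missingness(self, rng):
        # Strongly MAR-by-value data should be rejected.
        y = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=800)
        y[y[:, 0] > 0.3, 1] = np.nan
        _, _, p = little_mcar_test(y)
        assert p < 1e-4


class TestSubgroups:
    def test_epds_gt9_is_strict(self, default_trial):
        df = default_trial.data
        df = df.copy()
        df.loc[df.index[0], "EPDS_T0"] = 9.0
        ds = default_trial.subset(np.ones(len(df), dtype=bool))
        ds.data.loc[ds.data.index[0], "EPDS_T0"] = 9.0
        filtered = subgroup_filter(ds, "epds_gt9")
        assert ds.data.loc[0, "id"] not in set(filtered.data["id"])
        assert (filtered.data["EPDS_T0"] > 9).all()

    def test_evaluative_listwise_excludes_single_missing_cell(self, complete_trial):
        ds = complete_trial.subset(np.ones(len(complete_trial), dtype=bool))
        ds.data.loc[0, "SCS_SF_T1"] = np.nan
        filtered = subgroup_filter(ds, "evaluative")
        assert len(filtered) == len(ds) - 1
        # Per-model variant keeps the record when its instrument is complete.
        per_model = subgroup_filter(ds, "evaluative", instruments=["EPDS"])
        assert len(per_model) == len(ds)

    def test_filter_counts_match_enumeration(self, default_trial):
        from lcstrial.schema import score_columns

        mask = default_trial.data[score_columns()].notna().all(axis=1)
        filtered = subgroup_filter(default_trial, "evaluative")
        assert len(filtered) == int(mask.sum())

    def test_unknown_rule_rejected(self, default_trial):
        with pytest.raises(ValueError):
            subgroup_filter(default_trial, "completers")


class TestCovariateFlagging:
    def test_imbalanced_covariate_flagged(self, rng):
        from lcstrial.simulate import SimConfig, generate_trial

        ds = generate_trial(SimConfig(seed=77, n_intervention=800, n_control=800,
                                      missingness={"mode": "none"}))
        ds.data["parity"] = np.where(
            (ds.data["arm"] == "intervention") | (rng.random(len(ds)) < 0.2),
            "primiparous", "multiparous",
        )
        assert "parity" in flag_covariates(ds)

    def test_absent_covariate_logged_not_flagged(self, default_trial, caplog):
        ds = default_trial.subset(np.ones(len(default_trial), dtype=bool))
        ds.data = ds.data.drop(columns=["income"])
        with caplog.at_level(logging.WARNING):
            flags = flag_covariates(ds)
        assert "income" not in flags
        assert any("income" in rec.message for rec in caplog.records)


class TestDescribe:
    def test_report_structure(self, default_trial):
        rep = describe(default_trial)
        assert rep["n"] == {"intervention": 600, "control": 600}
        assert "pdpi_r" in rep["covariates"]
        assert "t" in rep["covariates"]["pdpi_r"]["test"]
        assert "EPDS" in rep["instruments"]
        assert rep["little_mcar"] is not None and rep["little_mcar"]["df"] > 0
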