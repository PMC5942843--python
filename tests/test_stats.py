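"""Repeatability and covariate statistics: Bland–Altman, CV, MDD, ICC(A,1),
right–left differences, repeated-measures ANOVA with sphericity handling and
stepwise covariate entry, linear regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plexusdti.phantom import CohortSpec, simulate_cohort_table
from plexusdti.stats import (
    PairedSeries,
    bland_altman,
    cv_percent,
    icc_agreement_single,
    icc_category,
    linreg,
    mdd,
    mdd_from_cv,
    repeatability_report,
    rl_percent_diff,
    rm_anova,
    rm_anova_stepwise,
)


class TestBlandAltman:
    def test_identical_pairs_zero_limits(self):
        x = np.array([0.3, 0.31, 0.29, 0.33])
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.lower == 0 and ba.upper == 0

    def test_hand_computed_limits(self):
        ba = bland_altman(np.array([1.0, 0.0]), np.array([0.0, 1.0]))  # d = (+1, -1)
        assert np.isclose(ba.mean_diff, 0.0)
        assert np.isclose(ba.upper, 1.96 * np.sqrt(2.0))
        assert np.isclose(ba.lower, -1.96 * np.sqrt(2.0))

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 0.1, 10), rng.normal(1, 0.1, 10)
        f, r = bland_altman(a, b), bland_altman(b, a)
        assert np.isclose(f.mean_diff, -r.mean_diff)
        assert np.isclose(f.upper, -r.lower)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries(x1=np.array([1.0]), x2=np.array([2.0]))


class TestCVAndMDD:
    def test_identical_pairs_zero(self):
        x = np.array([0.3, 0.35, 0.4])
        assert cv_percent(x, x) == 0.0
        assert mdd(x, x) == 0.0

    def test_printed_summary_triple_consistency(self):
        # FA nerve-mean row: mean 0.33, CV 15.6% -> MDD prints 0.10
        assert np.isclose(mdd_from_cv(0.33, 15.6), 0.101, atol=5e-4)
        # AD row: mean 1.85, CV 11.4% -> 0.41
        assert np.isclose(mdd_from_cv(1.85, 11.4), 0.413, atol=5e-4)

    def test_cv_matches_definition(self):
        # mean 0.33 with SD of paired differences 0.0515 -> CV 15.6%
        rng = np.random.default_rng(1)
        x1 = rng.normal(0.33, 0.02, 2000)
        d = rng.normal(0, 0.0515, 2000)
        x2 = x1 - d
        cv = cv_percent(x1, x2)
        grand = np.concatenate([x1, x2]).mean()
        assert np.isclose(cv, 100 * d.std(ddof=1) / grand, atol=1e-9)
        assert abs(cv - 15.6) < 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0))
    def test_cv_scale_invariant_and_mdd_identity(self, k):
        rng = np.random.default_rng(4)
        x1 = rng.normal(1.0, 0.2, 30)
        x2 = x1 + rng.normal(0, 0.1, 30)
        assert np.isclose(cv_percent(k * x1, k * x2), cv_percent(x1, x2), rtol=1e-9)
        # MDD = 1.96*(CV/100)*mean identically
        p = PairedSeries(x1=x1, x2=x2)
        assert np.isclose(mdd(p), mdd_from_cv(p.grand_mean, cv_percent(p)), rtol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(np.array([1.0, -1.0]), np.array([-1.0, 1.0]))


class TestICC:
    def test_duplicated_columns_give_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        icc, cat = icc_agreement_single(np.column_stack([col, col]))
        assert np.isclose(icc, 1.0) and cat == "excellent"

    def test_independent_noise_concentrates_at_zero(self):
        rng = np.random.default_rng(2)
        icc, _ = icc_agreement_single(rng.normal(0, 1, (1000, 2)))
        assert abs(icc) < 0.1

    def test_matches_brute_force_anova_sums(self):
        y = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 4.0], [6.0, 6.0]])
        n, k = y.shape
        # independent oracle: definitional sums of squares
        grand = y.mean()
        msr = k * ((y.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((y.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        icc, _ = icc_agreement_single(y)
        assert np.isclose(icc, expected, rtol=1e-12)

    def test_agreement_categories(self):
        assert icc_category(0.2) == "poor"
        assert icc_category(0.5) == "fair"
        assert icc_category(0.7) == "good"
        assert icc_category(0.8) == "excellent"

    def test_incomplete_matrix_rejected(self):
        y = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            icc_agreement_single(y)

    def test_matches_pingouin_icc_a1(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (8, 1)) + rng.normal(0, 0.5, (8, 3))
        icc, _ = icc_agreement_single(y)
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(8), 3),
                "r": np.tile(np.arange(3), 8),
                "y": y.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "s", "r", "y")
        ref_icc = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert np.isclose(icc, ref_icc, atol=1e-12)


class TestRLDiff:
    def test_equal_sides_zero(self):
        assert rl_percent_diff(1.3, 1.3) == 0.0

    def test_arithmetic(self):
        assert np.isclose(rl_percent_diff(1.1, 0.9), 20.0)

    def test_antisymmetric(self):
        assert np.isclose(rl_percent_diff(1.1, 0.9), -rl_percent_diff(0.9, 1.1))


class TestRMAnova:
    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        n = 12
        Y = rng.normal(0, 1, (n, 8)) + rng.normal(0, 0.5, (n, 1))
        eff = rm_anova(Y)
        rows = []
        for i in range(n):
            for si, s in enumerate(("right", "left")):
                for ri, r in enumerate(["C5", "C6", "C7", "C8"]):
                    rows.append({"subj": i, "side": s, "root": r, "y": Y[i, si * 4 + ri]})
        ref = pg.rm_anova(
            pd.DataFrame(rows), dv="y", within=["side", "root"], subject="subj", detailed=True
        )
        for name, src in (("side", "side"), ("root", "root"), ("side_x_root", "side * root")):
            row = ref[ref["Source"] == src].iloc[0]
            assert np.isclose(eff[name]["F"], row["F"], rtol=1e-8)
            assert np.isclose(eff[name]["p"], row["p_unc"], rtol=1e-8)
            assert np.isclose(eff[name]["epsilon"], row["eps"], rtol=1e-6)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        rej = sum(
            rm_anova(rng.normal(0, 1, (20, 8)))["side"]["p"] < 0.05 for _ in range(500)
        )
        assert 0.03 <= rej / 500 <= 0.07

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(8)
        n = 60
        Y = rng.normal(0, 1, (n, 8)) + rng.normal(0, 1.0, (n, 1))  # CS covariance
        eff = rm_anova(Y)
        assert eff["root"]["epsilon"] > 0.9
        assert abs(eff["root"]["p_gg"] - eff["root"]["p"]) < 0.05
        assert eff["root"]["p_corrected"] == eff["root"]["p"]  # Mauchly accepts


class TestStepwise:
    def _cohort(self, seed, **kw):
        return simulate_cohort_table(CohortSpec(**kw), rng=np.random.default_rng(seed))

    def test_bodyweight_enters_first_bmi_excluded_after(self):
        # strong pure-bodyweight effect with a correlated BMI candidate
        table, cov = self._cohort(12345)
        res = rm_anova_stepwise(table, cov, metric="md", candidates=("weight_kg", "bmi"))
        assert res.selected_covariates[0] == "weight_kg"
        assert "bmi" not in res.selected_covariates

    def test_entry_p_one_orders_by_marginal_f(self):
        rng = np.random.default_rng(9)
        n = 40
        # orthogonalised candidates: conditional order equals marginal-F order
        raw = rng.normal(0, 1, (n, 4))
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), raw]))
        cands = q[:, 1:]
        y8 = rng.normal(0, 0.5, (n, 8)) + (cands @ [0.9, 0.5, 0.2, 0.05])[:, None]
        table_rows = []
        for i in range(n):
            for si, s in enumerate(("right", "left")):
                for ri, r in enumerate(["C5", "C6", "C7", "C8"]):
                    table_rows.append(
                        dict(subject=f"S{i}", session=1, rater=1, side=s, root=r,
                             md=y8[i, si * 4 + ri])
                    )
        cov = pd.DataFrame(
            {"subject": [f"S{i}" for i in range(n)],
             **{f"c{j}": cands[:, j] for j in range(4)}}
        )
        res = rm_anova_stepwise(
            pd.DataFrame(table_rows), cov, metric="md",
            candidates=("c0", "c1", "c2", "c3"), entry_p=1.0,
        )
        u = y8.mean(axis=1)
        marg_f = []
        for j in range(4):
            r = np.corrcoef(cands[:, j], u)[0, 1]
            marg_f.append(r**2 / (1 - r**2))
        expected = [f"c{j}" for j in np.argsort(marg_f)[::-1]]
        assert res.selected_covariates == expected

    def test_missing_cells_rejected(self):
        table, cov = self._cohort(1, n_subjects=5)
        broken = table[~((table.subject == "S01") & (table.root == "C7"))]
        with pytest.raises(ValueError, match="cell|incomplete"):
            rm_anova_stepwise(broken, cov, metric="md")

    def test_row_order_invariance(self):
        table, cov = self._cohort(2)
        a = rm_anova_stepwise(table, cov, metric="md")
        shuffled = table.sample(frac=1.0, random_state=0)
        b = rm_anova_stepwise(shuffled, cov, metric="md")
        assert a.selected_covariates == b.selected_covariates
        assert np.isclose(a.effects["side"]["F"], b.effects["side"]["F"])


class TestLinreg:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = linreg(x, 2.0 * x + 1.0)
        assert np.isclose(res.r_squared, 1.0)
        assert np.isclose(res.slope, 2.0)

    def test_null_relation_large_n(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, 10_000)
        res = linreg(x, rng.normal(0, 1, 10_000))
        assert abs(res.slope) < 0.1 and res.r_squared < 0.01

    def test_cohort_slope_recovery_within_ci(self):
        hits = 0
        for rep in range(200):
            table, cov = simulate_cohort_table(
                CohortSpec(n_sessions=1), rng=np.random.default_rng(40_000 + rep)
            )
            subj = table.groupby("subject")["md"].mean()
            w = cov.set_index("subject").loc[subj.index, "weight_kg"]
            res = linreg(w.to_numpy(), subj.to_numpy())
            lo, hi = res.slope_ci()
            if lo <= -3.49e-6 <= hi:
                hits += 1
        assert hits / 200 >= 0.90

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            linreg(np.ones(5), np.arange(5.0))


class TestRepeatabilityReport:
    def test_shape_and_identity(self):
        table, _ = simulate_cohort_table(CohortSpec(), rng=np.random.default_rng(3))
        rep = repeatability_report(table, pairing="session")
        assert len(rep) == 5 * 4  # 4 roots + Total, 4 metrics
        # MDD == 1.96*(CV/100)*mean on every row
        np.testing.assert_allclose(
            rep["mdd"], 1.96 * rep["cv_pct"] / 100.0 * rep["mean"], rtol=1e-9
        )

    def test_cv_near_generator_settings(self):
        # within-subject noise emulates observed repeatability (CV ~8-17%)
        table, _ = simulate_cohort_table(
            CohortSpec(n_subjects=60), rng=np.random.default_rng(21)
        )
        rep = repeatability_report(table, pairing="session")
        total = rep[rep.root == "Total"].set_index("metric")
        assert 12.0 < total.loc["fa", "cv_pct"] < 19.0
        assert 9.0 < total.loc["md", "cv_pct"] < 15.0
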