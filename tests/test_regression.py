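import numpy as np
import pytest

from _oracles import naive_or_2x2
from ploidyscope import (
    GroupedCohort,
    Pattern,
    conditional_odds_ratio,
    fit_logistic_firth,
    fit_logistic_grouped,
    grouped_cohort_from_frame,
)
from ploidyscope.errors import ModelError


def two_by_two(a, b, c, d):
    """Exposed (icm=1): a positive / b negative; unexposed: c / d."""
    return GroupedCohort(
        patterns=[
            Pattern(cytology=0, icm=1, n_positive_outcome=a, n_total=a + b),
            Pattern(cytology=0, icm=0, n_positive_outcome=c, n_total=c + d),
        ]
    )


class TestFitLogisticGrouped:
    def test_null_cohort_gives_unit_odds_ratios(self):
        cohort = GroupedCohort(
            patterns=[
                Pattern(cytology=cyt, icm=icm, n_positive_outcome=30, n_total=100)
                for cyt in (0, 1)
                for icm in (0, 1)
            ]
        )
        fit = fit_logistic_grouped(cohort, ["cytology", "icm"])
        assert fit.converged
        assert fit.odds_ratios["cytology"] == pytest.approx(1.0, abs=1e-6)
        assert fit.odds_ratios["icm"] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("a,b,c,d", [(30, 10, 5, 55), (8, 2, 4, 16), (1, 9, 3, 7)])
    def test_single_predictor_matches_cross_product_ratio(self, a, b, c, d):
        fit = fit_logistic_grouped(two_by_two(a, b, c, d), ["icm"])
        assert fit.converged
        assert fit.odds_ratios["icm"] == pytest.approx(naive_or_2x2(a, b, c, d), rel=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        cells = [(0, 0, 12, 40), (0, 1, 25, 35), (1, 0, 18, 30), (1, 1, 52, 60)]
        cohort = GroupedCohort(
            patterns=[Pattern(cytology=cyt, icm=icm, n_positive_outcome=y, n_total=n)
                      for cyt, icm, y, n in cells]
        )
        fit = fit_logistic_grouped(cohort, ["cytology", "icm"])
        X = np.array([[1.0, cyt, icm] for cyt, icm, _, _ in cells])
        y = np.array([[y, n - y] for _, _, y, n in cells], dtype=float)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for j, name in enumerate(["intercept", "cytology", "icm"]):
            assert fit.coefficients[name] == pytest.approx(ref.params[j], abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_saturated_two_predictor_fit_equals_conditional_ors(self, seed):
        # all eight cells >= 1: the saturated model (both predictors plus
        # interaction) reproduces the closed-form stratum-wise cross-product
        # ratios exactly
        rng = np.random.default_rng(seed)
        cells = rng.integers(1, 60, size=8)
        patterns, idx = [], 0
        for cyt in (0, 1):
            for icm in (0, 1):
                pos, neg = int(cells[idx]), int(cells[idx + 1])
                idx += 2
                patterns.append(
                    Pattern(cytology=cyt, icm=icm, n_positive_outcome=pos, n_total=pos + neg)
                )
        cohort = GroupedCohort(patterns)
        fit = fit_logistic_grouped(cohort, ["cytology", "icm", "cytology:icm"])
        assert fit.converged
        cond0 = conditional_odds_ratio(cohort, "icm", stratum={"cytology": 0})
        cond1 = conditional_odds_ratio(cohort, "icm", stratum={"cytology": 1})
        assert fit.odds_ratios["icm"] == pytest.approx(cond0["or"], rel=1e-6)
        or_icm_in_positive = fit.odds_ratios["icm"] * fit.odds_ratios["cytology:icm"]
        assert or_icm_in_positive == pytest.approx(cond1["or"], rel=1e-6)

    def test_deviance_never_increases(self):
        fit = fit_logistic_grouped(two_by_two(30, 10, 5, 55), ["icm"])
        trace = fit.deviance_trace
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_study_fixture_cytology_alone_is_separated(self, study_cohort_df):
        grouped = grouped_cohort_from_frame(study_cohort_df)
        fit = fit_logistic_grouped(grouped, ["cytology"])
        assert "cytology" in fit.separation
        assert not fit.converged
        assert fit.coefficients["cytology"] is None
        assert fit.odds_ratios["cytology"] == float("inf")
        assert fit.wald_ci["cytology"] is None

    def test_study_fixture_two_predictor_icm_or_is_identifiable(self, study_cohort_df):
        grouped = grouped_cohort_from_frame(study_cohort_df)
        fit = fit_logistic_grouped(grouped, ["cytology", "icm"])
        assert "cytology" in fit.separation
        assert "icm" not in fit.separation
        assert fit.odds_ratios["icm"] == pytest.approx(201.6, rel=1e-3)
        low, high = fit.wald_ci["icm"]
        assert low == pytest.approx(78.43, abs=0.05)
        assert high == pytest.approx(518.23, abs=0.5)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ModelError):
            fit_logistic_grouped(two_by_two(3, 4, 5, 6), ["icm", "icm"])


class TestFirth:
    def test_finite_under_separation(self, study_cohort_df):
        grouped = grouped_cohort_from_frame(study_cohort_df)
        fit = fit_logistic_firth(grouped, ["cytology", "icm"])
        assert fit.converged
        assert all(np.isfinite(v) for v in fit.coefficients.values())
        assert any("Firth" in note for note in fit.notes)

    def test_close_to_mle_when_no_separation(self):
        mle = fit_logistic_grouped(two_by_two(300, 100, 50, 550), ["icm"])
        firth = fit_logistic_firth(two_by_two(300, 100, 50, 550), ["icm"])
        assert firth.coefficients["icm"] == pytest.approx(
            mle.coefficients["icm"], abs=0.05
        )


class TestConditionalOddsRatio:
    def test_study_fixture_icm_within_cytology_positive(self, study_cohort_df):
        grouped = grouped_cohort_from_frame(study_cohort_df)
        out = conditional_odds_ratio(grouped, "icm", stratum={"cytology": 1})
        assert out["or"] == pytest.approx(201.6, abs=1e-9)
        assert out["cells"] == {"a": 288, "b": 6, "c": 20, "d": 84}
        low, high = out["ci"]
        assert round(low, 2) == pytest.approx(78.43, abs=0.005)
        assert round(high, 2) == pytest.approx(518.23, abs=0.005)

    def test_balanced_table_gives_unit_or(self):
        out = conditional_odds_ratio(two_by_two(7, 7, 7, 7), "icm")
        assert out["or"] == pytest.approx(1.0)

    def test_zero_cell_undefined_unless_continuity(self):
        cohort = two_by_two(10, 0, 5, 5)
        out = conditional_odds_ratio(cohort, "icm")
        assert out["or"] is None
        corrected = conditional_odds_ratio(cohort, "icm", continuity=True)
        assert corrected["or"] == pytest.approx(naive_or_2x2(10.5, 0.5, 5.5, 5.5))


class TestParameterRecovery:
    def test_known_coefficients_recovered_within_3_se(self):
        """Simulate grouped data from known (b0, b1, b2) and refit."""
        from scipy.special import expit

        true = {"intercept": -1.0, "cytology": 1.2, "icm": 2.0}
        rng = np.random.default_rng(2024)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            patterns = []
            for cyt in (0, 1):
                for icm in (0, 1):
                    p = expit(true["intercept"] + true["cytology"] * cyt + true["icm"] * icm)
                    n_tot = 500
                    y = int(rng.binomial(n_tot, p))
                    patterns.append(
                        Pattern(cytology=cyt, icm=icm, n_positive_outcome=y, n_total=n_tot)
                    )
            fit = fit_logistic_grouped(GroupedCohort(patterns), ["cytology", "icm"])
            if not fit.converged:
                continue
            hit = True
            for name, beta in true.items():
                est = fit.coefficients[name]
                low, high = np.log(fit.wald_ci[name])
                se = (high - low) / (2 * 1.959964)
                if abs(est - beta) > 3 * se:
                    hit = False
            ok += hit
        assert ok >= 0.95 * n_rep
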