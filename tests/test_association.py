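import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from snpcc.association import (
    chisq_2x2,
    crude_or,
    fit_logistic,
    genotype_distribution_test,
    trend_test,
)
from snpcc.data_model import GenotypeCounts, TwoByTwo, make_contrast
from snpcc.errors import (
    CollinearityError,
    SeparationError,
    ValidationError,
    ZeroCellError,
)
from conftest import cohort_from_groups

positive_cells = st.tuples(*[st.integers(1, 400)] * 4)


class TestCrudeOr:
    def test_rs2976392_het_row(self):
        est = crude_or(TwoByTwo(308, 319, 299, 403))
        assert round(est.or_hat, 2) == 1.30
        assert round(est.ci_low, 2) == 1.05
        assert round(est.ci_high, 2) == 1.62
        assert round(est.p, 3) == 0.017

    def test_rs4072037_protective_row(self):
        est = crude_or(TwoByTwo(143, 528, 201, 553))
        assert round(est.or_hat, 2) == 0.75
        assert round(est.ci_low, 2) == 0.58
        assert round(est.ci_high, 2) == 0.95

    def test_symmetric_table(self):
        est = crude_or(TwoByTwo(10, 10, 10, 10))
        assert est.or_hat == pytest.approx(1.0)
        assert est.p == pytest.approx(1.0)

    def test_zero_cell_raises_with_advice(self):
        with pytest.raises(ZeroCellError, match="0.5"):
            crude_or(TwoByTwo(0, 5, 5, 5))

    def test_optional_continuity_correction(self):
        est = crude_or(TwoByTwo(0, 5, 5, 5), correction=0.5)
        assert est.or_hat == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    @given(positive_cells)
    def test_antisymmetry(self, cells):
        t = TwoByTwo(*cells)
        fwd, rev = crude_or(t), crude_or(t.swapped())
        assert rev.or_hat == pytest.approx(1 / fwd.or_hat)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low)
        assert rev.p == pytest.approx(fwd.p)

    @given(positive_cells)
    def test_ci_reconstructs_from_se(self, cells):
        est = crude_or(TwoByTwo(*cells))
        z = stats.norm.ppf(0.975)
        assert est.ci_low == pytest.approx(np.exp(est.log_or - z * est.se_log))
        assert est.ci_high == pytest.approx(np.exp(est.log_or + z * est.se_log))
        assert est.ci_low <= est.or_hat <= est.ci_high


class TestGenotypeDistributionTest:
    def test_rs2976392(self):
        res = genotype_distribution_test(
            GenotypeCounts("rs2976392", (319, 308, 65), (403, 299, 72))
        )
        assert res.df == 2
        assert round(res.p, 3) == 0.058

    def test_rs2274223(self):
        res = genotype_distribution_test(
            GenotypeCounts("rs2274223", (405, 254, 33), (514, 226, 34))
        )
        assert round(res.p, 3) == 0.007

    def test_identical_rows(self):
        res = genotype_distribution_test(GenotypeCounts("rs1", (10, 20, 30), (10, 20, 30)))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_empty_column_dropped_with_warning(self):
        counts = GenotypeCounts("rs1", (10, 20, 0), (15, 15, 0))
        with pytest.warns(UserWarning, match="df reduced"):
            res = genotype_distribution_test(counts)
        assert res.df == 1

    @given(
        case=st.tuples(*[st.integers(1, 100)] * 3),
        control=st.tuples(*[st.integers(1, 100)] * 3),
    )
    def test_matches_scipy_contingency(self, case, control):
        res = genotype_distribution_test(GenotypeCounts("rs1", case, control))
        chi2, p, df, _ = stats.chi2_contingency([case, control], correction=False)
        assert res.chi2 == pytest.approx(chi2)
        assert res.p == pytest.approx(p)
        assert res.df == df == 2


class TestChisq2x2:
    def test_rs2274223_dominant(self):
        res = chisq_2x2(TwoByTwo(287, 405, 260, 514))
        assert round(res.p, 3) == 0.002

    def test_rs2294008_dominant_resolved_counts(self):
        res = chisq_2x2(TwoByTwo(370, 322, 369, 405))
        assert round(res.p, 3) == 0.027

    def test_uniform_table(self):
        res = chisq_2x2(TwoByTwo(5, 5, 5, 5))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning):
            res = chisq_2x2(TwoByTwo(0, 10, 0, 10))
        assert res.p == 1.0

    @pytest.mark.parametrize(
        "cells",
        [
            (309, 322, 297, 405),
            (308, 319, 299, 403),
            (254, 405, 226, 514),
            (143, 528, 201, 553),
            (370, 322, 369, 405),
            (373, 319, 371, 403),
            (287, 405, 260, 514),
            (164, 528, 221, 553),
            (404, 288, 405, 369),
        ],
    )
    def test_wald_and_pearson_agree_on_study_contrasts(self, cells):
        """The two conventions agree to ~2 significant figures on every
        study contrast (they can disagree by one unit in the third decimal
        after rounding, e.g. 0.0226 vs 0.0225)."""
        wald = crude_or(TwoByTwo(*cells)).p
        pearson = chisq_2x2(TwoByTwo(*cells)).p
        assert abs(wald - pearson) < 0.001
        assert round(wald, 2) == round(pearson, 2)


class TestTrendTest:
    def test_flat_distribution(self):
        res = trend_test(GenotypeCounts("rs1", (30, 30, 30), (30, 30, 30)))
        assert res.p == pytest.approx(1.0)

    def test_monotone_trend_detected(self):
        res = trend_test(GenotypeCounts("rs1", (10, 30, 60), (60, 30, 10)))
        assert res.p < 1e-6

    def test_distinct_from_2df_test(self):
        counts = GenotypeCounts("rs2294008", (322, 309, 61), (405, 297, 72))
        assert trend_test(counts).p != genotype_distribution_test(counts).p


class TestFitLogistic:
    def test_saturated_single_predictor_equals_crude_or(self, snp_defs):
        cohort = cohort_from_groups(
            snp_defs,
            [
                {"status": "case", "genotypes": {"rs2976392": "AG"}, "n": 308},
                {"status": "case", "genotypes": {"rs2976392": "GG"}, "n": 319},
                {"status": "control", "genotypes": {"rs2976392": "AG"}, "n": 299},
                {"status": "control", "genotypes": {"rs2976392": "GG"}, "n": 403},
            ],
        )
        logit = fit_logistic(cohort, "rs2976392", "het_vs_ref")
        crude = crude_or(TwoByTwo(308, 319, 299, 403))
        assert logit.or_hat == pytest.approx(crude.or_hat, rel=1e-6)
        assert logit.se_log == pytest.approx(crude.se_log, rel=1e-5)
        assert logit.n_used == 308 + 319 + 299 + 403

    def test_separation_error_names_term(self, snp_defs):
        cohort = cohort_from_groups(
            snp_defs,
            [
                {"status": "case", "sex": "male",
                 "genotypes": {"rs2976392": "AG"}, "n": 20},
                {"status": "case", "sex": "male",
                 "genotypes": {"rs2976392": "GG"}, "n": 20},
                {"status": "control", "sex": "female",
                 "genotypes": {"rs2976392": "AG"}, "n": 20},
                {"status": "control", "sex": "female",
                 "genotypes": {"rs2976392": "GG"}, "n": 20},
            ],
        )
        with pytest.raises(SeparationError, match="sex_male"):
            fit_logistic(cohort, "rs2976392", "het_vs_ref", ["sex"])

    def test_constant_covariate_rejected(self, snp_defs):
        cohort = cohort_from_groups(
            snp_defs,
            [
                {"status": "case", "genotypes": {"rs2976392": "AG"}, "n": 10},
                {"status": "control", "genotypes": {"rs2976392": "GG"}, "n": 10},
            ],
        )
        with pytest.raises((ValidationError, SeparationError)):
            fit_logistic(cohort, "rs2976392", "het_vs_ref", ["smoking"])

    def test_unknown_covariate(self, small_cohort):
        with pytest.raises(ValidationError, match="unknown covariate"):
            fit_logistic(small_cohort, "rs2294008", "dominant", ["height"])

    def test_adjusted_flag_and_covariates_recorded(self, study_cohort):
        est = fit_logistic(
            study_cohort, "rs2274223", "dominant",
            ["age", "sex", "bmi", "smoking", "drinking"],
        )
        assert est.adjusted
        assert est.covariates == ("age", "sex", "bmi", "smoking", "drinking")
        assert est.or_hat > 1  # risk direction preserved under adjustment
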