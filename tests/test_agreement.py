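import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import assaydiff.agreement as agr
from assaydiff.exceptions import (
    DegenerateStatisticError,
    InsufficientDataError,
    SingularDesignError,
)
from assaydiff.synthetic import SyntheticConfig, generate

from conftest import make_dataset


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    @pytest.mark.parametrize(
        "msb,msw,k,expected",
        [
            (102.08, 3.87, 2, 0.93),   # printed mean squares round to 0.93
            (5.0, 5.0, 2, 0.0),        # no between-subject excess
            (5.0, 0.0, 2, 1.0),        # perfect within-subject agreement
        ],
    )
    def test_from_components(self, msb, msw, k, expected):
        val = agr.icc_from_components(agr.AnovaComponents(msb, msw, k))
        assert round(val, 2) == expected

    def test_printed_components_value(self):
        val = agr.icc_from_components(agr.AnovaComponents(102.08, 3.87, 2))
        assert val == pytest.approx((102.08 - 3.87) / (102.08 + 3.87))

    def test_zero_denominator(self):
        with pytest.raises(DegenerateStatisticError):
            agr.icc_from_components(agr.AnovaComponents(0.0, 0.0, 2))

    def test_identical_methods_give_one(self):
        data = make_dataset([(40, "male", v, v) for v in (5, 10, 20, 30)])
        _, val = agr.icc(data)
        assert val == pytest.approx(1.0)

    def test_matches_sums_of_squares_oracle(self, study_cohort):
        """Brute-force one-way ANOVA from explicit sums of squares."""
        x = np.array([[s.clia, s.lcms] for s in study_cohort])
        n, k = x.shape
        grand = x.sum() / (n * k)
        row_means = x.sum(axis=1) / k
        ssb = k * sum((rm - grand) ** 2 for rm in row_means)
        ssw = sum((x[i, j] - row_means[i]) ** 2
                  for i in range(n) for j in range(k))
        msb, msw = ssb / (n - 1), ssw / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        comp, val = agr.icc(study_cohort)
        assert comp.msb == pytest.approx(msb, abs=1e-10)
        assert comp.msw == pytest.approx(msw, abs=1e-10)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_independent_methods_near_zero(self):
        rng = np.random.default_rng(11)
        rows = [
            (40, "male", c, l)
            for c, l in zip(rng.uniform(3, 50, 5000), rng.uniform(3, 50, 5000))
        ]
        _, val = agr.icc(make_dataset(rows))
        assert abs(val) < 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            agr.icc(make_dataset([(40, "male", 10, 11), (50, "male", 12, 13)]))

    @given(
        msb=st.floats(0.1, 1e3), msw=st.floats(0.1, 1e3),
        bump=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_components(self, msb, msw, bump):
        base = agr.icc_from_components(agr.AnovaComponents(msb, msw, 2))
        more_between = agr.icc_from_components(
            agr.AnovaComponents(msb + bump, msw, 2))
        more_within = agr.icc_from_components(
            agr.AnovaComponents(msb, msw + bump, 2))
        assert more_between > base
        assert more_within < base


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

class TestBlandAltman:
    def test_printed_mean_sd_arithmetic(self):
        # direct arithmetic on the printed mean/SD; the published limits
        # (-5.95, 8.61) were computed from unrounded inputs
        mean, sd = 1.33, 3.71
        lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
        assert lo == pytest.approx(-5.95, abs=0.02)
        assert hi == pytest.approx(8.61, abs=0.02)

    def test_identical_diffs_collapse(self):
        data = make_dataset([(40, "male", c, c + 2.5) for c in (5, 10, 20)])
        res = agr.bland_altman(data)
        assert res.sd_diff == 0
        assert res.loa_lower == res.mean_diff == res.loa_upper == 2.5

    def test_two_pass_oracle(self, study_cohort):
        diffs = [s.lcms - s.clia for s in study_cohort]
        mean = sum(diffs) / len(diffs)
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1))
        res = agr.bland_altman(study_cohort)
        assert res.mean_diff == pytest.approx(mean, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_loa_identity_exact(self, seed):
        res = agr.bland_altman(generate(SyntheticConfig(n=50, seed=seed)))
        assert res.loa_lower == res.mean_diff - 1.96 * res.sd_diff
        assert res.loa_upper == res.mean_diff + 1.96 * res.sd_diff
        assert res.loa_lower <= res.mean_diff <= res.loa_upper

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            agr.bland_altman(make_dataset([(40, "male", 10, 11)]))


# ---------------------------------------------------------------------------
# paired t
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_null_case(self):
        rows = [(40, "male", 20, 20 + e) for e in
                (0.01, -0.01, 0.02, -0.02, 0.03, -0.03)]
        t, p = agr.paired_t(make_dataset(rows))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_shifted_cohort_significant(self):
        data = generate(SyntheticConfig(n=138, seed=5))
        t, p = agr.paired_t(data)
        assert p < 0.01
        # independent t CDF evaluation
        d = np.array(data.diffs)
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_manual = 2 * stats.t.sf(abs(t_manual), df=len(d) - 1)
        assert t == pytest.approx(t_manual, rel=1e-10)
        assert p == pytest.approx(p_manual, rel=1e-10)

    def test_single_sample_error(self):
        with pytest.raises(InsufficientDataError):
            agr.paired_t(make_dataset([(40, "male", 10, 12)]))

    def test_degenerate_variance_error(self):
        data = make_dataset([(40, "male", c, c + 1) for c in (5, 10, 20)])
        with pytest.raises(DegenerateStatisticError):
            agr.paired_t(data)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

class TestComparisonRegression:
    def test_exact_line(self):
        rows = [(40, "male", c, 2 * c + 1) for c in range(1, 11)]
        fit = agr.comparison_regression(make_dataset(rows))
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery_ci(self):
        fit = agr.comparison_regression(generate(SyntheticConfig(n=500, seed=9)))
        assert fit.slope_ci95[0] <= 1.161 <= fit.slope_ci95[1]
        assert fit.intercept_ci95[0] <= -2.009 <= fit.intercept_ci95[1]

    def test_constant_predictor_error(self):
        rows = [(40, "male", 10, v) for v in (11, 12, 13)]
        with pytest.raises(SingularDesignError):
            agr.comparison_regression(make_dataset(rows))

    def test_rmse_sse_identity_and_ci_contains_estimate(self, study_cohort):
        fit = agr.comparison_regression(study_cohort)
        assert fit.rmse ** 2 * (fit.n - 2) == pytest.approx(fit.sse, rel=1e-10)
        assert fit.slope_ci95[0] <= fit.slope <= fit.slope_ci95[1]
        assert fit.intercept_ci95[0] <= fit.intercept <= fit.intercept_ci95[1]


# ---------------------------------------------------------------------------
# crosstab / kappa / wilson
# ---------------------------------------------------------------------------

def crosstab_counts_dataset():
    """Dataset engineered to reproduce the published 2x2 at 20 ng/mL."""
    rows = []
    rows += [(40, "male", 25, 25)] * 60   # both >= 20
    rows += [(40, "male", 25, 15)] * 5    # clia >= 20, lcms < 20
    rows += [(40, "male", 15, 25)] * 7    # clia < 20, lcms >= 20
    rows += [(40, "male", 15, 15)] * 66   # both < 20
    return make_dataset(rows)


class TestCrossTab:
    def test_published_counts(self):
        tab = agr.threshold_crosstab(crosstab_counts_dataset(), 20.0)
        assert (tab.n_pp, tab.n_pn, tab.n_np, tab.n_nn) == (60, 5, 7, 66)
        assert tab.agreement_rate == pytest.approx(126 / 138)
        assert round(tab.agreement_rate * 100, 1) == 91.3
        assert round(tab.kappa, 2) == 0.83
        assert tab.discordant == 12

    def test_boundary_value_is_positive(self):
        tab = agr.threshold_crosstab(
            make_dataset([(40, "male", 20.0, 19.999)]), 20.0)
        assert tab.n_pn == 1

    def test_degenerate_same_side(self):
        data = make_dataset([(40, "male", 25, 26)] * 4)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            tab = agr.threshold_crosstab(data, 20.0)
        assert tab.agreement_rate == 1.0
        assert math.isnan(tab.kappa)

    def test_matches_loop_oracle(self):
        data = generate(SyntheticConfig(n=300, seed=13))
        tab = agr.threshold_crosstab(data, 20.0)
        counts = [0, 0, 0, 0]
        for s in data:
            c, l = s.clia >= 20.0, s.lcms >= 20.0
            counts[(0 if c else 2) + (0 if l else 1)] += 1
        assert [tab.n_pp, tab.n_pn, tab.n_np, tab.n_nn] == counts


class TestCohenKappa:
    @pytest.mark.parametrize(
        "cells,expected",
        [((60, 5, 7, 66), 0.83), ((50, 0, 0, 50), 1.0),
         ((25, 25, 25, 25), 0.0)],
    )
    def test_examples(self, cells, expected):
        assert round(agr.cohen_kappa(*cells), 2) == expected

    def test_empty_table(self):
        with pytest.raises(DegenerateStatisticError):
            agr.cohen_kappa(0, 0, 0, 0)

    @given(
        n_pp=st.integers(1, 50), n_pn=st.integers(0, 50),
        n_np=st.integers(0, 50), n_nn=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_one_iff_no_discordance(self, n_pp, n_pn, n_np, n_nn):
        k = agr.cohen_kappa(n_pp, n_pn, n_np, n_nn)
        if n_pn == 0 and n_np == 0:
            assert k == pytest.approx(1.0)
        else:
            assert k < 1.0


class TestWilson:
    def test_published_proportion(self):
        lo, hi = agr.wilson_ci(12, 138)
        assert (round(lo, 4), round(hi, 4)) == (0.0504, 0.1458)
        assert (round(lo * 100, 1), round(hi * 100, 1)) == (5.0, 14.6)

    def test_boundary_cases(self):
        assert agr.wilson_ci(0, 17)[0] == 0.0
        assert agr.wilson_ci(17, 17)[1] == 1.0

    def test_zero_n(self):
        with pytest.raises(DegenerateStatisticError):
            agr.wilson_ci(0, 0)

    @given(n=st.integers(1, 500), data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_interval_contains_estimate(self, n, data):
        s = data.draw(st.integers(0, n))
        lo, hi = agr.wilson_ci(s, n)
        assert 0.0 <= lo <= s / n <= hi <= 1.0


class TestReclassification:
    def test_published_pooled_proportion(self):
        res = agr.reclassification(crosstab_counts_dataset(), (20.0,))
        assert res.pooled_discordant == 12
        assert round(res.pooled_proportion, 4) == 0.087
        assert (round(res.pooled_wilson_ci[0] * 100, 1),
                round(res.pooled_wilson_ci[1] * 100, 1)) == (5.0, 14.6)

    def test_fully_concordant_dataset(self):
        data = make_dataset([(40, "male", 35, 36)] * 5
                            + [(40, "male", 10, 11)] * 5)
        res = agr.reclassification(data, (20.0, 30.0))
        assert res.pooled_discordant == 0

    def test_union_oracle(self):
        data = generate(SyntheticConfig(n=300, seed=17))
        res = agr.reclassification(data, (20.0, 30.0))
        union = {
            s.sample_id for s in data
            if (s.clia >= 20) != (s.lcms >= 20) or (s.clia >= 30) != (s.lcms >= 30)
        }
        assert res.pooled_discordant == len(union)

    def test_empty_thresholds_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            agr.reclassification(crosstab_counts_dataset(), ())
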