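"""Statistical machinery: paired t, MSE, mixed-model fits, coefficient z tests,
agreement tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bufcomp.comparison import (
    AssociationFit,
    ComparisonError,
    agreement_status,
    compare_coefficients,
    fit_association,
    mse,
    paired_ttest,
    tabulate_agreement,
)


def make_fit(coef, se, p, method="sausage", outcome="o", bem="b", stratum="pooled"):
    return AssociationFit(outcome=outcome, bem=bem, method=method, trim=25.0,
                          coef=coef, se=se, p=p, term="linear", converged=True,
                          n=100, stratum=stratum)


class TestPairedTTest:
    def test_identical_vectors(self):
        t, df, p, status = paired_ttest(np.ones(5), np.ones(5))
        assert (t, p, status) == (0.0, 1.0, "identical")
        assert df == 4

    def test_hand_computed_example(self):
        """Differences (1, 1, 2): mean 4/3, sd 1/sqrt(3) → t = 4 with df = 2."""
        t, df, p, status = paired_ttest(np.array([2.0, 3.0, 5.0]),
                                        np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(4.0)
        assert df == 2
        assert p == pytest.approx(2 * stats.t.sf(4.0, 2))

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        t1 = paired_ttest(x, y)[0]
        t2 = paired_ttest(y, x)[0]
        assert t1 == pytest.approx(-t2)

    def test_constant_nonzero_difference_degenerate(self):
        t, df, p, status = paired_ttest(np.arange(4.0) + 2.0, np.arange(4.0))
        assert status == "degenerate" and p == 0.0 and t == np.inf

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.3, size=50)
        t, df, p, _ = paired_ttest(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_rejection_rate_calibrated(self):
        """Paired noise: rejection at alpha = 0.05 ≈ 5% over 2000 reps."""
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=20)
            y = x + rng.normal(size=20)  # paired, equal means
            if paired_ttest(x, y)[2] < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_invariant_to_participant_ordering(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(size=40)
        perm = rng.permutation(40)
        assert paired_ttest(x, y)[0] == pytest.approx(paired_ttest(x[perm], y[perm])[0])
        assert mse(x, y) == pytest.approx(mse(x[perm], y[perm]))


class TestMse:
    def test_identical_zero(self):
        assert mse(np.arange(5.0), np.arange(5.0)) == 0.0

    def test_constant_shift(self):
        assert mse(np.arange(5.0) + 3.0, np.arange(5.0)) == pytest.approx(9.0)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=25), rng.normal(size=25)
        naive = sum((a - b) ** 2 for a, b in zip(x, y)) / 25
        assert mse(x, y) == pytest.approx(naive)


def simulate(rng, n=400, n_clusters=20, b=0.3, cluster_sd=0.5, resid_sd=1.0):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    clusters = np.repeat(np.arange(n_clusters), n // n_clusters)
    y = b * x + rng.normal(0, cluster_sd, n_clusters)[clusters] + rng.normal(0, resid_sd, n)
    return y, x, clusters


class TestFitAssociation:
    def test_recovers_known_coefficient(self):
        rng = np.random.default_rng(5)
        y, x, cl = simulate(rng, n=1000, n_clusters=50, b=0.3)
        fit = fit_association(y, x, cl)
        assert fit.converged
        assert abs(fit.coef - 0.3) < 2 * fit.se

    def test_zero_cluster_variance_matches_ols(self):
        """With no cluster effect the mixed model collapses to OLS."""
        rng = np.random.default_rng(6)
        y, x, cl = simulate(rng, n=500, n_clusters=10, b=0.2, cluster_sd=0.0)
        fit = fit_association(y, x, cl)
        ols = stats.linregress(x, y)
        assert fit.coef == pytest.approx(ols.slope, abs=1e-3)

    def test_covariates_enter_design(self):
        rng = np.random.default_rng(7)
        y, x, cl = simulate(rng, n=300, n_clusters=10, b=0.25)
        cov = pd.DataFrame({
            "age": rng.uniform(18, 66, 300),
            "gender": rng.choice(["female", "male"], 300),
        })
        y = y + 0.02 * (cov["age"] - 42).to_numpy()
        fit = fit_association(y, x, cl, covariates=cov)
        assert fit.converged
        assert abs(fit.coef - 0.25) < 3 * fit.se

    def test_spline_term_reports_omnibus_p(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        clusters = np.repeat(np.arange(10), n // 10)
        y = 0.5 * x**2 + rng.normal(size=n)  # purely curvilinear signal
        fit = fit_association(y, x, clusters, term="spline", spline_df=4)
        assert fit.term == "spline(4)"
        assert np.isnan(fit.coef)
        assert fit.p < 0.01  # omnibus test detects the curvature

    def test_needs_two_clusters(self):
        with pytest.raises(ComparisonError):
            fit_association(np.ones(10), np.ones(10), np.zeros(10))


class TestCompareCoefficients:
    def test_equal_coefficients(self):
        cc = compare_coefficients(make_fit(0.3, 0.1, 0.01),
                                  make_fit(0.3, 0.1, 0.01, method="detailed"))
        assert cc.z == 0.0 and cc.p == 1.0
        assert cc.status == "both"

    def test_closed_form_z(self):
        cc = compare_coefficients(make_fit(0.3, 0.1, 0.003),
                                  make_fit(0.1, 0.1, 0.32, method="detailed"))
        assert cc.z == pytest.approx(np.sqrt(2.0))
        assert cc.p == pytest.approx(2 * stats.norm.sf(np.sqrt(2.0)), rel=1e-6)
        assert cc.status == "only_method_1"

    def test_antisymmetric_under_swap(self):
        f1 = make_fit(0.3, 0.12, 0.01)
        f2 = make_fit(0.15, 0.08, 0.2, method="detailed")
        a = compare_coefficients(f1, f2)
        b = compare_coefficients(f2, f1)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_nonconverged_fit_rejected(self):
        bad = make_fit(0.1, 0.1, 0.5)
        bad.converged = False
        with pytest.raises(ComparisonError):
            compare_coefficients(bad, make_fit(0.1, 0.1, 0.5))

    def test_mismatched_outcome_rejected(self):
        with pytest.raises(ComparisonError):
            compare_coefficients(make_fit(0.1, 0.1, 0.5, outcome="a"),
                                 make_fit(0.1, 0.1, 0.5, outcome="b"))

    @given(p1=st.floats(0, 1), p2=st.floats(0, 1),
           alpha=st.floats(0.01, 0.2))
    @settings(max_examples=200, deadline=None)
    def test_status_pure_function_of_pvalues(self, p1, p2, alpha):
        status = agreement_status(p1, p2, alpha)
        expected = {
            (True, True): "both", (True, False): "only_method_1",
            (False, True): "only_method_2", (False, False): "neither",
        }[(p1 < alpha, p2 < alpha)]
        assert status == expected


class TestTabulateAgreement:
    def test_all_nonsignificant_zero_counts(self):
        comps = [
            compare_coefficients(make_fit(0.1, 0.2, 0.6, bem=f"b{i}"),
                                 make_fit(0.1, 0.2, 0.7, bem=f"b{i}",
                                          method="detailed"))
            for i in range(4)
        ]
        table = tabulate_agreement(comps)
        assert table.n_any_significant.sum() == 0
        assert table.n_differing.sum() == 0

    def test_hand_built_tally(self):
        """6 fits with known p values → counts match a manual tally."""
        pairs = [
            (0.01, 0.02),  # both
            (0.01, 0.50),  # only method 1
            (0.50, 0.01),  # only method 2
            (0.60, 0.70),  # neither
            (0.04, 0.06),  # only method 1 (boundary straddle)
            (0.05, 0.05),  # neither (p = alpha is not significant)
        ]
        comps = [
            compare_coefficients(make_fit(0.2, 0.1, p1, bem=f"b{i}"),
                                 make_fit(0.2, 0.1, p2, bem=f"b{i}",
                                          method="detailed"))
            for i, (p1, p2) in enumerate(pairs)
        ]
        table = tabulate_agreement(comps)
        row = table.iloc[0]
        assert row.n_pairs == 6
        assert row.n_any_significant == 4
        assert row.n_both_significant == 1
        assert row.n_differing == 3
        assert row.n_only_method_1 == 2
        assert row.n_only_method_2 == 1
        assert row.pct_differing == pytest.approx(50.0)
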