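"""Agreement statistics: oracles, identities and published-table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from limbalign.reliability import (RaterTable, UndefinedStatisticError,
                                   agreement_stats, icc_a1, pearson,
                                   reliability_report, rmse_identity)


def brute_force_icc_a1(ratings):
    """ICC(A,1) from first-principles sums of squares (explicit loops)."""
    ratings = np.asarray(ratings, float)
    n, k = ratings.shape
    grand = ratings.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        row_mean = sum(ratings[i]) / k
        ss_rows += k * (row_mean - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        col_mean = sum(ratings[:, j]) / n
        ss_cols += n * (col_mean - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (ratings[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestAgreementStats:
    def test_identical_sources(self):
        a = np.array([1.0, 2.0, 3.0])
        out = agreement_stats(a, a)
        assert out["mean_error"] == 0 and out["sd"] == 0 and out["rmse"] == 0

    def test_hand_computed_example(self):
        out = agreement_stats(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert out["mean_error"] == pytest.approx(0.0)
        assert out["sd"] == pytest.approx(1.0)
        assert out["rmse"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_ci_is_exact_t_interval(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        out = agreement_stats(a, b)
        d = a - b
        half = stats.t.ppf(0.975, 9) * d.std(ddof=1) / np.sqrt(10)
        assert out["mean_error_ci"][0] == pytest.approx(d.mean() - half)
        assert out["mean_error_ci"][1] == pytest.approx(d.mean() + half)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_rmse_algebraic_identity(self, values):
        d = np.asarray(values)
        out = agreement_stats(d, np.zeros_like(d))
        n = d.size
        lhs = out["rmse"] ** 2
        rhs = out["mean_error"] ** 2 + out["sd"] ** 2 * (n - 1) / n
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(UndefinedStatisticError):
            agreement_stats([1.0], [2.0])


class TestIccA1:
    def test_duplicated_column_perfect_agreement(self):
        a = np.array([1.0, 2, 3, 4, 5])
        icc, _ = icc_a1(np.column_stack([a, a]))
        assert icc == pytest.approx(1.0)

    def test_constant_bias_penalized_below_pearson(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a + 5
        icc, _ = icc_a1(np.column_stack([a, b]))
        r, _ = pearson(a, b)
        assert r == pytest.approx(1.0)
        assert icc < r

    def test_matches_brute_force_anova_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.integers(0, 10, size=(6, 2)).astype(float)
            m[:, 1] += rng.normal(0, 0.5, 6)  # avoid exact degeneracy
            icc, _ = icc_a1(m)
            assert icc == pytest.approx(brute_force_icc_a1(m), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        truth = rng.normal(90, 3, size=30)
        m = np.column_stack([truth + rng.normal(0, 1, 30),
                             truth + rng.normal(0, 1, 30)])
        icc, ci = icc_a1(m)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(30), 2),
            "rater": np.tile([0, 1], 30),
            "score": m.reshape(-1),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in ref.index else "ICC2"
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert icc == pytest.approx(ref.loc[key, "ICC"], abs=1e-10)
        lo, hi = ref.loc[key, ci_col]
        assert ci[0] == pytest.approx(lo, abs=5e-3)
        assert ci[1] == pytest.approx(hi, abs=5e-3)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_a1(np.ones((5, 2)))

    def test_symmetric_and_shift_invariant(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(12, 2))
        icc1, _ = icc_a1(m)
        icc2, _ = icc_a1(m[:, ::-1])
        icc3, _ = icc_a1(m + 7.5)
        assert icc1 == pytest.approx(icc2, abs=1e-12)
        assert icc1 == pytest.approx(icc3, abs=1e-9)

    def test_simulated_raters_match_variance_components(self):
        """truth ~ N(90, 3^2), two sources add independent N(0,1) noise:
        ICC converges to 9/(9+1) = 0.9."""
        rng = np.random.default_rng(42)
        truth = rng.normal(90, 3, size=500)
        m = np.column_stack([truth + rng.normal(0, 1, 500),
                             truth + rng.normal(0, 1, 500)])
        icc, _ = icc_a1(m)
        assert icc == pytest.approx(0.9, abs=0.02)


class TestPearson:
    def test_exact_linear_relation(self):
        a = np.array([1.0, 2, 3, 4])
        r, p = pearson(a, 2 * a + 1)
        assert r == pytest.approx(1.0)

    def test_hand_summation_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 1, 4, 3])
        sa, sb = a - a.mean(), b - b.mean()
        r_oracle = (sa * sb).sum() / np.sqrt((sa**2).sum() * (sb**2).sum())
        r, p = pearson(a, b)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        t = r * np.sqrt((4 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 2), abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson(np.ones(5), np.arange(5.0))


class TestReliabilityReport:
    def _tables(self, n=20, seed=0, drop=None):
        rng = np.random.default_rng(seed)
        params = ["mMPTA", "mLDFA", "mFAmTA", "mLDTA", "FSAmTA"]
        truth = rng.normal(90, 3, size=(n, 5))
        a = pd.DataFrame(truth + rng.normal(0, 1, (n, 5)), columns=params)
        b = pd.DataFrame(truth + rng.normal(0, 1, (n, 5)), columns=params)
        if drop:
            b.loc[drop[0], drop[1]] = np.nan
        return RaterTable(a), RaterTable(b)

    def test_oracle_identity_gives_perfect_rows(self):
        ta, _ = self._tables()
        rows = reliability_report(ta, RaterTable(ta.values.copy()))
        assert len(rows) == 5
        for r in rows:
            assert r.icc == pytest.approx(1.0, abs=1e-9)
            assert r.rmse == pytest.approx(0.0, abs=1e-9)

    def test_pairwise_deletion_changes_n_for_one_parameter(self):
        ta, tb = self._tables(drop=(3, "mLDTA"))
        rows = {r.parameter: r for r in reliability_report(ta, tb)}
        assert rows["mLDTA"].n == 19
        assert rows["mMPTA"].n == 20

    def test_result_invariants(self):
        ta, tb = self._tables(seed=3)
        for r in reliability_report(ta, tb):
            assert -1 <= r.icc <= 1
            assert r.rmse >= abs(r.mean_error) - 1e-12
            assert r.icc_ci[0] <= r.icc <= r.icc_ci[1]
            assert r.mean_error_ci[0] <= r.mean_error <= r.mean_error_ci[1]

    def test_no_overlap_rejected(self):
        ta, tb = self._tables()
        tb.values.index = tb.values.index + 1000
        with pytest.raises(UndefinedStatisticError):
            reliability_report(ta, tb)


# Published inter-rater table rows (mean error, SD, n, printed RMSE) whose
# RMSE should be reconstructible from the other two columns at printed
# precision under either SD convention.
PRINTED_ROWS = [
    ("human-human mFAmTA", 0.09, 1.11, 95, 1.11, 2),
    ("human-human FSAmTA", 0.10, 1.03, 95, 1.03, 2),
    ("human-AI mLDTA (a)", 0.97, 1.98, 94, 2.2, 1),
    ("human-AI mLDTA (b)", 0.49, 1.38, 94, 1.46, 2),
]


class TestPrintedTableIdentity:
    @pytest.mark.parametrize("label,me,sd,n,printed,dec", PRINTED_ROWS)
    def test_rmse_reconstructs_printed_cell(self, label, me, sd, n, printed, dec):
        tol = 0.5 * 10 ** (-dec)
        assert abs(rmse_identity(me, sd) - printed) <= tol + 1e-12
        assert abs(rmse_identity(me, sd, n) - printed) <= tol + 1e-12
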