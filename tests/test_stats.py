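"""Wilson intervals, frequency tables and catalogue summaries."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from carrierscreen import (
    ValidationError,
    frequency_table,
    run_pipeline,
    summarize_catalogue,
    wilson_ci,
)

Z95 = 1.96


def score_residual(p, phat, N, z=Z95):
    """(phat - p)^2 - z^2 p(1-p)/N: zero exactly at the Wilson endpoints."""
    return (phat - p) ** 2 - z * z * p * (1 - p) / N


def bisect_endpoint(n, N, lo, hi, z=Z95):
    """Root of the score equation bracketed in (lo, hi)."""
    phat = n / N
    f = lambda p: score_residual(p, phat, N, z)
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


class TestWilson:
    @pytest.mark.parametrize(
        "n, N, lower, upper",
        [
            (9, 200, 0.0239, 0.0833),
            (1, 200, 0.00088, 0.0277),
        ],
    )
    def test_small_count_examples(self, n, N, lower, upper):
        lo, hi = wilson_ci(n, N)
        assert lo == pytest.approx(lower, abs=5e-4)
        assert hi == pytest.approx(upper, abs=5e-4)

    def test_zero_count_clamps_lower_to_zero(self):
        lo, hi = wilson_ci(0, 50)
        assert lo == 0.0 and 0 < hi < 1

    def test_full_count_clamps_upper_to_one(self):
        lo, hi = wilson_ci(50, 50)
        assert hi == 1.0 and 0 < lo < 1

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            wilson_ci(0, 0)
        with pytest.raises(ValidationError):
            wilson_ci(5, 4)
        with pytest.raises(ValidationError):
            wilson_ci(1, 10, conf=1.0)

    def test_score_equation_root_check(self):
        """Unclamped endpoints satisfy (phat-p)^2 = z^2 p(1-p)/N to 1e-10,
        and match bisection of the score statistic, for all 0<=n<=N<=50."""
        for N in range(1, 51):
            for n in range(N + 1):
                phat = n / N
                lo, hi = wilson_ci(n, N)
                if n > 0:
                    assert abs(score_residual(lo, phat, N)) < 1e-10
                    assert lo == pytest.approx(bisect_endpoint(n, N, 0.0, phat), abs=1e-9)
                else:
                    assert lo == 0.0
                if n < N:
                    assert abs(score_residual(hi, phat, N)) < 1e-10
                    # p = phat is itself a root when n = 0; bracket past it
                    lo_bracket = phat if n > 0 else 1e-12
                    assert hi == pytest.approx(bisect_endpoint(n, N, lo_bracket, 1.0), abs=1e-9)
                else:
                    assert hi == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(N=st.integers(1, 500), n_frac=st.floats(0, 1))
    def test_contains_point_estimate_and_nests(self, N, n_frac):
        n = round(n_frac * N)
        lo95, hi95 = wilson_ci(n, N, 0.95)
        lo99, hi99 = wilson_ci(n, N, 0.99)
        assert lo95 <= n / N <= hi95
        assert lo99 <= lo95 and hi99 >= hi95  # 99% interval contains 95%

    @settings(derandomize=True, max_examples=200)
    @given(N=st.integers(1, 500), n_frac=st.floats(0, 1))
    def test_mirror_symmetry(self, N, n_frac):
        n = round(n_frac * N)
        lo, hi = wilson_ci(n, N)
        lo_m, hi_m = wilson_ci(N - n, N)
        assert lo == pytest.approx(1 - hi_m, abs=1e-12)
        assert hi == pytest.approx(1 - lo_m, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(N=st.integers(1, 500), n_frac=st.floats(0, 1))
    def test_against_statsmodels(self, N, n_frac):
        """Independent cross-check; statsmodels uses the full-precision
        normal quantile where this package pins z=1.96 at 95%, so agreement
        is to ~1e-5."""
        n = round(n_frac * N)
        lo, hi = wilson_ci(n, N)
        sm_lo, sm_hi = proportion_confint(n, N, alpha=0.05, method="wilson")
        assert lo == pytest.approx(sm_lo, abs=2e-4)
        assert hi == pytest.approx(sm_hi, abs=2e-4)


@pytest.fixture(scope="module")
def run(ref):
    return run_pipeline(ref.panel, ref.catalogue, ref.individuals, ref.genotypes)


class TestFrequencyTable:
    def row(self, run, label):
        return next(f for f in run.frequencies if f.label == label)

    def test_cftr_row(self, run):
        f = self.row(run, "CFTR")
        assert f.n == 9
        assert f.pct == pytest.approx(4.5)
        assert f.one_in == pytest.approx(22.22, abs=5e-3)

    def test_gaa_row(self, run):
        f = self.row(run, "GAA")
        assert f.n == 3
        assert f.pct == pytest.approx(1.5)
        assert f.one_in == pytest.approx(66.67, abs=5e-3)

    def test_total_row_counts_distinct_individuals(self, run):
        total = self.row(run, "total")
        assert total.n == 52
        per_gene_sum = sum(f.n for f in run.frequencies if f.label != "total")
        assert per_gene_sum - total.n == 5  # the five double carriers

    def test_degenerate_cohort_of_one(self):
        from carrierscreen import CarrierCall

        call = CarrierCall("A", "CFTR", "Cystic fibrosis", ("v1",), "carrier")
        rows = frequency_table([call], cohort_size=1)
        assert rows[0].pct == 100.0 and rows[0].one_in == 1.0

    def test_invariant_bounds(self, run):
        for f in run.frequencies:
            assert 0 <= f.ci_lower_pct <= f.pct <= f.ci_upper_pct <= 100


class TestCatalogueSummary:
    def test_reference_summary(self, catalogue):
        s = summarize_catalogue(catalogue)
        assert s.distinct_variants == 47
        assert s.total_occurrences == 57
        assert s.kind_pct["missense"] == pytest.approx(72.34, abs=5e-3)
        assert s.novel_count == 3
        assert s.reported_subcontinent_pct == pytest.approx(100 * 13 / 44, abs=1e-9)
        assert sum(s.kind_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_catalogue(self):
        s = summarize_catalogue([])
        assert s.distinct_variants == 0 and s.total_occurrences == 0
        assert s.kind_pct == {} and s.reported_subcontinent_pct is None
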