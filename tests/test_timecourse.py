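"""Per-month summaries, Pearson correlation, phase regressions, switch rule."""

import math

import numpy as np
import pytest
from scipy import stats

from scallopsex import (
    CohortSummary,
    detect_switch,
    fit_phase_regression,
    pearson,
    summarize_cohort,
)
from scallopsex.errors import InsufficientDataError, ValidationError


def pearson_oracle(x, y):
    """Direct covariance/SD Sigma-formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x * x).sum() - x.sum() ** 2 / n
    syy = (y * y).sum() - y.sum() ** 2 / n
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * stats.t.sf(abs(t), n - 2)


class TestPearson:
    def test_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, [-2 * v + 5 for v in x])[0] == pytest.approx(-1.0)

    def test_matches_sigma_formula_oracle(self):
        x = [1.2, 3.4, 2.2, 5.1, 4.0]
        y = [0.9, 2.8, 2.5, 4.9, 3.1]
        r, p = pearson(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_zero_variance_is_missing(self):
        r, p = pearson([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            pearson([1, 2], [3, 4])


class TestSummarizeCohort:
    def make(self, calls):
        n = len(calls)
        x = np.linspace(0, 1, n)
        return summarize_cohort(7, calls, x, x + 1)

    @pytest.mark.parametrize(
        "calls, rate",
        [
            (["undifferentiated"] * 8, 0.0),
            (["female"] * 4 + ["male"] * 4, 1.0),
            (["undifferentiated"] * 5 + ["female", "female", "male"], 0.375),
        ],
    )
    def test_differentiation_rate(self, calls, rate):
        assert self.make(calls).differentiation_rate == pytest.approx(rate)

    def test_intermediate_counts_as_not_yet_differentiated(self):
        s = self.make(["female", "intermediate", "undifferentiated", "male"])
        assert s.differentiation_rate == pytest.approx(0.5)
        assert s.n == 4

    def test_counts_exclude_missing(self):
        s = self.make(["female", "missing", "male"])
        assert s.n == 2 and s.n_missing == 1
        assert s.differentiation_rate == pytest.approx(1.0)

    def test_rate_monotone_when_undiff_flips_to_sexed(self):
        base = ["undifferentiated"] * 6 + ["female", "male"]
        flipped = ["female"] + base[1:]
        assert self.make(flipped).differentiation_rate >= self.make(base).differentiation_rate

    def test_empty_cohort_errors(self):
        with pytest.raises(ValidationError):
            summarize_cohort(5, [], [], [])

    def test_fewer_than_three_pairs_gives_missing_r(self):
        s = summarize_cohort(5, ["undifferentiated"] * 2, [0.1, 0.2], [0.3, 0.4])
        assert math.isnan(s.pearson_r)


class TestPhaseRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_phase_regression(x, x, "undifferentiated")
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_ols_matches_normal_equations(self):
        x = np.array([0.1, 0.9, 1.7, 2.2, 3.3, 4.1])
        y = np.array([1.0, 2.1, 2.9, 3.5, 4.9, 5.4])
        fit = fit_phase_regression(x, y, "differentiated")
        slope0 = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope0, abs=1e-12)
        assert fit.intercept == pytest.approx(y.mean() - slope0 * x.mean(), abs=1e-12)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValidationError):
            fit_phase_regression([1, 1, 1], [1, 2, 3], "undifferentiated")


def summaries_from_rs(rs, n=8):
    out = []
    for month, r in enumerate(rs, start=5):
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
        out.append(
            CohortSummary(month, n, n, 0, 0, 0, 0, 0.0, r, p)
        )
    return out


class TestDetectSwitch:
    def test_locates_switch_between_positive_regime_and_first_nonpositive(self):
        rs = [0.96, 0.98, 0.86, 0.1, -0.59, -0.79, -0.9, -0.96]
        report = detect_switch(summaries_from_rs(rs))
        assert report["switch_detected"]
        assert report["last_positive_month"] == 7  # 3rd entry (months start at 5)
        assert report["first_nonpositive_month"] == 9  # 5th entry

    def test_all_positive_sequence(self):
        report = detect_switch(summaries_from_rs([0.9, 0.95, 0.92]))
        assert not report["switch_detected"]
        assert report["note"] == "no switch detected"

    def test_single_month_errors(self):
        with pytest.raises(InsufficientDataError):
            detect_switch(summaries_from_rs([0.9]))
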