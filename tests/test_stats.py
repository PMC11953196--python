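import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from macuhole.index import score_table
from macuhole.stats import (
    StatsReport,
    build_report,
    concordance,
    describe,
    jarque_bera,
    spearman,
    univariate_regression,
    wilcoxon_change_test,
)


# --- independent oracles used by several tests ------------------------------


def brute_spearman_rho(x, y):
    """Pearson correlation of average ranks, written out long-hand."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def brute_ccc(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def ranksum_exact_p(a, b):
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(a)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = (n * (len(pooled) + 1)) / 2.0
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


class TestDescribe:
    def test_odd_symmetric(self):
        d = describe([1, 2, 3, 4, 5])
        assert (d.median, d.q1, d.q3, d.min, d.max) == (3, 2, 4, 1, 5)

    def test_constant_vector(self):
        d = describe([1, 1, 1, 1])
        assert d.median == d.q1 == d.q3 == d.min == d.max == 1

    def test_interpolated_quartiles(self):
        d = describe([1, 2, 3, 4])
        assert d.q1 == pytest.approx(1.75)
        assert d.q3 == pytest.approx(3.25)

    def test_missing_dropped(self):
        d = describe([1.0, float("nan"), 3.0])
        assert d.n_nonmissing == 2
        assert d.median == 2.0

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            describe([float("nan")])

    def test_quartile_ordering_invariant(self, rng):
        for _ in range(50):
            d = describe(rng.normal(size=rng.integers(1, 40)))
            assert d.min <= d.q1 <= d.median <= d.q3 <= d.max


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]).rho == pytest.approx(1.0)

    def test_antitone(self):
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_four_pairs(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.rho == pytest.approx(0.6)
        assert res.n_used == 4

    def test_matches_brute_force_small_vectors(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 11))
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=n).tolist()
            assert spearman(x, y).rho == pytest.approx(
                brute_spearman_rho(x, y), abs=1e-12
            )

    def test_listwise_deletion_leaves_complete_pairs_alone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        base = spearman(x, y)
        with_missing = spearman(x + [6.0, float("nan")], y + [float("nan"), 7.0])
        assert with_missing.rho == pytest.approx(base.rho)
        assert with_missing.n_used == base.n_used

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="complete pairs"):
            spearman([1, 2, 3], [4, 5, 6])

    def test_zero_rank_variance(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=25, deadline=None)
    @given(x=st.lists(st.integers(-50, 50), min_size=10, max_size=20, unique=True),
           data=st.data())
    def test_monotone_transform_invariance(self, x, data):
        y = data.draw(st.lists(st.integers(-50, 50), min_size=len(x), max_size=len(x),
                               unique=True))
        base = spearman(x, y)
        transformed = spearman([math.exp(v / 25.0) for v in x], y)
        assert transformed.rho == pytest.approx(base.rho, abs=1e-12)

    def test_exact_p_matches_t_approx_direction(self):
        # small-n exact p: perfectly monotone 5 pairs -> p = 2/5! exactly... the
        # two-sided enumeration counts both extreme orderings
        res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2.0 / math.factorial(5))


class TestWilcoxon:
    def test_exact_p_three_vs_three(self):
        res = wilcoxon_change_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_swap_symmetry(self, rng):
        a = rng.normal(size=8).tolist()
        b = rng.normal(size=9).tolist()
        assert wilcoxon_change_test(a, b).p_value == pytest.approx(
            wilcoxon_change_test(b, a).p_value
        )

    def test_matches_enumeration_oracle_all_small_sizes(self, rng):
        for n, m in itertools.product(range(3, 7), range(3, 7)):
            vals = rng.permutation(np.arange(1.0, n + m + 1.0))
            a, b = vals[:n].tolist(), vals[n:].tolist()
            res = wilcoxon_change_test(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(ranksum_exact_p(a, b), abs=1e-12)

    def test_signed_rank_all_zero_differences(self):
        with pytest.raises(ValueError, match="nonzero"):
            wilcoxon_change_test([1, 2, 3, 4], [1, 2, 3, 4], mode="signed-rank")

    def test_signed_rank_runs(self):
        res = wilcoxon_change_test([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], mode="signed-rank")
        assert res.mode == "signed-rank"
        assert 0 < res.p_value <= 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_change_test([], [1, 2, 3])

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown mode"):
            wilcoxon_change_test([1, 2, 3], [4, 5, 6], mode="bogus")


class TestJarqueBera:
    def test_hand_computed_small_sample(self):
        # n=5, S=0, K=1.7 -> JB = 5/6 * (1.3^2 / 4)
        res = jarque_bera([1, 2, 3, 4, 5])
        assert res.skewness == pytest.approx(0.0, abs=1e-12)
        assert res.kurtosis == pytest.approx(1.7)
        assert res.statistic == pytest.approx(5.0 / 6.0 * (1.3**2 / 4.0))

    def test_symmetric_two_point_sample(self):
        res = jarque_bera([-1, -1, -1, -1, 1, 1, 1, 1])
        assert res.skewness == 0.0

    def test_matches_scipy(self, rng):
        x = rng.normal(size=200)
        ours = jarque_bera(x)
        theirs = sps.jarque_bera(x)
        assert ours.statistic == pytest.approx(theirs.statistic)
        assert ours.p_value == pytest.approx(theirs.pvalue)

    def test_level_on_normal_samples(self):
        hits = sum(
            jarque_bera(np.random.default_rng(seed).standard_normal(5000)).p_value > 0.05
            for seed in range(100)
        )
        assert hits >= 95

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            jarque_bera([2.0] * 10)


class TestRegression:
    def test_perfect_fit(self):
        x = [0, 1, 2, 3, 4]
        res = univariate_regression(x, [2 * v + 1 for v in x])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_flat_response(self):
        res = univariate_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert res.slope == pytest.approx(0.0)

    def test_closed_form_four_points(self):
        res = univariate_regression([0, 1, 2, 3], [1, 2, 2, 4])
        assert res.slope == pytest.approx(0.9)
        assert res.intercept == pytest.approx(0.9)

    def test_constant_predictor(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_regression([2, 2, 2, 2], [1, 2, 3, 4])

    def test_adjusted_r2_below_r2(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = x + rng.normal(size=15)
            res = univariate_regression(x, y)
            assert res.adjusted_r2 <= res.r_squared
            if res.r_squared < 1.0:
                assert res.adjusted_r2 < res.r_squared


class TestConcordance:
    def test_identical_vectors(self):
        res = concordance([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.ccc == pytest.approx(1.0)
        assert res.ci_low <= res.ccc <= res.ci_high

    def test_shift_by_one(self):
        # hand evaluation of Lin's formula with population moments
        res = concordance([1, 2, 3], [2, 3, 4])
        assert res.ccc == pytest.approx(4.0 / 7.0)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 11))
            x = rng.normal(size=n).tolist()
            y = rng.normal(size=n).tolist()
            assert concordance(x, y).ccc == pytest.approx(brute_ccc(x, y), abs=1e-12)

    def test_scale_bias_penalized(self, rng):
        x = rng.normal(loc=5.0, size=30)
        y = 2.0 * x
        res = concordance(x, y)
        r = sps.pearsonr(x, y).statistic
        assert res.ccc < r

    def test_ccc_never_exceeds_pearson(self, rng):
        for _ in range(30):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            r = sps.pearsonr(x, y).statistic
            assert abs(concordance(x, y).ccc) <= abs(r) + 1e-12

    def test_ci_brackets_estimate(self, rng):
        for _ in range(20):
            x = rng.normal(size=25)
            y = x + rng.normal(scale=0.3, size=25)
            res = concordance(x, y)
            assert res.ci_low <= res.ccc <= res.ci_high

    def test_zero_variance_both(self):
        with pytest.raises(ValueError):
            concordance([1, 1, 1], [2, 2, 2])


class TestBuildReport:
    def test_full_report_blocks(self, default_cohort_38):
        scored, _ = score_table(default_cohort_38)
        report = build_report(scored)
        assert report.n_eyes == 38
        assert "piin" in report.descriptives
        assert "minimum_diameter_um" in report.correlations
        assert "bcva_logmar" in report.change_tests
        assert report.regression is not None
        assert report.concordance is not None
        assert set(report.concordance) == {"la_mm2", "pra_mm2", "ta_mm2"}

    def test_missing_required_columns_listed(self):
        with pytest.raises(KeyError, match="piin"):
            build_report(pd.DataFrame({"la_mm2": [0.1, 0.2]}))

    def test_grader_block_conditional(self, default_cohort_38):
        scored, _ = score_table(
            default_cohort_38.drop(columns=["grader2_la_mm2", "grader2_ta_mm2"])
        )
        report = build_report(scored)
        assert report.concordance is None

    def test_json_round_trip(self, default_cohort_38):
        scored, _ = score_table(default_cohort_38)
        report = build_report(scored)
        text = report.to_json()
        restored = StatsReport.from_json(text)
        assert restored.to_json() == text
        assert json.loads(text)["n_eyes"] == 38

    def test_correlation_block_against_scipy(self, default_cohort_38):
        scored, _ = score_table(default_cohort_38)
        report = build_report(scored)
        ref = sps.spearmanr(scored["piin"], scored["ta_mm2"]).statistic
        assert report.correlations["ta_mm2"]["rho"] == pytest.approx(ref)

    def test_text_rendering_mentions_significance(self, default_cohort_38):
        scored, _ = score_table(default_cohort_38)
        text = build_report(scored).to_text()
        assert "Index correlations" in text
        assert "Intergrader agreement" in text
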