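import math

import numpy as np
import pandas as pd
import pytest

from utilicit import datasets
from utilicit.analysis import (
    AnalysisError,
    comparison_table,
    demographic_correlations,
    lowess_fit,
    mean_ci,
    rank_concordance,
    rank_states,
    round_half_up,
    spearman,
    summarize,
    summary_table,
    wilcoxon_rank_sum,
)

# low-to-high orderings implied by the published per-state means
SG_ORDER = [18, 17, 14, 15, 10, 4, 9, 3, 5, 16, 2, 1, 11, 6, 7, 8, 13, 12]
RS_ORDER = [18, 17, 14, 15, 10, 9, 4, 16, 5, 2, 3, 8, 7, 6, 11, 1, 13, 12]


# ---------------------------------------------------------------- oracles

def quantile_oracle(values, q):
    """Sort-and-interpolate quantile, written independently of numpy."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank with midranks, then plain Pearson on the ranks."""
    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


# ---------------------------------------------------------------- summarize

class TestSummarize:
    def test_constant_sample(self):
        s = summarize([0.5, 0.5, 0.5])
        assert (s.mean, s.sd) == (0.5, 0.0)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 0.5

    def test_symmetric_grid(self):
        s = summarize([0, 0.25, 0.5, 0.75, 1])
        assert (s.q1, s.median, s.q3) == (0.25, 0.5, 0.75)

    def test_matches_bruteforce_oracle_on_random_vector(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(size=47)
        s = summarize(v)
        assert s.median == pytest.approx(quantile_oracle(v, 0.5), abs=1e-12)
        assert s.q1 == pytest.approx(quantile_oracle(v, 0.25), abs=1e-12)
        assert s.q3 == pytest.approx(quantile_oracle(v, 0.75), abs=1e-12)
        assert s.sd == pytest.approx(math.sqrt(sum((x - v.mean()) ** 2 for x in v) / 46), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(AnalysisError):
            summarize([])


# ---------------------------------------------------------------- ranking

class TestRanking:
    def test_published_sg_ordering(self, sg_means):
        assert rank_states(sg_means) == SG_ORDER

    def test_published_rs_ordering(self, rs_means):
        assert rank_states(rs_means) == RS_ORDER

    def test_ties_break_by_state_id(self):
        assert rank_states({s: 0.5 for s in range(1, 19)}) == list(range(1, 19))

    def test_concordance_of_published_orderings(self, sg_means, rs_means):
        c = rank_concordance(rank_states(sg_means), rank_states(rs_means))
        assert c.n_same_position == 9
        assert c.common_prefix_len == 5  # the five worst states agree
        assert c.common_suffix_len == 2  # the two best states agree

    def test_identical_orders_fully_concordant(self):
        c = rank_concordance(SG_ORDER, SG_ORDER)
        assert (c.n_same_position, c.common_prefix_len, c.common_suffix_len) == (18, 18, 18)

    def test_reversed_even_order_has_no_fixed_point(self):
        c = rank_concordance(SG_ORDER, SG_ORDER[::-1])
        assert c.n_same_position == 0

    def test_different_id_sets_rejected(self):
        with pytest.raises(AnalysisError):
            rank_concordance([1, 2, 3], [1, 2, 4])


# ---------------------------------------------------------------- CIs

class TestMeanCI:
    def test_reproduces_published_first_month_interval(self):
        low, high = mean_ci(0.902, 0.203, 47)
        assert (round_half_up(low, 2), round_half_up(high, 2)) == (0.84, 0.96)

    def test_reproduces_published_palliative_interval(self):
        low, high = mean_ci(0.213, 0.336, 47)
        assert (round_half_up(low, 2), round_half_up(high, 2)) == (0.12, 0.31)

    def test_degenerate_sd_collapses_interval(self):
        assert mean_ci(0.4, 0.0, 10) == (0.4, 0.4)

    def test_small_n_rejected(self):
        with pytest.raises(AnalysisError):
            mean_ci(0.5, 0.1, 1)


# ---------------------------------------------------------------- correlation & tests

class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.5, 7.0]
        rho, _ = spearman(x, [2.0, 4.0, 5.0, 9.0])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            x = rng.integers(0, 10, size=12).astype(float)  # ties likely
            y = rng.uniform(size=12)
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            spearman([1, 2, 3], [1, 2])


class TestRankSum:
    def test_identical_samples_give_unit_p(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_tail(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        stat, p = wilcoxon_rank_sum(a, b)
        assert stat == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------- LOWESS

class TestLowess:
    def test_reproduces_a_line(self):
        x = np.linspace(0, 1, 30)
        y = 2.0 * x + 0.5
        assert np.allclose(lowess_fit(x, y), y, atol=1e-8)

    def test_constant_with_full_span(self):
        x = np.arange(10.0)
        fitted = lowess_fit(x, np.full(10, 0.7), span=1.0)
        assert np.allclose(fitted, 0.7, atol=1e-10)

    def test_robust_iterations_resist_an_outlier(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 40)
        y = x.copy()
        y[20] = 5.0  # gross outlier
        robust = lowess_fit(x, y, robust_iters=3)
        naive = lowess_fit(x, y, robust_iters=0)
        assert abs(robust[20] - x[20]) < abs(naive[20] - x[20])

    def test_invalid_span_rejected(self):
        with pytest.raises(AnalysisError):
            lowess_fit([0, 1], [0, 1], span=1.5)


# ---------------------------------------------------------------- tables

class TestTables:
    def test_summary_table_shape_and_invariants(self, small_run):
        catalog, respondents, records = small_run
        table = summary_table(records, catalog)
        assert len(table) == 36
        assert list(table["method"].unique()) == ["SG", "RS"]
        for _, r in table.iterrows():
            assert r["min"] <= r["q1"] <= r["median"] <= r["q3"] <= r["max"]
            assert 0.0 <= r["min"] and r["max"] <= 1.0
            assert r["sd"] >= 0.0

    def test_summary_table_requires_full_coverage(self, small_run):
        catalog, _, records = small_run
        partial = [r for r in records if r.state_id != 7]
        with pytest.raises(AnalysisError, match="state 7"):
            summary_table(partial, catalog)

    def test_comparison_table_against_published_fixture(self, reference_summary):
        table = comparison_table(reference_summary, n=47, comparator=datasets.load_comparator())
        row1 = table[table["state_id"] == 1].iloc[0]
        assert (row1["mean"], row1["ci_low"], row1["ci_high"]) == (0.90, 0.84, 0.96)
        assert (row1["comparator_mean"], row1["comparator_ci_low"]) == (0.95, 0.94)
        row18 = table[table["state_id"] == 18].iloc[0]
        assert (row18["mean"], row18["ci_low"], row18["ci_high"]) == (0.21, 0.12, 0.31)

    def test_comparator_gap_stays_na(self, reference_summary):
        table = comparison_table(reference_summary, n=47, comparator=datasets.load_comparator())
        row11 = table[table["state_id"] == 11].iloc[0]
        assert pd.isna(row11["comparator_mean"])
        assert (row11["mean"], row11["ci_low"], row11["ci_high"]) == (0.91, 0.85, 0.97)

    def test_demographic_correlations_cover_states_and_sex(self, small_run):
        catalog, respondents, records = small_run
        profiles = [r.profile for r in respondents]
        corr = demographic_correlations(records, profiles)
        age_rows = corr[corr["test"] == "spearman_age"]
        assert len(age_rows) == 36
        defined = age_rows["statistic"].dropna()  # NaN where a margin is constant
        assert ((defined >= -1) & (defined <= 1)).all()
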