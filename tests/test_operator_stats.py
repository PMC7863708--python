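import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kruskal, mannwhitneyu

from renogray import (
    DegenerateSampleError,
    InsufficientGroupsError,
    anderson_darling_normality,
    compare_physicians,
    kruskal_wallis,
    wilcoxon_rank_sum,
)
from renogray.operator_stats import _mann_whitney_null


class TestAndersonDarling:
    def test_matches_r_nortest_frozen_oracle(self):
        # Samples regenerated from the recorded stream; reference p-values
        # computed once with R nortest::ad.test on the same numbers.
        rng = np.random.default_rng(42)
        x = np.round(rng.normal(50, 10, 60), 6)
        y = np.round(rng.uniform(0, 100, 60), 6)
        a_x, p_x = anderson_darling_normality(x)
        a_y, p_y = anderson_darling_normality(y)
        assert p_x == pytest.approx(0.7704729201, abs=1e-8)
        assert p_y == pytest.approx(0.1637889949, abs=1e-8)
        # the returned statistic is the small-sample-corrected A2*
        n = 60
        corr = 1 + 0.75 / n + 2.25 / n**2
        assert a_x / corr == pytest.approx(0.2388536415, abs=1e-8)

    def test_type_one_error_on_normal_draws(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            anderson_darling_normality(rng.normal(size=5000))[1] < 0.05
            for _ in range(100)
        )
        assert rejections <= 10  # p > 0.05 in >= 90% of repetitions

    def test_power_against_uniform(self):
        rng = np.random.default_rng(8)
        _, p = anderson_darling_normality(rng.uniform(size=5000))
        assert p < 0.05

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateSampleError):
            anderson_darling_normality([1.0] * 20)
        with pytest.raises(DegenerateSampleError):
            anderson_darling_normality([1, 2, 3])


class TestKruskalWallis:
    def test_identical_groups_give_h_zero(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert df == 2
        # perfectly balanced ranks: H = 0, p = 1
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_constant_defined_as_null(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_two_untied_groups_hand_computed(self):
        # ranks 1..6, R1=6, R2=15: H = 12/42*(36/3+225/3) - 21 = 27/7
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7, abs=1e-12)
        assert df == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [
            np.round(rng.normal(loc, 1.0, size=rng.integers(5, 40)), 1)
            for loc in (0.0, 0.3, 0.8)
        ]
        h, df, p = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_needs_two_groups(self):
        with pytest.raises(InsufficientGroupsError):
            kruskal_wallis([[1, 2, 3]])


def _enumerate_rank_sum_p(a, b):
    """Full-enumeration two-sided exact p for untied samples."""
    pooled = sorted(a) + sorted(b)
    assert len(set(pooled)) == len(pooled)
    n1, n = len(a), len(a) + len(b)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    center = n1 * (n - n1) / 2
    dev = abs(u_obs - center)
    total = hits = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        total += 1
        hits += abs(u - center) >= dev - 1e-12
    return hits / total


class TestWilcoxonRankSum:
    def test_identical_samples_p_one(self):
        w, p = wilcoxon_rank_sum([3, 1, 2], [1, 2, 3])
        assert p == 1.0

    def test_most_extreme_small_case(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
        pooled = rng.permutation(100)[: n1 + n2]  # distinct -> no ties
        a, b = pooled[:n1].tolist(), pooled[n1:].tolist()
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_enumerate_rank_sum_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.permutation(1000)[:15].tolist()
        b = rng.permutation(1000)[500:515].tolist()
        if set(a) & set(b):
            a = [x + 0.5 for x in a]
        _, p = wilcoxon_rank_sum(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_large_sample_approximation_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = np.round(rng.normal(0, 1, 60), 1)  # rounding induces ties
        b = np.round(rng.normal(0.4, 1, 55), 1)
        _, p = wilcoxon_rank_sum(a, b)
        ref = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_null_distribution_total_count(self):
        counts = _mann_whitney_null(4, 5)
        assert counts.sum() == math.comb(9, 4)
        assert np.array_equal(counts, counts[::-1])  # symmetry of U

    def test_kw_two_groups_agrees_with_rank_sum(self):
        rng = np.random.default_rng(3)
        a = rng.permutation(10_000)[:50].astype(float)
        b = rng.permutation(10_000)[5000:5050].astype(float)
        _, _, p_kw = kruskal_wallis([a, b])
        # compare against the rank-sum normal approximation (force it via
        # sample size > 25)
        _, p_w = wilcoxon_rank_sum(a, b)
        assert abs(p_kw - p_w) < 0.01


def _null_table(rng, n_per=40, physicians=("doc1", "doc2", "doc3")):
    rows = []
    for doc in physicians:
        for _ in range(n_per):
            pcts = rng.dirichlet(np.ones(14)) * 100
            row = {
                "category": "random",
                "physician_id": doc,
                "device_id": "devA",
                "gsm": rng.normal(90, 10),
            }
            row.update({f"band_{i:02d}": pcts[i - 1] for i in range(1, 15)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestComparePhysicians:
    def test_null_table_flag_fraction_near_alpha(self):
        rng = np.random.default_rng(11)
        flags = []
        for _ in range(12):
            report = compare_physicians(_null_table(rng), "random")
            flags.extend(report.pairwise["significant"].tolist())
        frac = np.mean(flags)
        assert 0.01 <= frac <= 0.10  # ~ alpha = 0.05

    def test_shifted_physician_flagged_on_gsm(self):
        rng = np.random.default_rng(12)
        table = _null_table(rng, n_per=48)
        table.loc[table.physician_id == "doc2", "gsm"] += 30
        report = compare_physicians(table, "random")
        pw = report.pairwise
        gsm = pw[pw.variable == "gsm"]
        involving = gsm[(gsm.group_a == "doc2") | (gsm.group_b == "doc2")]
        assert involving["significant"].all()
        other = gsm[(gsm.group_a != "doc2") & (gsm.group_b != "doc2")]
        assert not other["significant"].any()
        counts = report.pair_significant_counts
        assert counts.loc[
            (counts.group_a == "doc1") & (counts.group_b == "doc2"), "gsm_significant"
        ].item()

    def test_report_shape_and_bookkeeping(self):
        rng = np.random.default_rng(13)
        report = compare_physicians(_null_table(rng, n_per=10), "random")
        assert len(report.kruskal) == 15  # GSM + 14 bands
        assert len(report.pairwise) == 15 * 3  # 3 physician pairs
        assert report.n_tests == 15 + 45
        assert ((report.pairwise.p >= 0) & (report.pairwise.p <= 1)).all()
        assert (
            report.pairwise.significant == (report.pairwise.p < report.alpha)
        ).all()

    def test_single_group_category_rejected(self):
        rng = np.random.default_rng(14)
        table = _null_table(rng, physicians=("solo",))
        with pytest.raises(InsufficientGroupsError):
            compare_physicians(table, "random")
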