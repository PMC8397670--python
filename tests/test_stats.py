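"""Rank statistics: tie-corrected Kruskal-Wallis, Holm policy, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sbrtbench.stats import (
    holm_adjust,
    kruskal_wallis,
    midranks,
    multiplicity_policy,
    summarize,
)


def brute_force_h(values, labels):
    """Direct evaluation of the tie-corrected rank formula (independent path)."""
    values = np.asarray(values, float)
    n = values.size
    ranks = scipy.stats.rankdata(values)  # midranks
    h = 0.0
    for g in set(labels):
        sel = np.array([lab == g for lab in labels])
        h += sel.sum() * (ranks[sel].mean() - (n + 1) / 2) ** 2
    h *= 12 / (n * (n + 1))
    _, t = np.unique(values, return_counts=True)
    c = 1 - ((t**3 - t).sum()) / (n**3 - n)
    return h / c if c > 0 else 0.0


class TestKruskalWallis:
    def test_separated_groups_match_rank_formula(self):
        vals = np.arange(1.0, 10.0)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(vals, groups)
        assert res.H == pytest.approx(7.2, abs=1e-12)  # hand: 12/90 * 3*(9+0+9)
        assert res.H == pytest.approx(brute_force_h(vals, groups), abs=1e-12)
        assert res.df == 2

    def test_identical_multisets_give_zero(self):
        vals = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = kruskal_wallis(vals, groups)
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0 or res.p == pytest.approx(1.0, abs=1e-9)

    def test_all_values_identical_convention(self):
        res = kruskal_wallis([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert res.H == 0.0
        assert res.p == 1.0

    def test_two_groups_matches_rank_sum_relation(self):
        # without ties, H for k=2 equals the squared standardized rank sum
        vals = np.array([3.1, 0.4, 9.2, 5.5, 7.7, 1.2, 6.3])
        groups = ["x"] * 3 + ["y"] * 4
        res = kruskal_wallis(vals, groups)
        ranks = scipy.stats.rankdata(vals)
        n1, n2, n = 3, 4, 7
        r1 = ranks[:3].sum()
        z2 = (r1 - n1 * (n + 1) / 2) ** 2 / (n1 * n2 * (n + 1) / 12)
        assert res.H == pytest.approx(z2, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        vals = rng.integers(0, 6, size=30).astype(float)  # heavy ties
        groups = np.repeat(["a", "b", "c"], 10)
        res = kruskal_wallis(vals, groups)
        ref = scipy.stats.kruskal(vals[:10], vals[10:20], vals[20:])
        assert res.H == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        vals = rng.random(18) * 50
        groups = np.repeat(["a", "b", "c"], 6)
        h1 = kruskal_wallis(vals, groups).H
        h2 = kruskal_wallis(np.exp(vals / 20), groups).H
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_exact_permutation_matches_enumeration_oracle(self):
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        groups = np.repeat(["a", "b", "c"], 3)
        res = kruskal_wallis(vals, groups, exact=True)
        # independent oracle: enumerate all labelled assignments directly
        count = total = 0
        for perm in set(itertools.permutations("aaabbbccc")):
            total += 1
            if brute_force_h(vals, list(perm)) >= res.H - 1e-12:
                count += 1
        assert total == 1680
        assert res.exact_p == pytest.approx(count / total, abs=0.005)

    def test_exact_refused_for_large_n(self):
        with pytest.raises(ValueError, match="N <= 12"):
            kruskal_wallis(np.arange(15.0), np.repeat(["a", "b", "c"], 5), exact=True)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])  # one group
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "b"])  # N < 3

    def test_midranks_average_ties(self):
        r = midranks(np.array([10.0, 20.0, 20.0, 30.0]))
        np.testing.assert_allclose(r, [1.0, 2.5, 2.5, 4.0])


class TestMultiplicity:
    def test_holm_hand_computed_values(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_primary_metric_never_adjusted(self):
        from sbrtbench.stats import KWResult

        results = {
            "primary": KWResult(H=5.0, df=2, p=0.02, group_ns=(5, 5, 5)),
            "m1": KWResult(H=4.0, df=2, p=0.01, group_ns=(5, 5, 5)),
            "m2": KWResult(H=3.0, df=2, p=0.02, group_ns=(5, 5, 5)),
            "m3": KWResult(H=2.0, df=2, p=0.04, group_ns=(5, 5, 5)),
        }
        out = multiplicity_policy(results, "primary")
        assert out["primary"].adjusted_p == pytest.approx(0.02)
        np.testing.assert_allclose(
            [out["m1"].adjusted_p, out["m2"].adjusted_p, out["m3"].adjusted_p],
            [0.03, 0.04, 0.04],
        )
        with pytest.raises(KeyError):
            multiplicity_policy(results, "absent")


class TestSummarize:
    def test_hand_computed_three_value_groups(self):
        df = pd.DataFrame(
            {
                "technique": ["a"] * 3 + ["b"] * 3,
                "m": [1.0, 5.0, 3.0, 10.0, 30.0, 20.0],
            }
        )
        out = summarize(df, "technique")
        assert out.loc[("m", "median"), "a"] == pytest.approx(3.0)
        assert out.loc[("m", "median"), "b"] == pytest.approx(20.0)
        assert out.loc[("m", "mean"), "a"] == pytest.approx(3.0)
        assert out.loc[("m", "std"), "a"] == pytest.approx(2.0)  # sample std

    def test_even_n_midpoint_median(self):
        df = pd.DataFrame({"g": ["a"] * 4, "m": [1.0, 2.0, 3.0, 10.0]})
        assert summarize(df, "g").loc[("m", "median"), "a"] == pytest.approx(2.5)

    def test_single_plan_group_std_absent(self):
        df = pd.DataFrame({"g": ["a", "b"], "m": [1.0, 2.0]})
        out = summarize(df, "g")
        assert np.isnan(out.loc[("m", "std"), "a"])
        assert out.loc[("m", "median"), "a"] == out.loc[("m", "mean"), "a"] == 1.0

    def test_permutation_invariant_within_groups(self, rng):
        vals = rng.random(12)
        df1 = pd.DataFrame({"g": np.repeat(["a", "b"], 6), "m": vals})
        shuffled = np.concatenate([rng.permutation(vals[:6]), rng.permutation(vals[6:])])
        df2 = pd.DataFrame({"g": np.repeat(["a", "b"], 6), "m": shuffled})
        pd.testing.assert_frame_equal(summarize(df1, "g"), summarize(df2, "g"))

    def test_unknown_group_key(self):
        with pytest.raises(KeyError):
            summarize(pd.DataFrame({"g": ["a"], "m": [1.0]}), "nope")
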