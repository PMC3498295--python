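"""Rank-test machinery against independent oracles, and assembled tables."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from forumnet.dyad_metrics import classify_dyads, compute_dyads
from forumnet.group_stats import (
    DegenerateDataError,
    bonferroni_adjust,
    build_dyad_comparison,
    build_forum_comparison,
    dunn_pairwise,
    kruskal_wallis,
    pairwise_kw,
    survivor_percentage,
)
from forumnet.network_builder import build_network
from forumnet.synthetic_forum import female_style, generate_corpus, generate_forums


# -- independent oracles -------------------------------------------------------


def midranks(values):
    """Rank with ties as midranks, by explicit position averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def kw_definitional(groups):
    """H from the definitional formula, written independently."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rbar = sum(ranks[start:start + len(g)]) / len(g)
        h += len(g) * rbar * rbar
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t ** 3 - t
    c = 1 - ties / (n ** 3 - n)
    return h / c


def kw_permutation_bracket(groups, h_obs):
    """Exact permutation tail probabilities over all label assignments.

    Returns (P(H > h_obs), P(H >= h_obs)).  The permutation distribution
    of H is discrete with large atoms at tiny N, so a continuous reference
    p-value is meaningfully compared against this bracket, not against
    either endpoint alone.
    """
    pooled = [x for g in groups for x in g]
    sizes = [len(g) for g in groups]
    idx = range(len(pooled))
    gt = ge = total = 0
    for first in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in first]
        if len(sizes) == 2:
            splits = [tuple(rest)]
        else:
            splits = itertools.combinations(rest, sizes[1])
        for second in splits:
            if len(sizes) == 2:
                assignment = [first, second]
            else:
                third = tuple(i for i in rest if i not in second)
                assignment = [first, second, third]
            perm_groups = [[pooled[i] for i in part] for part in assignment]
            total += 1
            h = kw_definitional(perm_groups)
            ge += h >= h_obs - 1e-12
            gt += h > h_obs + 1e-12
    return gt / total, ge / total


def bracket_distance(p: float, bracket: tuple[float, float]) -> float:
    lo, hi = bracket
    return max(0.0, lo - p, p - hi)


# -- Kruskal-Wallis ------------------------------------------------------------


class TestKruskalWallis:
    def test_symmetric_ranks_give_zero_statistic(self):
        res = kruskal_wallis([[1, 4], [2, 3]])
        assert res.mean_ranks == (2.5, 2.5)
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_no_tie_case_matches_definitional_formula_and_chi_square(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(kw_definitional(groups), abs=1e-12)
        assert res.p == pytest.approx(float(scipy.stats.chi2.sf(res.H, 1)), abs=1e-15)

    def test_tied_case_matches_midrank_oracle_and_permutation_brackets_p(self):
        groups = [[1, 1, 2], [2, 3, 3]]
        res = kruskal_wallis(groups)
        assert res.H == pytest.approx(kw_definitional(groups), abs=1e-12)
        assert bracket_distance(res.p, kw_permutation_bracket(groups, res.H)) < 0.1

    def test_small_samples_match_oracles_exhaustively(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 6)
            pooled = rng.integers(0, 6, size=n1 + n2)
            groups = [list(pooled[:n1]), list(pooled[n1:])]
            if len(set(map(int, pooled))) == 1:
                continue
            res = kruskal_wallis(groups)
            assert res.H == pytest.approx(kw_definitional(groups), abs=1e-10)
            assert bracket_distance(res.p, kw_permutation_bracket(groups, res.H)) < 0.1

    def test_matches_scipy_cross_check_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = [list(rng.integers(0, 8, size=rng.integers(3, 12))) for _ in range(3)]
            if len({x for g in groups for x in g}) == 1:
                continue
            res = kruskal_wallis(groups)
            ref = scipy.stats.kruskal(*groups)
            assert res.H == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_two_group_h_equals_squared_dunn_z_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            pooled = rng.permutation(rng.integers(4, 16))  # distinct values
            n1 = rng.integers(2, len(pooled) - 1)
            groups = [list(pooled[:n1]), list(pooled[n1:])]
            res = kruskal_wallis(groups)
            (cmp,) = dunn_pairwise(groups)
            assert res.H == pytest.approx(cmp.z ** 2, abs=1e-10)

    @given(
        data=st.lists(
            st.floats(min_value=0.5, max_value=50, allow_nan=False), min_size=6, max_size=24
        ),
        split=st.integers(min_value=2, max_value=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, data, split):
        k = min(split, len(data) - 2)
        groups = [data[i::k] for i in range(k)]
        if any(len(g) == 0 for g in groups) or len(set(data)) == 1:
            return
        res = kruskal_wallis(groups)
        res_log = kruskal_wallis([[math.log(x) for x in g] for g in groups])
        assert res_log.H == pytest.approx(res.H, abs=1e-10)

    def test_weighted_mean_rank_is_the_grand_mean_rank(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(size=7)), list(rng.normal(size=4)), list(rng.normal(size=9))]
        res = kruskal_wallis(groups)
        weighted = sum(n * r for n, r in zip(res.group_sizes, res.mean_ranks))
        assert weighted / res.n_total == pytest.approx((res.n_total + 1) / 2)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1, 1], [1, 1, 1]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


# -- Dunn pairwise -------------------------------------------------------------


def dunn_oracle(groups, i, j):
    """Independently coded Dunn z for one pair on the joint ranking."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = midranks(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    rbar = [
        sum(ranks[bounds[k]:bounds[k + 1]]) / len(groups[k]) for k in range(len(groups))
    ]
    ties = sum(
        pooled.count(v) ** 3 - pooled.count(v) for v in set(pooled)
    )
    s = n * (n + 1) / 12 - ties / (12 * (n - 1))
    se = math.sqrt(s * (1 / len(groups[i]) + 1 / len(groups[j])))
    return (rbar[i] - rbar[j]) / se


class TestDunn:
    def test_identical_groups_compare_as_null(self):
        (cmp,) = dunn_pairwise([[1, 2, 3], [1, 2, 3]])
        assert cmp.diff == pytest.approx(0.0)
        assert cmp.z == pytest.approx(0.0)
        assert cmp.p_raw == pytest.approx(1.0)

    def test_five_groups_give_ten_pairwise_rows(self):
        rng = np.random.default_rng(2)
        groups = [list(rng.normal(loc=i, size=6)) for i in range(5)]
        rows = dunn_pairwise(groups, labels=list("abcde"))
        assert len(rows) == 10
        assert all(r.p_adjusted == min(1.0, 10 * r.p_raw) for r in rows)

    def test_tied_small_groups_match_the_independent_formula(self):
        groups = [[1, 1, 2], [2, 2, 3], [3, 4, 4]]
        rows = dunn_pairwise(groups, labels=["g0", "g1", "g2"])
        pairs = {(r.group_i, r.group_j): r for r in rows}
        for (i, j), key in [((0, 1), ("g0", "g1")), ((0, 2), ("g0", "g2")), ((1, 2), ("g1", "g2"))]:
            z = dunn_oracle(groups, i, j)
            assert pairs[key].z == pytest.approx(z, abs=1e-10)
            assert pairs[key].p_raw == pytest.approx(
                2 * scipy.stats.norm.sf(abs(z)), abs=1e-10
            )

    def test_diff_is_antisymmetric_under_group_swap(self):
        groups = [[1, 5, 7], [2, 2, 9]]
        (fwd,) = dunn_pairwise(groups)
        (rev,) = dunn_pairwise(groups[::-1])
        assert fwd.diff == pytest.approx(-rev.diff)

    def test_pairwise_kw_variant_agrees_in_sign(self):
        rng = np.random.default_rng(8)
        groups = [list(rng.normal(0, 1, 10)), list(rng.normal(1.5, 1, 10))]
        (d,) = dunn_pairwise(groups)
        (k,) = pairwise_kw(groups)
        assert math.copysign(1, d.diff) == math.copysign(1, k.diff)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 10, 0.10), (0.5, 10, 1.0), (0.37, 1, 0.37)]
    )
    def test_multiplies_and_caps(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    @given(p=st.floats(min_value=0, max_value=1), m=st.integers(min_value=1, max_value=50))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases_and_stays_capped(self, p, m):
        adj = bonferroni_adjust(p, m)
        assert p <= adj <= 1.0

    def test_out_of_range_inputs_are_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)


class TestSurvivorPercentage:
    @pytest.mark.parametrize(
        "patients,survivors,expected",
        [(1453, 587, 28.8), (351, 54, 13.3)],
    )
    def test_reproduces_published_forum_percentages(self, patients, survivors, expected):
        assert round(survivor_percentage(patients, survivors), 1) == expected

    def test_no_survivors_is_zero_percent(self):
        assert survivor_percentage(25, 0) == 0.0

    def test_no_diagnosed_members_is_undefined(self):
        with pytest.raises(ValueError):
            survivor_percentage(0, 0)


# -- assembled tables ----------------------------------------------------------


class TestForumComparison:
    def test_single_pair_of_forums_gives_one_row(self):
        corpus = generate_forums(
            [female_style("f1", n_threads=40), female_style("f2", n_threads=40)], seed=3
        )
        table = build_forum_comparison(corpus, ["f1", "f2"], "breadth")
        assert len(table.pairwise) == 1
        assert table.omnibus.df == 1

    def test_identically_planted_forums_compare_as_null(self):
        # same config and same generator seed in both forums: the metric
        # distributions are identical, so the mean-rank diff is exactly 0
        cfg1, cfg2 = female_style("f1", n_threads=60), female_style("f2", n_threads=60)
        for seed in range(1, 6):
            a = generate_corpus(cfg1, seed)
            b = generate_corpus(cfg2, seed)
            corpus = type(a)(
                members=a.members + b.members,
                threads=a.threads + b.threads,
                posts=a.posts + b.posts,
            )
            table = build_forum_comparison(corpus, ["f1", "f2"], "breadth")
            (row,) = table.pairwise
            assert row.diff == pytest.approx(0.0, abs=1e-9)
            assert row.p_adjusted > 0.5


class TestDyadComparison:
    @staticmethod
    def _classified(seed, **cfg_over):
        cfg = female_style(**cfg_over)
        corpus = generate_corpus(cfg, seed)
        net = build_network(corpus, cfg.forum_name)
        dyads, _ = classify_dyads(compute_dyads(net), net, strict_groups=True)
        return dyads

    def test_single_group_forum_yields_na_cell(self):
        dyads = self._classified(1, n_threads=40)
        only_patients = [d for d in dyads if d.group is not None and d.group.value == "patient_dyad"]
        frame = build_dyad_comparison({"f": only_patients}, "duration")
        row = frame.iloc[0]
        assert np.isnan(row["diff"]) and np.isnan(row["p"])

    def test_identical_outcome_distributions_give_zero_diff(self):
        dyads = self._classified(2, n_threads=40)
        for d in dyads:
            d.last_date = d.first_date  # constant durations in both groups
        frame = build_dyad_comparison({"f": dyads}, "duration")
        assert np.isnan(frame.iloc[0]["diff"])  # degenerate -> NA

    def test_high_homophily_plants_highly_intimate_patient_enrichment(self):
        wins = 0
        for seed in range(1, 21):
            dyads = self._classified(seed, homophily=0.9)
            row = build_dyad_comparison(
                {"female_style": dyads}, "highly_intimate_indicator"
            ).iloc[0]
            wins += (not np.isnan(row["diff"])) and row["diff"] > 0
        assert wins >= 18
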