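"""Rank-sum and BH-FDR against enumeration oracles; partition comparisons."""

import itertools

import numpy as np
import pytest

from capstate.group_stats import (
    bh_fdr,
    compare_partition,
    find_prototypes,
    ranksum_compare,
)
from capstate.matching import MatchResult


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration (tie-free samples)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def bh_oracle(p, q):
    """Literal step-up procedure: largest i with p_(i) <= i q / m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = (np.arange(1, m + 1) * q) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.max(np.flatnonzero(below))
        reject[order[: cutoff + 1]] = True
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0), reject


class TestRankSum:
    def test_fully_separated_small_samples(self):
        w, p = ranksum_compare([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert np.isclose(p, 0.1)  # 2 / C(6,3) = 2/20

    def test_identical_samples_p_one(self):
        _, p = ranksum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isclose(p, 1.0)

    @pytest.mark.parametrize("n1,n2", [(3, 4), (5, 5), (4, 6)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + 0.5
        _, p = ranksum_compare(x, y)
        assert np.isclose(p, exact_ranksum_p(x, y), atol=1e-12)

    def test_type_one_error_rate(self, rng):
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            _, p = ranksum_compare(rng.normal(size=8), rng.normal(size=10))
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ranksum_compare([1.0], [2.0, 3.0])


class TestBH:
    def test_hand_example_all_rejected(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()  # largest i with p_(i) <= i*0.05/4 is i=4

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.03])
        assert adj[0] == 0.03

    def test_matches_step_up_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(size=rng.integers(1, 12))
            adj, rej = bh_fdr(p, q=0.05)
            adj_o, rej_o = bh_oracle(p, 0.05)
            assert np.allclose(adj, adj_o, atol=1e-12)
            assert np.array_equal(rej, rej_o)


def fake_match(pairs, retained=None):
    k = len(pairs)
    return MatchResult(
        pairs=list(pairs),
        pair_correlations=np.ones(k),
        total_distance=0.0,
        retained=None if retained is None else np.asarray(retained),
    )


def metric_tables(rng, n_subjects, k, occ_shift=0.0, shift_cap=0):
    tables = []
    for _ in range(n_subjects):
        occ = rng.dirichlet(np.ones(k) * 20)
        occ[shift_cap] += occ_shift
        occ = occ / occ.sum()
        tables.append(
            {
                "occurrence": occ,
                "duration": 5 + rng.normal(0, 0.5, size=k),
                "laterality_pos": rng.normal(0, 0.1, size=k),
                "laterality_neg": rng.normal(0, 0.1, size=k),
            }
        )
    return tables


class TestComparePartition:
    def test_zero_retained_pairs_empty_result(self, rng):
        match = fake_match([(0, 0), (1, 1)], retained=[False, False])
        out = compare_partition(
            metric_tables(rng, 4, 2), metric_tables(rng, 4, 2), match, 2
        )
        assert out == []

    def test_planted_occurrence_difference_flagged(self, rng):
        k = 4
        wt = metric_tables(rng, 8, k)
        tg = metric_tables(rng, 10, k, occ_shift=0.4, shift_cap=1)
        match = fake_match([(i, i) for i in range(k)])
        out = compare_partition(wt, tg, match, k)
        sig = {(c.pair, c.metric) for c in out if c.significant}
        assert ((1, 1), "occurrence") in sig
        # no other metric family lights up
        assert all(m == "occurrence" for (_, m) in sig)

    def test_invariant_to_subject_order(self, rng):
        k = 3
        wt = metric_tables(rng, 6, k)
        tg = metric_tables(rng, 6, k)
        match = fake_match([(i, i) for i in range(k)])
        a = compare_partition(wt, tg, match, k)
        b = compare_partition(wt[::-1], tg[::-1], match, k)
        assert [c.p_raw for c in a] == [c.p_raw for c in b]

    def test_identical_groups_rarely_significant(self, rng):
        n_sig = n_tot = 0
        for rep in range(5):
            k = 3
            wt = metric_tables(rng, 8, k)
            tg = metric_tables(rng, 10, k)
            out = compare_partition(wt, tg, fake_match([(i, i) for i in range(k)]), k)
            n_sig += sum(c.significant for c in out)
            n_tot += len(out)
        assert n_sig / n_tot <= 0.05


class TestQppIncidenceComparison:
    def test_matches_scipy_and_is_flagged(self, rng):
        from scipy import stats as sps

        from capstate.group_stats import compare_qpp_incidence

        x = rng.normal(10, 2, size=8)
        y = rng.normal(14, 2, size=10)
        t, p, flag = compare_qpp_incidence(x, y)
        ref = sps.ttest_ind(x, y)
        assert np.isclose(t, ref.statistic) and np.isclose(p, ref.pvalue)
        assert flag == "unpaired-t"

    def test_too_few_values_rejected(self):
        from capstate.group_stats import compare_qpp_incidence

        with pytest.raises(ValueError):
            compare_qpp_incidence([1.0], [2.0, 3.0])


class TestPrototypes:
    def test_all_similar_caps_form_one_prototype(self, rng):
        base = rng.normal(size=50)
        caps = [
            (k, 0, base + 0.05 * rng.normal(size=50)) for k in range(2, 9)
        ]
        groups = find_prototypes(caps, r_min=0.7)
        assert len(groups) == 1
        assert groups[0].n_partitions == 7

    def test_two_orthogonal_families(self, rng):
        a = np.zeros(40)
        a[:20] = 1.0
        b = np.zeros(40)
        b[20:] = 1.0
        caps = [(2, 0, a), (3, 0, a), (2, 1, b), (3, 1, b)]
        groups = find_prototypes(caps, r_min=0.7)
        assert len(groups) == 2
        assert all(g.n_partitions == 2 for g in groups)

    def test_each_cap_used_once(self, rng):
        caps = [(k, i, rng.normal(size=30)) for k in range(2, 6) for i in range(2)]
        groups = find_prototypes(caps, r_min=0.5)
        members = [m for g in groups for m in g.members]
        assert len(members) == len(set(members)) == len(caps)
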