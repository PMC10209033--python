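import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from aspmine.mining import Corpus
from aspmine.significance import (
    ContingencyTable,
    adjusted_pvalue,
    bonferroni_level,
    fet_pvalue,
    generate_permutations,
    hypergeom_g,
    pvalue_lower_bound,
    wy_calibrate,
    wy_calibrate_naive,
)

from conftest import random_dataset


def oracle_fet(n_pos, n_neg, d_all, d_pos):
    """Exhaustive doubled-tail hypergeometric p-value in exact rationals."""
    denom = math.comb(n_pos + n_neg, d_all)
    lo, hi = max(0, d_all - n_neg), min(n_pos, d_all)
    num = {a: math.comb(n_pos, a) * math.comb(n_neg, d_all - a) for a in range(lo, hi + 1)}
    tail = sum(v for v in num.values() if v <= num[d_pos])
    return float(min(Fraction(1), 2 * Fraction(tail, denom)))


@pytest.mark.parametrize(
    "args, expected",
    [((2, 2, 2, 2), 1 / 6), ((2, 2, 2, 1), 4 / 6), ((3, 3, 3, 4), 0.0), ((3, 3, 3, 0), 1 / 20)],
)
def test_hypergeometric_probability(args, expected):
    assert hypergeom_g(*args) == pytest.approx(expected, abs=1e-15)


def test_hypergeometric_domain_errors():
    with pytest.raises(ValueError):
        hypergeom_g(-1, 2, 1, 0)
    with pytest.raises(ValueError):
        hypergeom_g(2, 2, 5, 1)


@pytest.mark.parametrize(
    "table, expected",
    [
        ((2, 2, 2, 2), 2 / 3),
        ((3, 3, 3, 3), 0.2),
        ((2, 2, 4, 2), 1.0),  # single attainable table, doubled mass capped
    ],
)
def test_fet_pvalue_worked_examples(table, expected):
    assert fet_pvalue(ContingencyTable(*table)).p_value == pytest.approx(expected, abs=1e-15)


def test_fet_observed_table_always_in_tail():
    res = fet_pvalue(ContingencyTable(5, 7, 4, 3))
    assert 3 in [a for a, _ in res.tail_terms]
    assert res.p_value >= 2 * hypergeom_g(5, 7, 4, 3) - 1e-15 or res.p_value == 1.0


def test_fet_matches_exact_oracle_small_tables():
    for n_pos in range(0, 13):
        for n_neg in range(0, 13):
            if n_pos + n_neg == 0:
                continue
            for d_all in range(0, n_pos + n_neg + 1):
                for d_pos in range(max(0, d_all - n_neg), min(n_pos, d_all) + 1):
                    got = fet_pvalue(ContingencyTable(n_pos, n_neg, d_all, d_pos)).p_value
                    assert got == oracle_fet(n_pos, n_neg, d_all, d_pos)


def test_fet_float_path_agrees_with_exact_path():
    # n > 64 switches to log-gamma; cross-check against the rational oracle
    for d_all, d_pos in [(10, 9), (30, 20), (50, 5), (70, 35)]:
        got = fet_pvalue(ContingencyTable(40, 60, d_all, d_pos)).p_value
        assert got == pytest.approx(oracle_fet(40, 60, d_all, d_pos), rel=1e-10)


@given(
    st.integers(1, 20), st.integers(1, 20), st.integers(0, 40), st.data()
)
def test_fet_pvalue_is_probability(n_pos, n_neg, d_all, data):
    d_all = min(d_all, n_pos + n_neg)
    lo, hi = max(0, d_all - n_neg), min(n_pos, d_all)
    d_pos = data.draw(st.integers(lo, hi))
    p = fet_pvalue(ContingencyTable(n_pos, n_neg, d_all, d_pos)).p_value
    assert 0 < p <= 1


@pytest.mark.parametrize("args, expected", [((2, 2, 2), 1 / 6), ((3, 3, 3), 1 / 20)])
def test_lower_bound_worked_examples(args, expected):
    assert pvalue_lower_bound(*args) == pytest.approx(expected, abs=1e-15)


def test_lower_bound_holds_for_all_descendants():
    """Exhaustive check of the subtree bound: for every pattern and every
    rightward extension present in the data, under several label
    permutations, p_low(parent support) <= p(descendant)."""
    rng = np.random.default_rng(5)
    ds = random_dataset(rng, n_proteins=10, length_range=(8, 20), alphabet="ACDE")
    n_pos, n_neg = ds.n_pos, ds.n_neg
    all_subs = set()
    for rec in ds:
        s = rec.sequence
        all_subs.update(s[i:j] for i in range(len(s)) for j in range(i + 1, len(s) + 1))

    def support(pattern, labels):
        idx = [i for i, r in enumerate(ds) if pattern in r.sequence]
        d_pos = sum(1 for i in idx if labels[i] == 1)
        return len(idx), d_pos

    labels0 = ds.labels
    for perm_seed in range(3):
        labels = np.random.default_rng(perm_seed).permutation(labels0)
        p_cache = {}
        for q in all_subs:
            d_all, d_pos = support(q, labels)
            p_cache[q] = fet_pvalue(ContingencyTable(n_pos, n_neg, d_all, d_pos)).p_value
        for q in all_subs:
            d_all_q, _ = support(q, labels)
            bound = pvalue_lower_bound(n_pos, n_neg, d_all_q)
            for q2 in all_subs:
                if q2.startswith(q):
                    assert bound <= p_cache[q2] + 1e-12


def test_permutation_plan_preserves_class_sizes_and_seed():
    rng = np.random.default_rng(1)
    ds = random_dataset(rng, n_proteins=12)
    plan1 = generate_permutations(ds, 20, seed=9)
    plan2 = generate_permutations(ds, 20, seed=9)
    assert np.array_equal(plan1.label_matrix, plan2.label_matrix)
    assert np.all((plan1.label_matrix == 1).sum(axis=1) == ds.n_pos)
    plan3 = generate_permutations(ds, 20, seed=10)
    assert not np.array_equal(plan1.label_matrix, plan3.label_matrix)


def test_permutations_are_uniform_per_position():
    rng = np.random.default_rng(2)
    ds = random_dataset(rng, n_proteins=10)
    m = 10_000
    plan = generate_permutations(ds, m, seed=3)
    freq = (plan.label_matrix == 1).mean(axis=0)
    expect = ds.n_pos / ds.n
    sigma = math.sqrt(expect * (1 - expect) / m)
    assert np.all(np.abs(freq - expect) < 4 * sigma)


@pytest.mark.parametrize("prune_level", ["distribution", "quantile"])
def test_pruned_calibration_reproduces_naive(prune_level):
    """Soundness of branch-and-bound pruning on random datasets."""
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        ds = random_dataset(rng, n_proteins=int(rng.integers(8, 25)),
                            length_range=(5, 40), alphabet="ACDEFG")
        plan = generate_permutations(ds, 40, seed=seed)
        naive = wy_calibrate_naive(ds, plan, alpha=0.05)
        fast = wy_calibrate(ds, plan, alpha=0.05, prune_level=prune_level)
        assert fast.delta == naive.delta
        assert fast.fwer_estimate == naive.fwer_estimate
        if prune_level == "distribution":
            assert np.array_equal(fast.min_p, naive.min_p)
        else:  # quantile pruning still preserves every minimum below delta
            exact = naive.min_p < naive.delta
            assert np.array_equal(fast.min_p[exact], naive.min_p[exact])


def test_pruning_actually_prunes(planted_fixture):
    ds, _ = planted_fixture
    plan = generate_permutations(ds, 50, seed=0)
    cal = wy_calibrate(Corpus(ds), plan, alpha=0.05)
    assert cal.stats.subtrees_pruned > 0
    assert cal.stats.pruning_rate > 0


def test_delta_is_order_statistic_and_fwer_bounded():
    rng = np.random.default_rng(8)
    ds = random_dataset(rng, n_proteins=15, length_range=(10, 30))
    plan = generate_permutations(ds, 40, seed=2)
    cal = wy_calibrate(ds, plan, alpha=0.05)
    k = math.ceil(0.05 * 40)
    assert cal.k == k
    assert cal.delta == np.sort(cal.min_p)[k - 1]
    assert cal.fwer_estimate <= (k - 1) / 40 < 0.05


def test_adjusted_pvalue_order_statistics():
    cal = wy_calibrate_naive(
        random_dataset(np.random.default_rng(4), n_proteins=8),
        generate_permutations(random_dataset(np.random.default_rng(4), n_proteins=8), 10, 0),
        alpha=0.1,
    )
    assert adjusted_pvalue(-1.0, cal) == 0.0
    assert adjusted_pvalue(2.0, cal) == 1.0
    med = float(np.median(cal.min_p))
    assert adjusted_pvalue(med, cal) >= 0.5


def test_bonferroni_reference():
    assert bonferroni_level(0.05, 1000) == pytest.approx(5e-5)
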