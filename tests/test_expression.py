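"""TPM, Poisson threshold, 10-kb clustering and differential expression."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srnakit.expression import (
    ClusterGroup,
    audic_claverie_p,
    differential_expression,
    group_clusters,
    hierarchical_clustering,
    normalize_tpm,
    poisson_count_threshold,
    poisson_noise_filter,
)
from srnakit.simdata import simulate_filter_study


def _em(counts, totals, loci=None):
    return normalize_tpm(pd.DataFrame(counts), totals, loci)


def test_tpm_formula_examples():
    em = _em({"S": {"a": 5, "b": 0}}, {"S": 1_000_000})
    assert float(em.tpm.loc["a", "S"]) == 5.0
    assert float(em.tpm.loc["b", "S"]) == 0.0


def test_tpm_sums_to_one_million_over_all_tags():
    rng = np.random.default_rng(0)
    counts = {"S": {f"t{i}": int(rng.integers(0, 500)) for i in range(300)}}
    total = sum(counts["S"].values())
    em = _em(counts, {"S": total})
    assert float(em.tpm["S"].sum()) == pytest.approx(1e6)


def test_tpm_matches_rational_arithmetic_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        c, t = int(rng.integers(0, 10_000)), int(rng.integers(1, 10**7))
        em = _em({"S": {"x": c}}, {"S": t})
        assert float(em.tpm.loc["x", "S"]) == pytest.approx(
            float(Fraction(c, t) * 10**6), rel=1e-12
        )


def test_zero_clean_total_rejected():
    with pytest.raises(ValueError):
        _em({"S": {"a": 1}}, {"S": 0})


def test_poisson_threshold_empty_background():
    assert poisson_count_threshold(0.0) == 1


@pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 5.0, 20.0])
def test_poisson_threshold_matches_tail_sum_oracle(lam):
    """c* equals the smallest c with an explicitly summed tail < 1e-4."""
    p_crit = 1e-4
    c = 1
    while True:
        import math

        tail = sum(
            math.exp(-lam + k * math.log(lam) - math.lgamma(k + 1))
            for k in range(c, c + 400)
        )
        if tail < p_crit:
            break
        c += 1
    assert poisson_count_threshold(lam, p_crit) == c


def test_noise_filter_keeps_planted_and_removes_noise():
    study = simulate_filter_study(["A", "B"], rng=np.random.default_rng(5))
    counts = pd.DataFrame(study.counts).T
    loci = pd.DataFrame(
        {n: {"chrom": c, "strand": "+", "position": p} for n, (c, p) in study.loci.items()}
    ).T
    em = normalize_tpm(counts, study.clean_totals, loci)
    chrom_lengths = {f"chr{i+1}": 12_500_000 for i in range(4)}
    filtered, report = poisson_noise_filter(
        em, chrom_lengths, study.positions, rng=np.random.default_rng(6)
    )
    kept = set(filtered.counts.index)
    planted = {
        n for n, noise in study.is_noise.items()
        if not noise and max(em.tpm.loc[n]) >= 10
    }
    noise = {n for n, v in study.is_noise.items() if v}
    assert planted <= kept, "well-expressed planted loci must survive"
    removed_noise = len(noise - kept) / len(noise)
    assert removed_noise >= 0.95
    for s in ("A", "B"):
        assert report.per_sample[s]["lambda"] == pytest.approx(1.0, rel=0.2)


def test_short_chromosome_rejected_by_filter():
    em = _em({"S": {"a": 5}}, {"S": 100})
    with pytest.raises(ValueError):
        poisson_noise_filter(em, {"c": 10}, {"S": {}})


def _loci(rows):
    return pd.DataFrame(
        {n: {"chrom": c, "strand": "+", "position": p} for n, (c, p) in rows.items()}
    ).T


def test_cluster_boundary_inclusive_at_10kb():
    counts = {"S": {"a": 10, "b": 10}}
    em = _em(counts, {"S": 1000}, _loci({"a": ("c1", 0), "b": ("c1", 9_999)}))
    groups = group_clusters(em)
    assert sorted(len(g.members) for g in groups) == [2]
    em2 = _em(counts, {"S": 1000}, _loci({"a": ("c1", 0), "b": ("c1", 10_001)}))
    assert sorted(len(g.members) for g in group_clusters(em2)) == [1, 1]


def test_clusters_match_union_find_oracle_and_are_order_invariant():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(2, 40))
        pos = sorted(int(p) for p in rng.integers(0, 200_000, size=n))
        names = [f"m{i}" for i in range(n)]
        rows = {nm: ("c1", p) for nm, p in zip(names, pos)}
        counts = {"S": {nm: 1 for nm in names}}
        em = _em(counts, {"S": 1000}, _loci(rows))
        groups = group_clusters(em)
        # union-find over consecutive pairs within 10 kb
        parent = list(range(n))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for i in range(n - 1):
            if pos[i + 1] - pos[i] <= 10_000:
                parent[find(i + 1)] = find(i)
        oracle = {}
        for i, nm in enumerate(names):
            oracle.setdefault(find(i), set()).add(nm)
        got = {frozenset(g.members) for g in groups}
        assert got == {frozenset(v) for v in oracle.values()}
        # partition property
        assert sorted(m for g in groups for m in g.members) == sorted(names)
        # order invariance
        shuffled = list(names)
        rng.shuffle(shuffled)
        em2 = _em({"S": {nm: 1 for nm in shuffled}}, {"S": 1000}, _loci(rows).loc[shuffled])
        assert {frozenset(g.members) for g in group_clusters(em2)} == got


def test_unpositioned_rows_become_flagged_singletons():
    loci = _loci({"a": ("c1", 100)})
    loci.loc["b"] = {"chrom": None, "strand": None, "position": None}
    em = _em({"S": {"a": 1, "b": 1}}, {"S": 10}, loci)
    groups = group_clusters(em)
    flags = {tuple(g.members): g.positioned for g in groups}
    assert flags[("a",)] is True and flags[("b",)] is False


def test_log2_ratio_closed_form():
    em = _em({"A": {"x": 400}, "B": {"x": 100}}, {"A": 1_000_000, "B": 1_000_000})
    res = differential_expression(em, "A", "B", pseudocount=0.0)
    assert res[0].log2_ratio == pytest.approx(2.0)


def test_equal_counts_not_flagged():
    em = _em({"A": {"x": 50}, "B": {"x": 50}}, {"A": 10_000, "B": 10_000})
    r = differential_expression(em, "A", "B")[0]
    assert r.log2_ratio == 0.0 and r.flag == "ns"


def test_differential_expression_antisymmetric():
    rng = np.random.default_rng(9)
    counts = {
        "A": {f"m{i}": int(rng.integers(0, 400)) for i in range(40)},
        "B": {f"m{i}": int(rng.integers(0, 400)) for i in range(40)},
    }
    em = _em(counts, {"A": 60_000, "B": 50_000})
    ab = {r.mirna: r for r in differential_expression(em, "A", "B")}
    ba = {r.mirna: r for r in differential_expression(em, "B", "A")}
    assert set(ab) == set(ba)
    for name in ab:
        assert ab[name].log2_ratio == pytest.approx(-ba[name].log2_ratio)
        assert ab[name].p_value == pytest.approx(ba[name].p_value)
        flips = {"up": "down", "down": "up", "ns": "ns"}
        assert flips[ab[name].flag] == ba[name].flag


def test_audic_claverie_matches_explicit_predictive_sum():
    """Closed-form NB tail equals direct summation of the AC predictive."""
    from math import exp, lgamma, log

    def pmf(y, x, n1, n2):
        r = n2 / n1
        return exp(
            y * log(r)
            + lgamma(x + y + 1)
            - lgamma(x + 1)
            - lgamma(y + 1)
            - (x + y + 1) * log(1 + r)
        )

    for x, y, n1, n2 in [(5, 9, 1000.0, 1500.0), (0, 3, 500.0, 500.0), (20, 4, 2e4, 1e4)]:
        lo = sum(pmf(k, x, n1, n2) for k in range(0, y + 1))
        hi = sum(pmf(k, x, n1, n2) for k in range(y, y + 2000))
        expect = min(1.0, 2 * min(lo, hi))
        assert audic_claverie_p(x, y, n1, n2) == pytest.approx(expect, rel=1e-6)


def test_min_tpm_prefilter_applied():
    em = _em({"A": {"lo": 1, "hi": 100}, "B": {"lo": 1, "hi": 1}}, {"A": 10**6, "B": 10**6})
    names = [r.mirna for r in differential_expression(em, "A", "B", min_tpm=3.0)]
    assert names == ["hi"]


def test_identical_samples_merge_at_zero_distance():
    counts = {"A": {f"m{i}": i + 1 for i in range(20)}}
    counts["B"] = dict(counts["A"])
    em = _em(counts, {"A": 1000, "B": 1000})
    Z, order = hierarchical_clustering(em)
    assert Z[0, 2] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        hierarchical_clustering(em, ["A"])


def test_replicate_pairs_merge_before_conditions():
    rng = np.random.default_rng(12)
    base = rng.integers(50, 2000, size=200).astype(float)
    shifted = base.copy()
    shifted[:50] *= 4.0
    counts = {}
    for name, mu in (("A", base), ("A2", base), ("B", shifted), ("B2", shifted)):
        counts[name] = {f"m{i}": int(rng.poisson(mu[i])) for i in range(200)}
    em = _em(counts, {k: sum(v.values()) for k, v in counts.items()})
    Z, order = hierarchical_clustering(em)
    first_two = {frozenset(_leaves(Z, len(order), int(Z[i, 0]), int(Z[i, 1]), order)) for i in range(2)}
    assert first_two == {frozenset({"A", "A2"}), frozenset({"B", "B2"})}


def _leaves(Z, n, a, b, order):
    out = []
    for node in (a, b):
        if node < n:
            out.append(order[node])
        else:
            row = Z[node - n]
            out.extend(_leaves(Z, n, int(row[0]), int(row[1]), order))
    return out
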