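"""Downregulation, additivity, haploinsufficiency and enrichment statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from cotarget_atlas import response_stats as rs
from cotarget_atlas import synthetic_data as sd


def rank_sum_enumeration_oracle(x, y) -> float:
    """Exact one-tailed ('x shifted down') p by enumerating all pooled
    label assignments.  Valid for small tie-free samples."""
    pooled = sorted(list(x) + list(y))
    obs = sum(pooled.index(v) + 1 for v in x)
    n1 = len(x)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if sum(combo) <= obs:
            count += 1
    return count / total


def hypergeom_enumeration_oracle(universe, gene_set, query) -> float:
    """P(overlap >= observed) by enumerating every possible query draw."""
    k_obs = len(gene_set & query)
    count = 0
    total = 0
    for combo in itertools.combinations(sorted(universe), len(query)):
        total += 1
        if len(gene_set & set(combo)) >= k_obs:
            count += 1
    return count / total


def test_rank_sum_exact_small_sample_values():
    assert rs.rank_sum_test([-1, -2, -3], [0, 0.1, 0.2], "less") == \
        pytest.approx(1 / 20)
    assert rs.rank_sum_test([0.9, 0.8], [0.1, 0.2], "greater") == \
        pytest.approx(1 / 6)


def test_rank_sum_matches_enumeration_for_small_samples(rng):
    for _ in range(20):
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 7))
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        got = rs.rank_sum_test(x, y, "less")
        want = rank_sum_enumeration_oracle(x, y)
        assert got == pytest.approx(want)


def test_rank_sum_identical_samples_near_half():
    p = rs.rank_sum_test(np.arange(30), np.arange(30) + 1e-9, "less")
    assert 0.4 < p < 0.6


def test_rank_sum_rejects_empty():
    with pytest.raises(ValueError):
        rs.rank_sum_test([], [1.0])


def _expr_frame(fc, fdr, condition="both"):
    idx = pd.Index([f"g{i}" for i in range(len(fc))], name="gene_id")
    return pd.DataFrame(
        {f"log2fc_{condition}": fc, f"fdr_{condition}": fdr}, index=idx
    )


def test_downregulation_summary_hand_computed_or():
    """30/100 vs 10/100 downregulated: OR = (30*90)/(70*10) ~ 3.857."""
    fc = np.r_[-np.ones(30), np.ones(70), -np.ones(10), np.ones(90)]
    fdr = np.zeros(200)
    expr = _expr_frame(fc, fdr)
    groups = {
        "A": {f"g{i}" for i in range(100)},
        "B": {f"g{i}" for i in range(100, 200)},
    }
    out = rs.downregulation_summary(expr, groups, "both",
                                    reference_group="B").set_index("group")
    assert out.loc["A", "fraction_down"] == pytest.approx(0.30)
    assert out.loc["B", "fraction_down"] == pytest.approx(0.10)
    assert out.loc["A", "odds_ratio"] == pytest.approx(30 * 90 / (70 * 10))
    assert np.isnan(out.loc["B", "odds_ratio"])


def test_downregulation_identical_groups_or_one():
    fc = np.r_[-np.ones(20), np.ones(30), -np.ones(20), np.ones(30)]
    expr = _expr_frame(fc, np.zeros(100))
    groups = {"A": {f"g{i}" for i in range(50)},
              "B": {f"g{i}" for i in range(50, 100)}}
    out = rs.downregulation_summary(expr, groups, "both",
                                    reference_group="B").set_index("group")
    assert out.loc["A", "odds_ratio"] == pytest.approx(1.0)


def test_or_inverts_under_group_swap():
    fc = np.r_[-np.ones(30), np.ones(70), -np.ones(10), np.ones(90)]
    expr = _expr_frame(fc, np.zeros(200))
    ga = {f"g{i}" for i in range(100)}
    gb = {f"g{i}" for i in range(100, 200)}
    ab = rs.downregulation_summary(expr, {"A": ga, "B": gb}, "both",
                                   reference_group="B").set_index("group")
    ba = rs.downregulation_summary(expr, {"A": ga, "B": gb}, "both",
                                   reference_group="A").set_index("group")
    assert ab.loc["A", "odds_ratio"] == pytest.approx(
        1 / ba.loc["B", "odds_ratio"]
    )


def test_overlap_targets_more_susceptible_in_planted_model():
    """Genes with sites for both miRNAs are downregulated more often in
    the double condition than single-site reference genes (OR > 1 in
    >= 95% of simulations)."""
    hits = 0
    n_sim = 100
    rng = np.random.default_rng(5)
    for _ in range(n_sim):
        n = 500
        both = -0.8 + rng.normal(0, 0.4, n)     # two additive sites
        single = -0.4 + rng.normal(0, 0.4, n)   # one site
        thr = -0.6
        a, b = int((both < thr).sum()), int((both >= thr).sum())
        c, d = int((single < thr).sum()), int((single >= thr).sum())
        hits += rs._odds_ratio(a, b, c, d) > 1
    assert hits >= 0.95 * n_sim


def test_fc_shift_test_returns_cdf_curves():
    fc = np.r_[-np.ones(10) * 2, np.zeros(20)]
    expr = _expr_frame(fc, np.zeros(30), condition="mir_a")
    p, curves = rs.fc_shift_test(
        expr, {f"g{i}" for i in range(10)},
        {f"g{i}" for i in range(10, 30)}, "mir_a",
    )
    assert p < 0.01
    assert set(curves["set"]) == {"group", "background"}
    assert curves.groupby("set")["cdf"].max().eq(1.0).all()


def test_additivity_expected_is_log2_sum():
    res = rs.additivity_test([-0.5], [-0.3], [-0.8])
    assert res.expected[0] == pytest.approx(-0.8)
    assert res.median_difference == pytest.approx(0.0)
    assert res.p_value == 1.0
    with pytest.raises(ValueError):
        rs.additivity_test([1, 2], [1], [1, 2])


def test_additivity_detects_planted_cooperativity():
    rng = np.random.default_rng(8)
    a, b, d = sd.simulate_paired_repression(20, delta=-0.5, sigma=0.1, rng=rng)
    res = rs.additivity_test(a, b, d, alternative="less")
    assert res.p_value < 0.001
    assert res.median_difference < -0.3


def test_hi_comparison_exact_value_and_mapping():
    hi = pd.Series(
        [0.9, 0.8, 0.1, 0.2, 0.5],
        index=pd.Index(["a", "b", "c", "d", "unused"], name="gene_id"),
    )
    p, n_g, n_o = rs.hi_comparison({"a", "b", "zzz"}, {"c", "d"}, hi)
    assert p == pytest.approx(1 / 6)
    assert (n_g, n_o) == (2, 2)
    with pytest.raises(ValueError):
        rs.hi_comparison({"zzz"}, {"c"}, hi)


def test_hi_planted_shift_power():
    """Beta-shifted group (delta 0.2, n=200/group) detected at alpha=0.05
    in >= 95% of simulations."""
    cfg = sd.SimConfig()
    detections = 0
    n_sim = 100
    for i in range(n_sim):
        cfg2 = sd.SimConfig(rng_seed=1000 + i)
        genes = [f"g{j}" for j in range(400)]
        boosted = set(genes[:200])
        hi = sd.simulate_hi(cfg2, genes, boosted)
        p, _, _ = rs.hi_comparison(boosted, set(genes[200:]), hi)
        detections += p < 0.05
    assert detections >= 0.95 * n_sim
    assert cfg.hi_shift == 0.2


def test_hypergeometric_enrichment_exact_and_enumerated():
    universe = {f"g{i}" for i in range(20)}
    gene_set = {f"g{i}" for i in range(5)}
    query = {"g0", "g1", "g2", "g10"}
    out = rs.gene_set_enrichment(query, {"S": gene_set}, universe)
    p = out.loc[0, "p_value"]
    assert p == pytest.approx(155 / 4845)
    assert p == pytest.approx(
        hypergeom_enumeration_oracle(universe, gene_set, query)
    )
    assert out.loc[0, "overlap"] == 3


def test_enrichment_disjoint_and_maximal_cases():
    universe = {f"g{i}" for i in range(20)}
    sets = {"S": {f"g{i}" for i in range(5)},
            "T": {f"g{i}" for i in range(10, 14)}}
    query = {f"g{i}" for i in range(5)}           # query == S
    out = rs.gene_set_enrichment(query, sets, universe).set_index("gene_set")
    assert out.loc["T", "overlap"] == 0
    assert out.loc["T", "p_value"] == pytest.approx(1.0)
    assert out.loc["S", "overlap"] == 5
    assert out.loc["S", "p_value"] == pytest.approx(1 / comb(20, 5))
    assert (out["q_value"] >= out["p_value"] - 1e-12).all()
    with pytest.raises(ValueError):
        rs.gene_set_enrichment(set(), sets, universe)
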