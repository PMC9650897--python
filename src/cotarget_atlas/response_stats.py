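"""Expression-response statistics over target groups.

Consumes a finished differential-expression table (gene-level log2 fold
change and FDR per transfection condition) and asks how target groups
defined by site geometry respond: fractions of significantly
downregulated genes and their odds ratios, rank-based fold-change shift
tests, log-additivity of the double condition against the summed
singles, haploinsufficiency-probability comparisons, and hypergeometric
gene-set enrichment.

A gene is "downregulated" when its fold change is negative and its FDR
is below threshold (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupResponse:
    """Downregulation summary for one target group."""

    group: str
    n_genes: int
    n_down: int
    fraction_down: float
    odds_ratio: float      # vs the reference group; NaN if undefined
    wilcoxon_p: float      # one-tailed shift test vs the reference group


@dataclass
class AdditivityResult:
    """Observed double-condition repression vs the log-additive expectation."""

    expected: np.ndarray
    observed: np.ndarray
    median_difference: float
    p_value: float
    alternative: str


def rank_sum_test(
    x, y, alternative: str = "less", exact_threshold: int = 10
) -> float:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both samples are small
    (min n <= ``exact_threshold``) and tie-free, otherwise the normal
    approximation with tie and continuity corrections.  ``alternative``
    refers to ``x`` relative to ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = (
        "exact"
        if (min(len(x), len(y)) <= exact_threshold and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def downregulated_mask(
    expr: pd.DataFrame, condition: str, fdr_threshold: float = 0.05
) -> pd.Series:
    """Boolean per-gene mask: log2FC < 0 and FDR < threshold."""
    fc = expr[f"log2fc_{condition}"]
    fdr = expr[f"fdr_{condition}"]
    return (fc < 0) & (fdr < fdr_threshold)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """OR of a 2x2 with Haldane-Anscombe 0.5 correction on zero cells."""
    if 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def downregulation_summary(
    expr: pd.DataFrame,
    groups: dict[str, set[str]],
    condition: str,
    fdr_threshold: float = 0.05,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Per-group downregulated fraction, OR and shift test vs a reference.

    ``groups`` maps label -> gene ids (looked up in ``expr``'s index).
    Odds ratios and one-tailed rank-sum p-values compare each group with
    ``reference_group`` (default: the pooled union of all other groups).
    Empty groups are skipped with a warning.
    """
    down = downregulated_mask(expr, condition, fdr_threshold)
    fc = expr[f"log2fc_{condition}"]
    rows: list[GroupResponse] = []
    labels = list(groups)
    for label in labels:
        genes = [g for g in groups[label] if g in expr.index]
        if not genes:
            warnings.warn(f"group {label!r} has no genes in the table; skipped")
            continue
        if reference_group is not None:
            ref_genes = [g for g in groups[reference_group] if g in expr.index]
        else:
            pool = set().union(*(groups[l] for l in labels if l != label))
            ref_genes = [g for g in pool if g in expr.index]
        n_down = int(down.loc[genes].sum())
        n = len(genes)
        if ref_genes and label != reference_group:
            r_down = int(down.loc[ref_genes].sum())
            r = len(ref_genes)
            odds = _odds_ratio(n_down, n - n_down, r_down, r - r_down)
            p = rank_sum_test(fc.loc[genes], fc.loc[ref_genes], "less")
        else:
            odds, p = float("nan"), float("nan")
        rows.append(GroupResponse(label, n, n_down, n_down / n, odds, p))
    return pd.DataFrame([r.__dict__ for r in rows])


def fc_shift_test(
    expr: pd.DataFrame,
    group_genes: set[str],
    background_genes: set[str],
    condition: str,
) -> tuple[float, pd.DataFrame]:
    """One-tailed rank-sum test that the group is shifted downward.

    Returns the p-value and the empirical CDF curves of both gene sets
    (long-form frame with columns set/log2fc/cdf), for cumulative
    fold-change plots.
    """
    g = [x for x in group_genes if x in expr.index]
    b = [x for x in background_genes if x in expr.index]
    if not g or not b:
        raise ValueError("both gene sets must be non-empty after mapping")
    fc = expr[f"log2fc_{condition}"]
    p = rank_sum_test(fc.loc[g], fc.loc[b], "less")
    frames = []
    for name, genes in (("group", g), ("background", b)):
        vals = np.sort(fc.loc[genes].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "set": name,
                    "log2fc": vals,
                    "cdf": np.arange(1, len(vals) + 1) / len(vals),
                }
            )
        )
    return p, pd.concat(frames, ignore_index=True)


def additivity_test(
    fc_single_a,
    fc_single_b,
    fc_double,
    alternative: str = "two-sided",
) -> AdditivityResult:
    """Compare observed double repression with the log-additive expectation.

    Expected log2FC of the double condition is the sum of the two single
    log2FCs per paired measurement.  The observed-minus-expected
    differences are tested with a Wilcoxon signed-rank test
    (``alternative`` as in scipy: "two-sided", "less" for cooperative
    deviation, "greater" for competitive).
    """
    a = np.asarray(fc_single_a, dtype=float)
    b = np.asarray(fc_single_b, dtype=float)
    d = np.asarray(fc_double, dtype=float)
    if not (len(a) == len(b) == len(d)):
        raise ValueError("paired vectors must have equal length")
    expected = a + b
    diff = d - expected
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, alternative=alternative).pvalue)
    return AdditivityResult(
        expected=expected,
        observed=d,
        median_difference=float(np.median(diff)),
        p_value=p,
        alternative=alternative,
    )


def hi_comparison(
    group_genes: set[str],
    other_genes: set[str],
    hi: pd.Series,
    alternative: str = "greater",
) -> tuple[float, int, int]:
    """One-tailed rank-sum test on haploinsufficiency probabilities.

    Tests whether ``group_genes`` (e.g. conserved-overlap or deep-class
    targets) have higher p(HI) than ``other_genes``.  Genes absent from
    the HI table are dropped; returns (p, n_group_mapped, n_other_mapped).
    """
    g = hi.reindex([x for x in group_genes if x in hi.index]).dropna()
    o = hi.reindex([x for x in other_genes if x in hi.index]).dropna()
    if len(g) == 0 or len(o) == 0:
        raise ValueError("a gene set is entirely unmapped in the HI table")
    p = rank_sum_test(g.to_numpy(), o.to_numpy(), alternative)
    return p, len(g), len(o)


def gene_set_enrichment(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query in each gene set.

    Gene sets are intersected with the universe; the query must be a
    subset of the universe.  p = P(X >= overlap) for X hypergeometric
    with the set size and query size as margins; q is the BH-adjusted
    p over all non-empty sets.
    """
    if not universe or not query_genes:
        raise ValueError("universe and query must be non-empty")
    query = set(query_genes) & set(universe)
    if not query:
        raise ValueError("query has no genes in the universe")
    M = len(universe)
    N = len(query)
    rows = []
    for name, members in gene_sets.items():
        inset = set(members) & set(universe)
        if not inset:
            continue
        k = len(inset & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(inset), N))
        rows.append({"gene_set": name, "set_size": len(inset),
                     "overlap": k, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = []
    return out
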