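"""Pairwise seed-overlap statistics with a GC-matched randomization null.

Two miRNAs whose site-match sequences share a long suffix/prefix produce
target sites that occupy overlapping 3'UTR coordinates ("seed overlap"
cotargeting).  For each site type the *maximum overlap* of a pair is the
longest block by which one site-match sequence can be slid onto the other
so that the overlapping characters agree exactly.  A pair is called
*extensively overlapping* when the maximum overlap is L-1 or L-2 for site
length L (7/6 nt for 8mer, 6/5 nt for the 7mer types, 5/4 nt for 6mer):
one step short of identity, so the merged region is a single near-site.

Significance of the extensive-overlap frequency within a miRNA group is
assessed against seeds randomized under a GC-content-matched null
(per-seed G+C count preserved, bases placed uniformly at random), with an
empirical p-value using the (r+1)/(B+1) estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seed_model import (
    SITE_LENGTHS,
    MirnaRecord,
    site_match,
)

#: maximum-overlap values that qualify as "extensive", per site type
EXTENSIVE_K = {
    "8mer": (7, 6),
    "7mer-m8": (6, 5),
    "7mer-A1": (6, 5),
    "6mer": (5, 4),
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class OverlapResult:
    """Maximum overlap between the site-match sequences of two families."""

    mirna_a: str
    mirna_b: str
    site_type: str
    k: int
    offset: int
    extensive: bool


@dataclass
class OverlapTestResult:
    """Observed extensive-overlap frequency and its randomization null."""

    group: str
    site_type: str
    observed_freq: float
    null_freqs: np.ndarray
    B: int
    p_emp: float = field(init=False)
    neg_log10_p: float = field(init=False)

    def __post_init__(self) -> None:
        r = int(np.sum(self.null_freqs >= self.observed_freq))
        self.p_emp = (1 + r) / (self.B + 1)
        self.neg_log10_p = float(-np.log10(self.p_emp))


def max_overlap(s1: str, s2: str) -> tuple[int, int]:
    """Largest exact suffix/prefix overlap between two site sequences.

    Returns ``(k, offset)`` where ``k`` is the largest ``n`` such that the
    last ``n`` characters of one sequence equal the first ``n`` of the
    other (both relative orders tried; ``n`` may reach ``min(len(s1),
    len(s2))``), and ``offset`` is the start of ``s2`` relative to the
    start of ``s1`` in the arrangement achieving ``k``.  When both orders
    achieve ``k``, the arrangement with ``s1`` leftmost is reported
    (offset >= 0).
    """
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    for n in range(min(len(s1), len(s2)), -1, -1):
        if n and s1[-n:] == s2[:n]:          # s1 leftmost
            return n, len(s1) - n
        if n and s2[-n:] == s1[:n]:          # s2 leftmost
            return n, -(len(s2) - n)
    return 0, len(s1)


def is_extensive(seq_a: str, seq_b: str, site_type: str) -> bool:
    """Whether the pair's maximum overlap is L-1 or L-2 for this site type.

    Equivalent to ``max_overlap(seq_a, seq_b)[0] in EXTENSIVE_K[site_type]``
    for equal-length sequences but avoids the full scan: since the
    qualifying overlaps are the two largest non-identical ones, it is
    enough that the sequences differ and some L-1 or L-2 suffix/prefix
    matches.
    """
    L = SITE_LENGTHS[site_type]
    if seq_a == seq_b:
        return False
    for n in EXTENSIVE_K[site_type]:
        if seq_a[-n:] == seq_b[:n] or seq_b[-n:] == seq_a[:n]:
            return True
    return False


# ---------------------------------------------------------------------------
# family-level helpers

def _family_seeds(records: list[MirnaRecord], group: int | None = None) -> dict[str, str]:
    """family_id -> seed, optionally restricted to one conservation group."""
    seeds: dict[str, str] = {}
    for r in records:
        if group is not None and int(r.conservation_group) != int(group):
            continue
        seeds.setdefault(r.family_id, r.seed)
    return seeds


def _site_seqs(seeds: dict[str, str], site_type: str) -> dict[str, str]:
    return {fam: site_match(seed, site_type).sequence for fam, seed in seeds.items()}


def pair_overlap_distribution(
    records: list[MirnaRecord], site_type: str, group: int | None = None
) -> pd.Series:
    """Relative occurrence of each maximum-overlap value k over all pairs.

    One entry per unordered pair of distinct families; identical-seed
    pairs are excluded (families already collapse identical seeds).
    Returns a Series indexed by k = 0..L whose values sum to 1.
    """
    seeds = _family_seeds(records, group)
    if len(seeds) < 2:
        raise ValueError("need at least 2 distinct families")
    seqs = _site_seqs(seeds, site_type)
    L = SITE_LENGTHS[site_type]
    counts = np.zeros(L + 1, dtype=float)
    n_pairs = 0
    for fa, fb in itertools.combinations(sorted(seqs), 2):
        if seeds[fa] == seeds[fb]:
            continue
        k, _ = max_overlap(seqs[fa], seqs[fb])
        counts[k] += 1
        n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no valid pairs (all seeds identical)")
    return pd.Series(counts / n_pairs, index=pd.RangeIndex(L + 1, name="k"))


# ---------------------------------------------------------------------------
# vectorized extensive-overlap frequency (used by the randomization test)
#
# Bases are coded A=0, C=1, G=2, U=3, so complementation is ``3 - code``
# and strong (G/C) bases are codes 1-2.  Site sequences are packed into
# base-4 integers; prefix/suffix comparison becomes integer arithmetic.

def _base_matrix(seqs: list[str]) -> np.ndarray:
    """(N, L) per-base code matrix from equal-length RNA strings."""
    return np.array([[_BASE_CODE[c] for c in s] for s in seqs], dtype=np.int64)


def _decode(arr: np.ndarray) -> list[str]:
    lut = np.array(list("ACGU"))
    return ["".join(row) for row in lut[arr]]


def _site_code_matrix(seed_arr: np.ndarray, site_type: str) -> np.ndarray:
    """Per-base codes of the site-match sequences for an (N, 7) seed matrix."""
    rc = (3 - seed_arr)[:, ::-1]            # reverse complement of nt 2-8
    rc6 = (3 - seed_arr[:, :6])[:, ::-1]    # reverse complement of nt 2-7
    a_col = np.zeros((seed_arr.shape[0], 1), dtype=np.int64)
    if site_type == "7mer-m8":
        return rc
    if site_type == "8mer":
        return np.hstack([rc, a_col])
    if site_type == "6mer":
        return rc6
    if site_type == "7mer-A1":
        return np.hstack([rc6, a_col])
    raise ValueError(f"unknown site type {site_type!r}")


def _pack(arr: np.ndarray) -> np.ndarray:
    L = arr.shape[1]
    weights = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
    return arr @ weights


def _extensive_freq_codes(codes: np.ndarray, site_type: str) -> float:
    N = len(codes)
    if N < 2:
        raise ValueError("need at least 2 sequences")
    L = SITE_LENGTHS[site_type]
    hit = np.zeros((N, N), dtype=bool)
    for n in EXTENSIVE_K[site_type]:
        prefix = codes // (4 ** (L - n))
        suffix = codes % (4**n)
        # suffix of row i matches prefix of column j -> i leftmost
        m = suffix[:, None] == prefix[None, :]
        hit |= m | m.T
    hit &= codes[:, None] != codes[None, :]
    iu = np.triu_indices(N, k=1)
    return float(hit[iu].mean())


def extensive_freq(seqs: list[str], site_type: str) -> float:
    """Fraction of unordered sequence pairs with extensive overlap.

    All N*(N-1)/2 pairs are counted in the denominator; identical pairs
    (k = L) are never extensive.
    """
    return _extensive_freq_codes(_pack(_base_matrix(seqs)), site_type)


def _gc_matched_seed_codes(
    gc_counts: np.ndarray, L: int, rng: np.random.Generator
) -> np.ndarray:
    """(N, L) random seed codes with the given per-seed G+C counts.

    Strong/weak base identities are uniform and strong positions are a
    uniform subset of the given size (rank trick on a uniform matrix).
    """
    N = len(gc_counts)
    U = rng.random((N, L))
    rank = U.argsort(axis=1, kind="stable").argsort(axis=1, kind="stable")
    strong = rank < np.asarray(gc_counts)[:, None]
    strong_codes = rng.integers(1, 3, size=(N, L))      # C or G
    weak_codes = rng.integers(0, 2, size=(N, L)) * 3    # A or U
    return np.where(strong, strong_codes, weak_codes)


def gc_matched_random_seeds(real_seeds: list[str], rng: np.random.Generator) -> list[str]:
    """Random seeds preserving each input seed's G+C count.

    For every input seed a random same-length string is drawn with the
    same number of G/C bases: strong (G or C) and weak (A or U) bases
    chosen uniformly and placed at uniformly random positions.
    """
    lengths = {len(s) for s in real_seeds}
    if len(lengths) != 1:
        raise ValueError("seeds must share one length")
    arr = _base_matrix(real_seeds)
    gc = ((arr == 1) | (arr == 2)).sum(axis=1)
    return _decode(_gc_matched_seed_codes(gc, arr.shape[1], rng))


def randomization_test(
    records: list[MirnaRecord],
    group: int | None,
    site_type: str,
    B: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> OverlapTestResult:
    """Empirical one-tailed test for enrichment of extensive seed overlap.

    The observed extensive-overlap frequency among all family pairs of the
    group is compared against ``B`` replicates in which every seed is
    replaced by a GC-matched random seed.  ``p_emp = (1 + #{null >=
    observed}) / (B + 1)``; the estimator never returns 0.
    """
    seeds = _family_seeds(records, group)
    label = "all" if group is None else str(int(group))
    return randomization_test_from_seeds(
        list(seeds.values()), site_type, B, rng_seed, group_label=label
    )


def randomization_test_from_seeds(
    seeds: list[str],
    site_type: str,
    B: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    group_label: str = "custom",
) -> OverlapTestResult:
    """`randomization_test` on an explicit list of family seeds."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(seeds) < 2:
        raise ValueError("need at least 2 distinct families in the group")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    real_arr = _base_matrix(seeds)
    gc = ((real_arr == 1) | (real_arr == 2)).sum(axis=1)
    observed = _extensive_freq_codes(
        _pack(_site_code_matrix(real_arr, site_type)), site_type
    )
    null = np.empty(B)
    for b in range(B):
        rand_arr = _gc_matched_seed_codes(gc, real_arr.shape[1], rng)
        null[b] = _extensive_freq_codes(
            _pack(_site_code_matrix(rand_arr, site_type)), site_type
        )
    return OverlapTestResult(
        group=group_label, site_type=site_type, observed_freq=observed,
        null_freqs=null, B=B,
    )


def extensive_pairs(
    records: list[MirnaRecord],
    group: int | None = None,
    site_types: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1"),
) -> list[OverlapResult]:
    """All unordered family pairs with extensive overlap, per site type.

    Pairs with identical seeds are excluded (same family by definition).
    A pair is reported once per qualifying site type; 6mer overlaps do not
    contribute to pair calling by default.
    """
    seeds = _family_seeds(records, group)
    out: list[OverlapResult] = []
    for st in site_types:
        seqs = _site_seqs(seeds, st)
        for fa, fb in itertools.combinations(sorted(seqs), 2):
            if seeds[fa] == seeds[fb]:
                continue
            k, offset = max_overlap(seqs[fa], seqs[fb])
            if k in EXTENSIVE_K[st]:
                out.append(OverlapResult(fa, fb, st, k, offset, True))
    return out


@dataclass
class AssociationResult:
    """One-tailed Fisher test of an annotation against extensive-overlap status."""

    annotation: str
    table: np.ndarray          # [[pos&anno, pos&!anno], [neg&anno, neg&!anno]]
    odds_ratio: float          # np.nan when a margin is empty
    p_value: float


def mirna_gene_association(
    pairs: list[OverlapResult], records: list[MirnaRecord]
) -> dict[str, AssociationResult]:
    """Association of extensive-overlap-positive families with genomic traits.

    Builds 2x2 tables of family-level extensive-overlap status against (a)
    miRNA-cluster membership and (b) multi-locus distribution, and returns
    one-tailed (greater) Fisher exact tests.
    """
    positive = {p.mirna_a for p in pairs} | {p.mirna_b for p in pairs}
    fam_cluster: dict[str, bool] = {}
    fam_multi: dict[str, bool] = {}
    for r in records:
        fam_cluster[r.family_id] = fam_cluster.get(r.family_id, False) or r.in_cluster
        fam_multi[r.family_id] = fam_multi.get(r.family_id, False) or (
            r.n_genomic_loci > 1
        )
    results = {}
    for name, anno in (("cluster", fam_cluster), ("multi_locus", fam_multi)):
        a = sum(1 for f, v in anno.items() if f in positive and v)
        b = sum(1 for f, v in anno.items() if f in positive and not v)
        c = sum(1 for f, v in anno.items() if f not in positive and v)
        d = sum(1 for f, v in anno.items() if f not in positive and not v)
        table = np.array([[a, b], [c, d]])
        if min(a + b, c + d, a + c, b + d) == 0:
            results[name] = AssociationResult(name, table, float("nan"), 1.0)
            continue
        odds, p = stats.fisher_exact(table, alternative="greater")
        results[name] = AssociationResult(name, table, float(odds), float(p))
    return results
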