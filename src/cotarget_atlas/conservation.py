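"""Target-site conservation: species counts, branch-length scores, classes.

A site's conservation is summarized two ways across an 84-species
vertebrate panel (human first; fish excluded from the underlying 100-way
alignments for alignment quality):

* ``n_species`` — the number of aligned species in which the site is
  present, human included (minimum 1);
* the branch length score (BLS) — the total branch length of the minimal
  subtree of the species phylogeny spanning all species carrying the site.

A site is called conserved when its BLS reaches the per-site-type cutoff
(1.8 for 8mer, 2.8 for 7mer-m8, 3.6 for 7mer-A1; 6mers carry no cutoff
and are never called conserved).  Conserved sites split into two depth
classes at a species-count threshold (default 62, the divide between
platypus and birds): "shallow" sites conserved in fewer species
(typically eutherian mammals) and "deep" sites conserved from human out
to coelacanth.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

#: TargetScan branch-length-score cutoffs defining a conserved site
BLS_CUTOFFS = {"8mer": 1.8, "7mer-m8": 2.8, "7mer-A1": 3.6}

#: species-count threshold splitting conserved sites into shallow/deep
DEFAULT_SPECIES_THRESHOLD = 62

#: default panel size (84-species vertebrate subset of the 100-way alignment)
DEFAULT_PANEL_SIZE = 84


@dataclass(frozen=True)
class ConservationCall:
    """Conservation classification of one target site."""

    site_id: str
    site_type: str
    bls: float
    n_species: int
    conserved: bool
    depth_class: str   # "nonconserved" | "shallow" | "deep"


def species_count(presence) -> int:
    """Number of species carrying a site (True entries, human included)."""
    vec = np.asarray(presence, dtype=bool)
    if vec.ndim != 1:
        raise ValueError("presence must be a flat vector")
    return int(vec.sum())


def load_tree(path_or_string, *, is_path: bool = True) -> dendropy.Tree:
    """Parse a Newick species tree with branch lengths."""
    if is_path:
        tree = dendropy.Tree.get(path=str(path_or_string), schema="newick")
    else:
        tree = dendropy.Tree.get(data=path_or_string, schema="newick")
    return tree


def branch_length_score(present_species, tree: dendropy.Tree) -> float:
    """Total branch length of the minimal subtree spanning the present species.

    The score is accumulated over the edges strictly below the MRCA of
    the present leaves that lead to at least one present leaf.  A site
    present in at most one species spans no branches and scores 0.
    """
    present = set(present_species)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = present - leaf_labels
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")
    if len(present) <= 1:
        return 0.0
    # postorder: count present leaves below each node
    counts: dict[int, int] = {}
    total = len(present)
    score = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in present else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        # edge above `node` is inside the spanning subtree iff it connects
        # a nonempty strict subset of present leaves to the rest
        if 0 < c < total and node.edge.length:
            score += node.edge.length
    return float(score)


def classify_site(
    bls: float,
    n_species: int,
    site_type: str,
    threshold: int = DEFAULT_SPECIES_THRESHOLD,
    site_id: str = "",
) -> ConservationCall:
    """Conserved/non-conserved call plus the shallow/deep depth class.

    ``conserved`` iff ``bls >= BLS_CUTOFFS[site_type]``; conserved sites
    are "deep" when present in at least ``threshold`` species, otherwise
    "shallow".  Raises for site types without a conservation cutoff
    (including 6mer).
    """
    if site_type not in BLS_CUTOFFS:
        raise ValueError(
            f"no conservation cutoff defined for site type {site_type!r}"
        )
    if not (np.isfinite(bls) and np.isfinite(n_species)):
        raise ValueError("bls and n_species must be finite")
    conserved = bool(bls >= BLS_CUTOFFS[site_type])
    if not conserved:
        depth = "nonconserved"
    elif n_species >= threshold:
        depth = "deep"
    else:
        depth = "shallow"
    return ConservationCall(site_id, site_type, float(bls), int(n_species),
                            conserved, depth)


def two_class_summary(calls: list[ConservationCall]) -> tuple[float, float]:
    """(fraction shallow, fraction deep) among conserved calls; sums to 1."""
    conserved = [c for c in calls if c.conserved]
    if not conserved:
        raise ValueError("no conserved sites")
    n_deep = sum(1 for c in conserved if c.depth_class == "deep")
    frac_deep = n_deep / len(conserved)
    return 1.0 - frac_deep, frac_deep


def conservation_profile(
    presence: pd.DataFrame, site_ids: list[str] | None = None
) -> pd.Series:
    """Per-species fraction of sites present, ordered by the panel.

    ``presence`` is a 0/1 table indexed by site_id with one column per
    panel species (human first).  ``site_ids`` restricts to a site class.
    """
    sub = presence if site_ids is None else presence.loc[list(site_ids)]
    if len(sub) == 0:
        raise ValueError("empty site class")
    return sub.mean(axis=0)


def classify_table(
    sites: pd.DataFrame, threshold: int = DEFAULT_SPECIES_THRESHOLD
) -> list[ConservationCall]:
    """Classify every 8mer/7mer-m8/7mer-A1 row of a site table.

    Expects columns ``site_id, site_type, bls, n_species``; rows with
    site types lacking a cutoff (6mer) are skipped.
    """
    calls = []
    for row in sites.itertuples(index=False):
        if row.site_type not in BLS_CUTOFFS:
            continue
        calls.append(
            classify_site(row.bls, row.n_species, row.site_type,
                          threshold=threshold, site_id=row.site_id)
        )
    return calls


def scan_alignment_for_site(aligned_seqs: dict[str, str], site_seq: str) -> list[str]:
    """Species whose ungapped aligned 3'UTR block contains the exact site.

    Helper for deriving presence from alignment blocks: each aligned
    sequence is stripped of gap characters and searched for an exact,
    gap-free occurrence of ``site_seq`` (RNA; T transliterated).
    """
    found = []
    target = site_seq.upper().replace("T", "U")
    for species, seq in aligned_seqs.items():
        ungapped = seq.upper().replace("-", "").replace("T", "U")
        if target in ungapped:
            found.append(species)
    return found
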