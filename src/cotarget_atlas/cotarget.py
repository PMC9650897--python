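"""Coordinate-based cotarget-site classification on 3'UTRs.

Two modes of cotargeting are distinguished by site geometry:

* **seed overlap** — two sites whose [start, end) intervals share at
  least one nucleotide, so the two miRNA-Argonaute complexes cannot be
  bound simultaneously.  "Conserved overlap" restricts both partners to
  conserved sites.
* **neighborhood** — two sites whose seed starts lie 15-100 nt apart
  (inclusive), close enough for cooperative repression but without
  steric conflict.

Coordinates are 0-based half-open internally; the seed start of a site
is its interval start (the fixed A1 of 8mer/7mer-A1 matches sits at the
3' end of the match as written on the mRNA, so the 7-nt or 6-nt seed
core always begins at the site start).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .conservation import ConservationCall
from .seed_model import SITE_LENGTHS

DEFAULT_NEIGHBORHOOD = (15, 100)


@dataclass
class UtrSite:
    """One predicted seed-match site on a gene's 3'UTR (0-based half-open)."""

    site_id: str
    gene_id: str
    utr_id: str
    start: int
    end: int
    family_id: str
    site_type: str
    conserved: bool
    call: ConservationCall | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"site {self.site_id}: invalid interval [{self.start}, {self.end})"
            )
        L = SITE_LENGTHS.get(self.site_type)
        if L is not None and self.end - self.start != L:
            raise ValueError(
                f"site {self.site_id}: {self.site_type} interval must span "
                f"{L} nt, got {self.end - self.start}"
            )

    @property
    def seed_start(self) -> int:
        return self.start


@dataclass
class CotargetAnnotation:
    """Per-site cotargeting status with partner site ids."""

    site_id: str
    seed_overlap: str = "none"     # none | same_mirna | distinct_mirna
    neighborhood: str = "none"     # none | same_mirna | distinct_mirna
    overlap_partners: list[str] = field(default_factory=list)
    neighborhood_partners: list[str] = field(default_factory=list)


def _pair_status(a: UtrSite, b: UtrSite) -> str:
    return "same_mirna" if a.family_id == b.family_id else "distinct_mirna"


def _merge_status(current: str, new: str) -> str:
    # distinct-miRNA partnership dominates the single-value summary
    if "distinct_mirna" in (current, new):
        return "distinct_mirna"
    if "same_mirna" in (current, new):
        return "same_mirna"
    return "none"


def intervals_overlap(a: UtrSite, b: UtrSite) -> bool:
    """>=1 shared nucleotide between two half-open intervals."""
    return a.start < b.end and b.start < a.end


def find_conserved_overlap(
    sites: list[UtrSite], *, conserved_only: bool = True
) -> dict[str, CotargetAnnotation]:
    """Seed-overlap partners: intersecting site intervals on the same UTR.

    With ``conserved_only`` (the "conserved overlap" definition) both
    partners must be conserved sites; pass ``False`` for the all-site
    variant.  Mixed site types are allowed; any >=1-nt intersection
    counts.  Returns an annotation for every input site.
    """
    ann = {s.site_id: CotargetAnnotation(s.site_id) for s in sites}
    by_utr: dict[str, list[UtrSite]] = defaultdict(list)
    for s in sites:
        if conserved_only and not s.conserved:
            continue
        by_utr[s.utr_id].append(s)
    for group in by_utr.values():
        for a, b in itertools.combinations(group, 2):
            if not intervals_overlap(a, b):
                continue
            status = _pair_status(a, b)
            for x, y in ((a, b), (b, a)):
                rec = ann[x.site_id]
                rec.seed_overlap = _merge_status(rec.seed_overlap, status)
                rec.overlap_partners.append(y.site_id)
    return ann


def find_neighborhood(
    sites: list[UtrSite],
    d_min: int = DEFAULT_NEIGHBORHOOD[0],
    d_max: int = DEFAULT_NEIGHBORHOOD[1],
    *,
    conserved_only: bool = True,
) -> dict[str, CotargetAnnotation]:
    """Neighborhood partners: seed starts d_min..d_max nt apart (inclusive).

    Pairs whose intervals overlap are never neighborhood pairs, whatever
    their seed-start distance.
    """
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) > d_max ({d_max})")
    ann = {s.site_id: CotargetAnnotation(s.site_id) for s in sites}
    by_utr: dict[str, list[UtrSite]] = defaultdict(list)
    for s in sites:
        if conserved_only and not s.conserved:
            continue
        by_utr[s.utr_id].append(s)
    for group in by_utr.values():
        for a, b in itertools.combinations(group, 2):
            if intervals_overlap(a, b):
                continue
            if not d_min <= abs(a.seed_start - b.seed_start) <= d_max:
                continue
            status = _pair_status(a, b)
            for x, y in ((a, b), (b, a)):
                rec = ann[x.site_id]
                rec.neighborhood = _merge_status(rec.neighborhood, status)
                rec.neighborhood_partners.append(y.site_id)
    return ann


def annotate_cotargets(
    sites: list[UtrSite],
    d_min: int = DEFAULT_NEIGHBORHOOD[0],
    d_max: int = DEFAULT_NEIGHBORHOOD[1],
    *,
    conserved_only: bool = True,
) -> dict[str, CotargetAnnotation]:
    """Combined seed-overlap + neighborhood annotation per site."""
    overlap = find_conserved_overlap(sites, conserved_only=conserved_only)
    neigh = find_neighborhood(sites, d_min, d_max, conserved_only=conserved_only)
    for sid, rec in overlap.items():
        rec.neighborhood = neigh[sid].neighborhood
        rec.neighborhood_partners = neigh[sid].neighborhood_partners
    return overlap


_STRENGTH = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 2, "6mer": 1}
_STRENGTH_LABEL = {3: "other_8mer_target", 2: "other_7mer_target",
                   1: "other_6mer_target"}


def gene_groups(
    sites: list[UtrSite],
    annotations: dict[str, CotargetAnnotation],
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-family target-group labels.

    For each (gene, family) with at least one site, assigns the gene's
    strongest category for that family:

    * ``conserved_overlap_target`` — carries a conserved site with a
      seed-overlap partner;
    * ``other_8mer_target`` / ``other_7mer_target`` /
      ``other_6mer_target`` — strongest conserved site type otherwise;
    * ``nonconserved_target`` — only non-conserved sites.

    ``single_conserved_site`` flags the strict subset with exactly one
    conserved site and zero non-conserved sites for that family.  Genes
    with no sites at all form the background and do not appear here.
    """
    by_gene_fam: dict[tuple[str, str], list[UtrSite]] = defaultdict(list)
    for s in sites:
        if families is not None and s.family_id not in families:
            continue
        by_gene_fam[(s.gene_id, s.family_id)].append(s)
    rows = []
    for (gene, fam), ss in sorted(by_gene_fam.items()):
        conserved_sites = [s for s in ss if s.conserved]
        n_nonconserved = len(ss) - len(conserved_sites)
        has_overlap = any(
            annotations[s.site_id].seed_overlap != "none" for s in conserved_sites
        )
        if has_overlap:
            label = "conserved_overlap_target"
        elif conserved_sites:
            strength = max(_STRENGTH[s.site_type] for s in conserved_sites)
            label = _STRENGTH_LABEL[strength]
        else:
            label = "nonconserved_target"
        rows.append(
            {
                "gene_id": gene,
                "family_id": fam,
                "group": label,
                "n_conserved_sites": len(conserved_sites),
                "n_nonconserved_sites": n_nonconserved,
                "single_conserved_site": (
                    len(conserved_sites) == 1 and n_nonconserved == 0
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "family_id", "group", "n_conserved_sites",
            "n_nonconserved_sites", "single_conserved_site",
        ],
    )


def cotarget_fractions(
    sites: list[UtrSite], annotations: dict[str, CotargetAnnotation]
) -> pd.DataFrame:
    """Summary of cotargeting status over conserved sites and site pairs.

    Reports both denominators (sites and unordered partner pairs) since
    either convention is in use.
    """
    conserved = [s for s in sites if s.conserved]
    n = len(conserved)
    rows = []
    for mode in ("seed_overlap", "neighborhood"):
        for status in ("same_mirna", "distinct_mirna"):
            hit_sites = [
                s for s in conserved
                if getattr(annotations[s.site_id], mode) == status
            ]
            pair_key = (
                "overlap_partners" if mode == "seed_overlap"
                else "neighborhood_partners"
            )
            pairs = set()
            for s in hit_sites:
                for p in getattr(annotations[s.site_id], pair_key):
                    pairs.add(frozenset((s.site_id, p)))
            rows.append(
                {
                    "mode": mode,
                    "status": status,
                    "n_sites": len(hit_sites),
                    "site_fraction": len(hit_sites) / n if n else float("nan"),
                    "n_pairs": len(pairs),
                }
            )
    return pd.DataFrame(rows)
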