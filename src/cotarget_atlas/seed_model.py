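"""miRNAs, seed sequences, and canonical seed-match site types.

A miRNA represses a transcript through complementarity between its seed
(nucleotides 2-8 of the mature strand) and a short match in the target
3'UTR.  Four canonical site types are distinguished, in decreasing order
of repression strength:

========  ======  ==================================================
type      length  sequence on the mRNA, written 5'->3'
========  ======  ==================================================
8mer      8       reverse complement of seed (nt 2-8) followed by A
7mer-m8   7       reverse complement of seed (nt 2-8)
7mer-A1   7       reverse complement of nt 2-7 followed by A
6mer      6       reverse complement of nt 2-7
========  ======  ==================================================

The A opposite miRNA position 1 is a fixed adenosine on the target, not a
complement of the miRNA, hence 8mer and 7mer-A1 site sequences always end
in A.  All sequences in this package are RNA (A/C/G/U); DNA input is
transliterated at I/O time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: canonical site types, strongest first
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: site-match length per type
SITE_LENGTHS = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


class ConservationGroup(enum.IntEnum):
    """miRNA family conservation groups (TargetScan convention)."""

    BROADLY_CONSERVED = 2   # conserved across most vertebrates
    CONSERVED = 1           # conserved across most mammals
    POORLY_CONSERVED = 0    # poorly conserved but confidently annotated
    MISANNOTATED = -1       # possibly misannotated as a miRNA


class AlphabetError(ValueError):
    """A sequence contains characters outside the RNA alphabet."""


class SeedLengthError(ValueError):
    """A sequence is too short (or the wrong length) for the operation."""


def _validate_rna(seq: str) -> str:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"non-RNA characters {sorted(bad)} in sequence {seq!r}; "
            "expected A/C/G/U"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    _validate_rna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def extract_seed(mature_seq: str) -> str:
    """Return the seed: nucleotides 2-8 (1-based) of a mature miRNA.

    Parameters
    ----------
    mature_seq:
        Mature miRNA sequence, 5'->3', RNA alphabet, length >= 8.
    """
    _validate_rna(mature_seq)
    if len(mature_seq) < 8:
        raise SeedLengthError(
            f"mature sequence has {len(mature_seq)} nt; need >= 8 to "
            "extract the nt 2-8 seed"
        )
    return mature_seq[1:8]


@dataclass(frozen=True)
class SiteMatch:
    """One canonical seed-match sequence as it appears on the target mRNA."""

    site_type: str
    sequence: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_LENGTHS:
            raise ValueError(f"unknown site type {self.site_type!r}")
        L = SITE_LENGTHS[self.site_type]
        if len(self.sequence) != L:
            raise SeedLengthError(
                f"{self.site_type} site must be {L} nt, got {self.sequence!r}"
            )
        if self.site_type in ("8mer", "7mer-A1") and not self.sequence.endswith("A"):
            raise ValueError(
                f"{self.site_type} sites end in the fixed A1 adenosine: "
                f"{self.sequence!r}"
            )

    @property
    def length(self) -> int:
        return SITE_LENGTHS[self.site_type]


def site_match(seed: str, site_type: str) -> SiteMatch:
    """Build the site-match sequence for a 7-nt seed and a site type.

    The returned sequence is written 5'->3' on the target mRNA:
    the reverse complement of the (sub)seed, with the fixed 3' A for
    8mer / 7mer-A1 sites.
    """
    _validate_rna(seed)
    if len(seed) != 7:
        raise SeedLengthError(f"seed must be 7 nt, got {len(seed)}")
    if site_type == "7mer-m8":
        return SiteMatch(site_type, reverse_complement(seed))
    if site_type == "8mer":
        return SiteMatch(site_type, reverse_complement(seed) + "A")
    if site_type == "6mer":
        # mature positions 2-7 = seed positions 1-6
        return SiteMatch(site_type, reverse_complement(seed[:6]))
    if site_type == "7mer-A1":
        return SiteMatch(site_type, reverse_complement(seed[:6]) + "A")
    raise ValueError(f"unknown site type {site_type!r}")


@dataclass
class MirnaRecord:
    """One mature miRNA with family and genomic annotations.

    ``conservation_group`` follows the TargetScan integer convention
    (2 broadly conserved / 1 conserved / 0 poorly conserved / -1
    misannotated).  ``in_cluster`` marks membership in a polycistronic
    miRNA cluster; ``n_genomic_loci`` counts genomic copies of the gene.
    """

    mirna_id: str
    mature_seq: str
    family_id: str
    conservation_group: ConservationGroup
    mirbase_accession: str | None = None
    mirgenedb_node: str | None = None
    in_cluster: bool = False
    n_genomic_loci: int = 1
    seed: str = field(init=False)

    def __post_init__(self) -> None:
        self.mature_seq = _validate_rna(self.mature_seq.upper().replace("T", "U"))
        self.conservation_group = ConservationGroup(self.conservation_group)
        if self.n_genomic_loci < 1:
            raise ValueError("n_genomic_loci must be >= 1")
        self.seed = extract_seed(self.mature_seq)


def read_mirna_catalog(path, *, require_accession: bool = True) -> list[MirnaRecord]:
    """Read a miRNA catalog TSV into :class:`MirnaRecord` objects.

    Expected header: ``mirna_id  mature_seq  family_id  conservation_group
    mirbase_accession  cluster_id  n_loci``.  T is transliterated to U.
    Rows without a MiRBase accession are dropped when ``require_accession``
    (reduces isomiR double counting).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"mirna_id", "mature_seq", "family_id", "conservation_group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        accession = getattr(row, "mirbase_accession", "") or None
        if require_accession and accession is None:
            continue
        cluster_id = getattr(row, "cluster_id", "") or ""
        n_loci = getattr(row, "n_loci", "") or "1"
        records.append(
            MirnaRecord(
                mirna_id=row.mirna_id,
                mature_seq=row.mature_seq,
                family_id=row.family_id,
                conservation_group=ConservationGroup(int(row.conservation_group)),
                mirbase_accession=accession,
                in_cluster=bool(cluster_id),
                n_genomic_loci=int(n_loci),
            )
        )
    return records


def write_mirna_catalog(records: list[MirnaRecord], path) -> None:
    """Write records in the catalog TSV dialect read by `read_mirna_catalog`."""
    rows = [
        {
            "mirna_id": r.mirna_id,
            "mature_seq": r.mature_seq,
            "family_id": r.family_id,
            "conservation_group": int(r.conservation_group),
            "mirbase_accession": r.mirbase_accession or "",
            "cluster_id": f"cluster_{r.family_id}" if r.in_cluster else "",
            "n_loci": r.n_genomic_loci,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
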