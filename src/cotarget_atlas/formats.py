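"""Readers and writers for the pipeline's file formats.

Formats handled here: the site-table TSV in two coordinate dialects
(``native`` 0-based half-open, ``targetscan`` 1-based inclusive),
expression and haploinsufficiency TSVs, GMT gene sets, FASTA (wrapped
lines, DNA/RNA auto-transliterated), a species-panel text list, BED
export (0-based half-open, BED-native) and a JSON run manifest with
input digests for reproducibility.  All tables normalize to the internal
conventions on read; read-then-write round-trips are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cotarget import UtrSite

log = logging.getLogger("cotarget_atlas")

SITE_TABLE_COLUMNS = [
    "site_id", "gene_id", "utr_id", "start", "end",
    "family_id", "site_type", "conserved", "bls", "n_species",
]


class ParseError(ValueError):
    """A malformed row or line in an input file."""


def read_site_table(path, coordinate_dialect: str = "native") -> list[UtrSite]:
    """Read a site table TSV, normalizing coordinates to 0-based half-open.

    ``coordinate_dialect='targetscan'`` converts 1-based inclusive
    (start, end) to half-open by subtracting 1 from start.  Invalid rows
    raise :class:`ParseError` naming the offending line.
    """
    if coordinate_dialect not in ("native", "targetscan"):
        raise ValueError(f"unknown coordinate dialect {coordinate_dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_TABLE_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        log.warning("%s: empty site table", path)
        return []
    sites = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        if coordinate_dialect == "targetscan":
            start -= 1
        if start >= end:
            raise ParseError(f"{path}, line {i}: start >= end after conversion")
        try:
            sites.append(
                UtrSite(
                    site_id=str(row.site_id),
                    gene_id=str(row.gene_id),
                    utr_id=str(row.utr_id),
                    start=start,
                    end=end,
                    family_id=str(row.family_id),
                    site_type=str(row.site_type),
                    conserved=bool(row.conserved),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {i}: {exc}") from exc
    log.info("%s: read %d sites", path, len(sites))
    return sites


def write_site_table(sites_or_df, path) -> None:
    """Write sites in the native (0-based half-open) TSV dialect."""
    if isinstance(sites_or_df, pd.DataFrame):
        df = sites_or_df
    else:
        df = pd.DataFrame(
            [
                {
                    "site_id": s.site_id, "gene_id": s.gene_id,
                    "utr_id": s.utr_id, "start": s.start, "end": s.end,
                    "family_id": s.family_id, "site_type": s.site_type,
                    "conserved": s.conserved,
                }
                for s in sites_or_df
            ]
        )
    df.to_csv(path, sep="\t", index=False)


def sites_from_frame(df: pd.DataFrame) -> list[UtrSite]:
    """Convert a native-dialect site DataFrame to UtrSite objects."""
    return [
        UtrSite(
            site_id=str(r.site_id), gene_id=str(r.gene_id), utr_id=str(r.utr_id),
            start=int(r.start), end=int(r.end), family_id=str(r.family_id),
            site_type=str(r.site_type), conserved=bool(r.conserved),
        )
        for r in df.itertuples(index=False)
    ]


def read_expression_table(path, cpm_filter: float | None = None) -> pd.DataFrame:
    """Gene-level log2FC/FDR table indexed by gene_id.

    When ``cpm_filter`` is given and a ``mean_cpm`` column exists, genes
    below the threshold are dropped (low-expression filter).
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if cpm_filter is not None and "mean_cpm" in df.columns:
        before = len(df)
        df = df[df["mean_cpm"] >= cpm_filter]
        log.info("%s: CPM filter kept %d/%d genes", path, len(df), before)
    return df


def read_hi_table(path) -> pd.Series:
    """gene_id -> haploinsufficiency probability."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    s = df["p_hi"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ParseError(f"{path}: p_hi values outside [0, 1]")
    return s


def read_gmt(path) -> dict[str, set[str]]:
    """Standard GMT: name, description, then genes, tab-separated.

    Duplicate genes within a set are deduplicated; empty sets dropped
    with a warning; lines with fewer than 3 fields raise ParseError.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}, line {lineno}: GMT lines need name, "
                    "description and >= 1 gene"
                )
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                log.warning("%s, line %d: empty set %s dropped", path, lineno, name)
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = sorted(sets[name])
            fh.write("\t".join([name, "synthetic"] + genes) + "\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA with wrapped lines; T transliterated to U (RNA internally)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is None:
                raise ParseError(f"{path}: sequence before first header")
            else:
                seqs[name].append(line.upper().replace("T", "U"))
    return {k: "".join(v) for k, v in seqs.items()}


def read_species_panel(path) -> list[str]:
    """Ordered species list, one per line, reference (human) first."""
    with open(path) as fh:
        panel = [line.strip() for line in fh if line.strip()]
    if not panel:
        raise ParseError(f"{path}: empty species panel")
    return panel


def write_species_panel(panel: list[str], path) -> None:
    Path(path).write_text("\n".join(panel) + "\n")


def read_presence_table(path) -> pd.DataFrame:
    """Species-presence TSV: site_id index, one 0/1 column per species."""
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    return df.astype(int)


def write_bed(sites, path, *, merged_overlaps: bool = False) -> None:
    """BED export of sites (0-based half-open, BED-native).

    With ``merged_overlaps``, overlapping site intervals on a UTR are
    merged into single regions first.
    """
    rows = sorted(
        ((s.utr_id, s.start, s.end, s.site_id) for s in sites),
        key=lambda r: (r[0], r[1]),
    )
    if merged_overlaps:
        merged = []
        for chrom, start, end, name in rows:
            if merged and merged[-1][0] == chrom and start < merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], end),
                              prev[3] + "," + name)
            else:
                merged.append((chrom, start, end, name))
        rows = merged
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, subcommand: str, config: dict,
                   inputs: list, rng_seed: int | None) -> Path:
    """One JSON manifest per output directory: config, digests, version."""
    out_dir = Path(out_dir)
    manifest = {
        "tool": "cotarget-atlas",
        "version": __version__,
        "subcommand": subcommand,
        "rng_seed": rng_seed,
        "config": config,
        "inputs": {
            str(p): file_digest(p) for p in inputs if Path(p).exists()
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
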