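# File formats

All tables are tab-separated with a header row. Sequences are RNA
(A/C/G/U); DNA input (T) is transliterated on read.

## miRNA catalog (`catalog.tsv`)

Columns: `mirna_id  mature_seq  family_id  conservation_group
mirbase_accession  cluster_id  n_loci`.
`conservation_group` is 2 (broadly conserved) / 1 (conserved) /
0 (poorly conserved) / −1 (misannotated). Rows without a MiRBase
accession are dropped by default (isomiR filter). `cluster_id`
non-empty marks polycistronic cluster membership; `n_loci` counts
genomic copies. The layout mirrors a TargetScan family-info file but is
its own documented dialect.

## Site table (`sites.tsv`)

Columns: `site_id  gene_id  utr_id  start  end  family_id  site_type
conserved` (optional extras: `bls  n_species  depth_class
planted_cotarget`). `site_type` ∈ {8mer, 7mer-m8, 7mer-A1, 6mer};
`end − start` must equal the site length. Two coordinate dialects:

- `native` — 0-based half-open (internal convention, BED-compatible);
- `targetscan` — 1-based inclusive; converted on read.

## Species data

- `species_panel.txt` — one species per line, reference (human) first,
  ordered by divergence.
- `tree.nwk` — Newick with branch lengths; leaves must cover the panel.
- `presence.tsv` — `site_id` plus one 0/1 column per panel species.

## Expression table (`expression.tsv`)

`gene_id` plus `log2fc_<cond>` and `fdr_<cond>` per condition
(`mir_a`, `mir_b`, `both` in the synthetic data) and `mean_cpm`.

## Haploinsufficiency table (`hi.tsv`)

`gene_id  p_hi` with p_hi in [0, 1].

## Gene sets (`*.gmt`)

Standard GMT: `name<TAB>description<TAB>gene1<TAB>gene2...`. Duplicates
within a set are collapsed; empty sets are dropped with a warning.

## Outputs

Stage outputs are TSVs mirroring the structures above plus JSON
summaries; every output directory contains a `manifest.json` with the
tool version, seed, configuration and SHA-256 digests of the inputs.
BED exports are 0-based half-open (native BED).
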