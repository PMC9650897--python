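# cotarget-atlas

Statistics for **"seed overlap" miRNA cotargeting**: how pairs of microRNAs
with similar seed sequences converge on overlapping 3′UTR target sites, how
deeply those sites are conserved across vertebrates, and what that means for
the repression of the shared target genes.

MicroRNAs recognize targets through the seed (nucleotides 2–8 of the mature
strand); the reverse complement of the seed in a 3′UTR defines a site, graded
8mer > 7mer-m8 > 7mer-A1 > 6mer by repression strength. When two miRNA
families have seeds that are near-shifts of each other, their site-match
sequences share a long prefix/suffix and their sites on a UTR *overlap in
coordinates* — the two silencing complexes cannot bind simultaneously, yet
such genes gain susceptibility to downregulation when both miRNAs are
present (the miR-128 / miR-148a pair on *KLF4* is the canonical case). This
package implements the complete analysis around that phenomenon, for
computational biologists working with TargetScan-style site predictions and
gene-level differential-expression tables.

## What it computes

- **Pairwise maximum overlap** `k(s₁, s₂)` — the largest `n` such that the
  last `n` characters of one site-match sequence equal the first `n` of the
  other (both orders tried). A pair is *extensively overlapping* when
  `k ∈ {L−1, L−2}` for site length `L` (7/6 nt for 8mer, 6/5 nt for the
  7mer types, 5/4 nt for 6mer).
- **Randomization test** — the observed extensive-overlap frequency of a
  miRNA group against `B` replicates with GC-content-matched random seeds;
  `p_emp = (1 + #{null ≥ obs}) / (B + 1)`, one-tailed for enrichment.
- **Conservation classes** — species counts across an 84-species vertebrate
  panel and branch length scores (BLS = total branch length of the minimal
  spanning subtree over the species carrying the site). Conserved sites
  (BLS ≥ 1.8 / 2.8 / 3.6 for 8mer / 7mer-m8 / 7mer-A1) split into a
  *shallow* class (< 62 species, typically eutherian mammals) and a *deep*
  class (≥ 62 species, human to coelacanth).
- **Cotarget geometry** — coordinate-based "conserved overlap" (≥ 1 shared
  nucleotide between two conserved sites) and "neighborhood" cotargeting
  (seed starts 15–100 nt apart), for same or distinct miRNAs.
- **Response statistics** — downregulated fractions (log2FC < 0, FDR < 0.05)
  and odds ratios per target group, one-tailed Wilcoxon rank-sum shift
  tests, log-additivity of double-transfection repression
  (`expected = log2FC_a + log2FC_b`), haploinsufficiency-probability
  comparisons, and hypergeometric gene-set enrichment with BH correction.
- **Synthetic data** — generators for every input table with planted,
  exactly recoverable structure (extensive pairs, cotarget geometry, the
  65/35 shallow/deep mixture, additive repression, shifted
  haploinsufficiency), so the entire pipeline is testable offline.

## Worked example

The chained pipeline on synthetic data (all stages, one seed):

```bash
cotarget-atlas full-run --rng-seed 17 --b 200 --out-dir demo
```

prints, among other things:

```
7 extensive pair records -> demo/overlap
classified 3467 sites: 64.3% shallow / 35.6% deep of conserved
                   group  n_genes  n_down  fraction_down  odds_ratio  wilcoxon_p
conserved_overlap_target       99       7       0.070707   10.601449    0.000857
     nonconserved_target     1225       8       0.006531    0.514051    0.618757
       other_7mer_target      847       6       0.007084    0.737897    0.567248
       other_8mer_target      514       7       0.013619    1.571006    0.415252
```

Reading this: the five planted extensive-overlap family pairs are recovered
(seven records because a pair is reported once per qualifying site type);
conserved sites split 64.3% / 35.6% into the shallow and deep classes
(planted mixture weight 0.65); and genes carrying conserved overlapped sites
are downregulated in the double-miRNA condition far more often than other
8/7mer targets (odds ratio ≈ 10.6, rank-sum p ≈ 9 × 10⁻⁴). The
`demo/overlap/overlap_summary.json` file holds the randomization test
(observed extensive-overlap frequency 0.0115 vs null mean 0.0024,
p_emp ≈ 0.005) and the one-tailed Fisher association of extensive-overlap
families with miRNA clusters (OR 13.2, p ≈ 0.005).

The single stages (`simulate`, `seed-overlap`, `conservation`, `cotarget`,
`response`, `enrich`) run individually on your own TSV/Newick/GMT inputs;
see `docs/formats.md` for the dialects, and `cotarget-atlas <cmd> --help`.

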