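# Methods

## The overlap statistic

For two site-match sequences written 5′→3′ on the mRNA, the maximum
overlap `k` is the largest `n` for which the length-`n` suffix of one
equals the length-`n` prefix of the other, with both relative orders
tried and ties broken by reporting the arrangement with the first
sequence leftmost. `k` may reach the full length (identical sequences);
a pair is *extensive* at `k = L−1` or `L−2`. The rationale for the
threshold: one or two shifted positions is the closest two distinct
seeds can come without being the same family, and produces a merged
region of `L+1` or `L+2` nt on the UTR — a single composite site. The
implementation packs sequences into base-4 integers so that the
group-wide pair frequency is a handful of integer matrix comparisons;
`max_overlap` itself is the readable string version, and the two paths
are cross-checked in the tests together with an independent
slide-and-compare oracle.

Pair calling across a catalog considers 8mer, 7mer-m8 and 7mer-A1
sequences; 6mer overlaps are tabulated in the distribution but do not
call pairs. Identical-seed pairs are excluded (families collapse
identical seeds; an identical pair is redundancy, not overlap).
Mixed-type overlap (an 8mer of one miRNA against a 7mer of another) is
handled coordinate-wise in the cotarget module, not in the seed-string
statistic.

## The randomization null

Each replicate replaces every family seed with a random seed carrying
the same G+C count (strong/weak identities uniform, positions uniform),
rebuilds the site-match sequences, and recomputes the extensive-overlap
frequency. With `B` replicates the empirical p is `(1 + r)/(B + 1)`
where `r` counts null frequencies at or above the observed one — never
zero, one-tailed for enrichment. Random seeds are not forced to differ
from real seeds; the collision probability is negligible and rejection
would bias the null.

The null count distribution is discrete. When the expected number of
extensive pairs per replicate is small (small groups, long site types),
ties between observed and null frequencies make the estimator visibly
conservative. The calibration checks in this package therefore run at
group size 200 with the 6mer site type, where ~50 extensive pairs are
expected per replicate and the discreteness is negligible; measured
rejection rates at α = 0.05 sit at 0.04–0.05.

## Conservation model

`n_species` counts the species (human included, minimum 1) whose
aligned UTR carries the site; the BLS is the total branch length of the
minimal subtree of the species tree spanning those species (0 for a
single species). The implementation walks the tree once in postorder
and sums edges lying below the MRCA that lead to at least one present
leaf; tests verify it against a path-union oracle on random topologies.
Conserved calls use the per-type BLS cutoffs 1.8 / 2.8 / 3.6
(8mer / 7mer-m8 / 7mer-A1); 6mers have no cutoff and raise on
classification. Conserved sites split at 62 species — the divide
between platypus and birds on the 84-species panel — into shallow
(< 62) and deep (≥ 62) classes. BLS values present in an input site
table are used as-is; recomputation from a presence row and a tree is
the fallback, because reference pipelines compute BLS on per-UTR trees
that are not distributed with the site tables, so a full-tree
recomputation need not reproduce their numbers exactly.

## Cotarget geometry

Coordinates are 0-based half-open internally (TargetScan's 1-based
inclusive dialect is converted at I/O). Seed-overlap partnership is ≥ 1
shared nucleotide between two site intervals on the same UTR — the
stringent `L−1/L−2` thresholds belong to the seed-string statistic
only. Neighborhood partnership is a seed-start distance in the
inclusive range [15, 100]; the "approximately 15–100 nt" convention in
the cooperativity literature is resolved to exact inclusive bounds, and
overlapping pairs are never neighborhood pairs. The seed start of every
site type equals its interval start, because the fixed A1 adenosine of
8mer/7mer-A1 matches sits at the 3′ end of the match as written on the
mRNA. A site may carry both annotations through different partners;
per-site summaries label a site by its strongest partnership
(distinct-miRNA over same-miRNA). Gene-level grouping assigns each
(gene, family) its strongest category — conserved-overlap target, then
other 8mer / 7mer / 6mer target by best conserved site, then
non-conserved target — and flags the strict subset with exactly one
conserved site and no non-conserved sites. Cotarget fraction summaries
report both site-count and pair-count denominators, since both
conventions exist.

## Response statistics

Downregulation is log2FC < 0 with BH-adjusted FDR < 0.05 (0.1
selectable). Odds ratios use the Haldane–Anscombe 0.5 correction when a
cell is empty. Rank-sum tests use the exact null when both samples have
min n ≤ 10 and no ties, otherwise the normal approximation with tie and
continuity corrections. The additivity test compares observed
double-condition log2FC with the sum of the two single-condition
log2FCs per paired measurement by a Wilcoxon signed-rank test
(one-tailed "less" = cooperative deviation; two-sided available).
Gene-set enrichment is the upper-tail hypergeometric probability with
BH correction across sets; the default universe is the expression
table's gene list (an all-annotated-genes universe is a caller choice).
The differential-expression fit itself is out of scope — the pipeline
consumes a finished table; when raw CPM values accompany it, a
max-CPM ≥ 1 filter can be applied at load.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
at the stated study conditions, and its defaults are fixed rather than
tuned: 84-species panel, 62-species threshold, shallow mixture weight
0.65 (shallow counts uniform on [20, 61], deep on [62, 84],
non-conserved on [1, 19]), neighborhood distances uniform on [15, 100],
10% of conserved sites in planted overlap pairs and 10% in neighborhood
pairs, per-site log2 effects β = −0.6 / −0.4 / −0.3 / −0.12 (8mer /
7mer-m8 / 7mer-A1 / 6mer, enforcing the canonical hierarchy), Gaussian
noise σ = 0.15, cooperativity δ = 0 (the additive regime), and a +0.2
Beta-mean shift for the haploinsufficiency of boosted gene classes.

Catalog planting shifts a base seed by 1–2 nt so the 7mer-m8 overlap is
exactly `L−1` or `L−2`, and rejection-samples every other seed until no
non-planted pair is extensive for any site type — making the planted
pairs a deterministic ground truth. Site placement separates unrelated
placements by > 110 nt so planted geometry is the only cotarget
geometry. The species panel is synthetic: a pectinate ultrametric tree
ordered by divergence, with a long internal edge between the 19th and
20th species so that the planted species counts and the BLS-cutoff
calls agree by construction (non-conserved sites, ≤ 19 species, have
BLS ≤ 0.95 < 1.8; conserved sites, ≥ 20 species, have BLS ≥ 3.86 ≥ 3.6).
Presence vectors are nested prefixes of the panel, which makes
per-species conservation profiles monotone.

Expression follows the additive model
`log2FC(x) = Σ_sites β(type) + N(0, σ)` per single condition and
`log2FC(both) = log2FC(a) + log2FC(b) + δ·[sites for both] + N(0, σ)`;
FDR flags come from two-sided z-tests at the known noise scale with BH
correction (the simplest model matching the consumption contract — the
real pipeline's negative-binomial fit is out of scope). One seed fixes
every emitted file byte for byte.

What the generator does **not** emulate: real UTR sequence evolution,
alignment errors, non-nested presence patterns, correlated expression
noise, site-context effects (local AU content, supplementary 3′
pairing) and read-count sampling. Passing tests therefore demonstrate
the correctness of the statistics and the recoverability of planted
structure, not performance on real alignments or real
differential-expression noise.

## Numerical and design notes

- Empirical p-values are bounded to `[1/(B+1), 1]` by the estimator.
- `max_overlap` tie-break: first argument leftmost; offsets are the
  start of the second sequence relative to the first.
- Wilcoxon signed-rank on an identically-zero difference vector returns
  p = 1 rather than erroring (degenerate-additivity input).
- Fisher association tables with an empty margin report OR as undefined
  (NaN) with p = 1 instead of raising.
- Problem sizes in the shipped checks (20,000 sites for the mixture,
  200 repeats × B = 200 for calibration, 500 simulations for the
  additivity error rate) were chosen so that the binomial noise of each
  estimate is well inside the tolerance being asserted.
- Whether -5p/-3p arms of one miRNA gene should ever pair in the
  overlap analysis is left to the catalog: records are compared at the
  family level, and arms with distinct family ids are ordinary pairs.

## Known limitations

- BLS on the single provided species tree will not numerically match
  per-UTR-tree scores from reference pipelines (by design; see above).
- The full-scale analysis of real TargetScan site tables is I/O-bound
  and has only been exercised at synthetic scale here.
- The randomization test's conservativeness for very small groups
  (< ~20 families) is inherent to discrete empirical p-values; report
  `p_emp` rather than comparing it to a nominal level in that regime.
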