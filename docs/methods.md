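# Methods

## Scope and data model

`retrosite` analyses retroviral integration-site datasets: sets of single
genomic bases (the first genomic nucleotide flanking the 3'-LTR
vector–genome junction), each with chromosome, 0-based position, strand
and a dataset label. All coordinates are 0-based half-open; a site is the
1-bp interval `[pos, pos+1)`. Inputs and outputs use plain-text genomics
formats: BED4/BED6, refFlat-style gene TSV, UCSC chrom.sizes, bedGraph
and TSV report tables with a `#schema:` header line.

## Junction-read processing

Reads arrive as FASTA plus a BLAST-outfmt-6-like table of genomic hits
(read_id, chrom, start, end, strand, percent identity, aligned length).
Processing has three steps:

1. **Filtering.** Unmapped reads are dropped, as are reads whose best hit
   (highest identity, ties to longer alignment) aligns fewer than
   `min_genomic_length` bp (default 20 bp — a typical uniqueness floor for
   LM-PCR junction fragments; the threshold is configurable because
   protocols differ).
2. **Ambiguity.** A read is *ambiguous* when ≥2 placements lie within
   `ambiguity_identity_delta` (default 2) percentage points of the best
   hit's identity; otherwise it is *unique*. Identity is treated as percent
   identity and the delta as an absolute percentage-point difference.
3. **Collapsing.** Unique reads sharing (chrom, junction base, strand)
   collapse to one site whose `support` counts the reads; the junction
   base is the hit start on the plus strand and `end − 1` on the minus
   strand. The collapsing key deliberately excludes the read sequence:
   sheared-DNA duplicates of different lengths at the same coordinate are
   redundant. Ambiguous reads emit one flagged placement each, linked by a
   `match_group`.

The **repeat-analysis set** keeps all unique sites plus one
representative per ambiguous group whose placements all fall inside
repeat intervals of a single family; groups touching two families, or any
non-repeat position, are dropped. This set is therefore never smaller
than the unique set, which is why repeat-table dataset totals exceed
unique-site totals.

## Annotation windows

* **Region class** (exclusive, precedence TSS-proximal > intragenic >
  intergenic): TSS-proximal when |signed distance to the nearest TSS| ≤
  2,500 bp (inclusive — inclusive bounds make the three percentages sum
  to exactly 100); intragenic when inside a transcription span
  `[tx_start, tx_end)`; intergenic otherwise. The transcription span, not
  an extended gene body, defines "inside a gene". A site TSS-proximal to
  one gene and intragenic in another is TSS-proximal.
* **Signed TSS distance**: to the nearest TSS within ±50 kb, sign
  following the gene's strand (positive = downstream in gene
  orientation); ties break on |distance| then gene id. Sites with no TSS
  within the window are excluded from distance profiles.
* **Features** (CpG, CNC, TFBS, DNase I HS, histone marks): hit when an
  interval overlaps the ±1 kb window `[pos−1000, pos+1001)` by ≥1 bp.
* **Repeats**: the family of the interval containing the site base
  itself — no window. Nested/overlapping repeats resolve to the smallest
  interval, then lexicographic family.
* **Target genes**: every gene with |TSS − pos| ≤ 50 kb, sorted by
  distance. Transcript isoforms sharing (chrom, strand, TSS, span) are
  deduplicated first so one promoter is not counted per isoform.

## Profiles

**TSS-distance histograms** cover ±50 kb at 2,500-bp resolution (coarse)
and ±2.5 kb at 50-bp resolution (fine; 100 bp also supported — both bin
widths are exposed because either convention appears in practice).
Fractions are normalised over sites with a defined, in-span distance.
Bins are right-closed `(lo, hi]` with the lowest edge inclusive, so a
distance landing exactly on an interior edge belongs to the bin ending
there; total mass is 1 at any bin width.

**ChIP density** is mean per-bp fragment coverage in 50-bp bins over a
5-kb window centred on each site, averaged over sites. Profiles are *not*
flipped by site strand by default (`flip_by_site_strand` enables it):
histone-mark environments around integrations are conventionally plotted
in genome orientation, and flipping would change nothing for symmetric
marks while silently halving interpretability for asymmetric ones.
Density is linear in the fragment track, which the tests assert.

**Chromatin states.** Mark presence uses the ±1 kb overlap rule. A rule
table maps mark combinations to states; a site receives a state only
when *exactly one* rule matches (the "unambiguous association"
semantics). The default table —
Promoter {H3K4me3}, Enhancer {H3K4me1, not H3K4me3},
Transcribed {H3K36me3, not H3K4me1/3},
Heterochromatin {H3K27me3, not H3K4me1/3, not H3K36me3} — encodes the
standard single-mark interpretations with forbidden sets enforcing
precedence of promoter over enhancer over transcription over repression.
The table is fully user-overridable (H3K27ac can be used as a qualifier
in custom rules); no published combination table is canonical, so the
default is a documented choice, not a claim.

## Cluster statistic

Under the null, n sites on an effective genome of length L form a
homogeneous Poisson process of rate λ = n/L. For cluster order k and
significance α, we solve P(Poisson(λw) ≥ k−1) = α for the expected count
λw by monotone root-finding (Brent, tolerance far below 1 bp) and set
w = ⌊λ*L/n⌋ — the largest integer window for which the probability that a
given site has ≥ k−1 further sites within w downstream stays ≤ α.
Defaults k = 3, α = 0.01. Because w scales as L/n, the definition adapts
to dataset size: larger datasets get proportionally tighter windows, so
cluster calls remain comparable across datasets of different depth. For
k = 3, α = 0.01 the root is λ* ≈ 0.148555; with n = 8,250 and
L = 2.995×10⁹ (a non-gap human genome length) w = 53,929 bp. L defaults
to the sum of the supplied chromosome sizes; gap subtraction is the
caller's responsibility and w is always reported alongside n and L.

**Calling.** Positions are sorted per chromosome; every run of k
consecutive sites spanning ≤ w qualifies, and runs sharing at least one
site (index gap ≤ k−1) chain transitively into one maximal cluster. This
is provably equivalent to enumerating all k-subsets with span ≤ w and
merging overlapping ones (the test suite checks the equivalence
exhaustively on random instances), but runs in O(n log n). Merging is
transitive rather than tiled so clusters of a hundred or more sites are
representable. Degenerate parameter regimes are guarded: α → 1 caps the
window, and a sub-bp window (extreme α or density) is reported as 1 bp
with a warning.

## Fisher comparisons

Each comparison is a 2×2 table (in-category/not × two datasets). The
two-sided p is the sum of point probabilities ≤ the observed table's —
the most common of the several two-sided conventions, stated here because
they differ; computation delegates to `scipy.stats.fisher_exact`, and the
test suite checks it against direct hypergeometric enumeration. The
sample odds ratio (a·d)/(b·c) is reported with 0/∞/NaN for degenerate
tables. α defaults to 0.01 with no multiple-testing correction (an
optional Bonferroni flag exists). For reproducing published tables,
counts are reconstructed as round(percent × total / 100); this helper is
never used in the pipeline proper.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not real genomes. `make_genome` places non-overlapping genes (default 50
genes of 5–30 kb on 2 × 1 Mb chromosomes — gene density ~2.5%/Mb-scale
spans keep every regime populated at small n), CpG islands of 1 kb on 60%
of TSSs, scattered CNC/TFBS/DNase intervals at 20/60/30 per Mb, repeats
covering ~45% of the genome in five families, and the canonical mark
layout (H3K4me3 at TSS ±1 kb, H3K4me1 on the 1–5 kb promoter flanks,
H3K36me3 over gene bodies beyond 2.5 kb of the TSS, H3K27me3 in random
intergenic blocks). Sites are drawn from a three-component mixture:
Gaussian around a uniformly chosen TSS (default spread 500 bp, chosen so
fine-binned profiles have a recoverable mode while a visible fraction
crosses the ±2.5 kb boundary), uniform within a uniformly chosen gene
span, and uniform over the genome. The random control is uniform over the
whole synthetic genome: there are no gaps, mappability or
restriction-site structure at this scale, so no further normalisation is
applied (real in-silico controls are normalised for such biases).
`generate_mark_fragments` samples fixed-length fragments with a
configurable enriched:background per-bp rate ratio (default 10:1).

What passing tests therefore show: the window conventions, the scan
statistic's calibration and the comparison machinery behave correctly on
data with known structure. What they do not show: robustness to
alignment artefacts, mappability holes, clonal expansion of transduced
cells, or PCR bias — real-data effects the generator deliberately omits.

## Numerical choices and limitations

* Root-finding tolerance for λ* is 1e-12 relative; w is floored to an
  integer bp.
* Ties everywhere break deterministically (smallest interval, then
  lexicographic label; |distance|, then gene id), so reruns are
  byte-identical for a fixed seed — the end-to-end tests assert this.
* Empty inputs: an empty read list collapses to an empty site list; an
  empty fragment track yields a valid all-zero density profile; an empty
  distance list is an error (nothing to profile); a dataset smaller than
  k cannot have a threshold derived.
* The Poisson downstream-neighbour formulation is this package's own
  stand-in for numerosity-adjusted hot-spot definitions used in the
  integration-site literature; with default parameters it lands in the
  same tens-of-kilobases regime (53,929 bp at n = 8,250, L = 2.995 Gb)
  but exact equality with any particular published window is not claimed,
  and the effective genome length used is always reported with w.
* Percent-identity semantics of alignment hits are taken at face value;
  raw-score dialects must be mapped to percent by the caller.
* No exon/intron substructure, no peak calling, no read alignment, no
  sequence-level simulation: coordinates only.
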