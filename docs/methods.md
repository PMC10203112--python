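# Methods

`stopcall` implements the computational side of a stop-codon-introducing
cytosine base-editing (CBE) workflow: guide design, off-target search,
editing-outcome quantification from amplicons, a genome-wide off-target
burden statistic for whole-genome sequencing call sets, and bespoke WGBS
methylation summaries. Everything is testable offline against seeded
synthetic genomes with planted ground truth.

## Stop-codon conversion model

A CBE (nCas9–cytidine-deaminase fusion) converts C·G to T·A inside an
editing window of the protospacer, counted 1-based from the PAM-distal (5')
end. Exactly four sense codons can be turned into stop codons this way:

| source | edit | strand of protospacer | result |
|--------|------|-----------------------|--------|
| CAA    | C1→T | coding (sense)        | TAA    |
| CAG    | C1→T | coding (sense)        | TAG    |
| CGA    | C1→T | coding (sense)        | TGA    |
| TGG    | G2+G3→A (C→T on opposite strand) | antisense | TAA |

These are the only possibilities: enumerating all single/multi C→T (sense)
and G→A (antisense) substitutions over the 61 sense codons yields stops only
for these four sources. For TGG the single-edit products TAG (G2→A) and TGA
(G3→A) are chemically implied and are also emitted, flagged non-canonical so
users can filter to the canonical double-edit TAA conversion.

`find_guides` reports every genomic protospacer placement (on the rule's
strand, with a PAM matching the profile immediately 3') whose window covers
*all* cytosines required by a rule. Codons spanning exon junctions are
eligible — only the edited bases must be exonic; the protospacer itself is
genomic DNA and may cross intron sequence. The start codon and the native
stop are excluded; stops in the final 5 % of the CDS are flagged
`late_truncation` but kept. A placement is identified by (contig, interval,
strand, rule, codon index): the codon index is part of the identity because
two adjacent TGG codons can share one placement and rule while being
distinct editing targets.

Correctness is enforced by construction and verified two ways in the test
suite: (i) applying each candidate's edits to the spliced CDS and
translating must yield a protein truncated exactly at the reported codon
with the reported stop; (ii) the candidate set must equal an independent
brute-force oracle that scans every window on both strands and every
codon-offset subset whose edit produces a stop.

### Editor profiles

The editing window and PAM are configuration, not inference. Shipped
profiles: `BE3` and `BE4` (20-nt guide, NGG, window [4,8] — the canonical
BE3-family window), `hA3A-eBE3-Y130F` (window [3,10]; the hyperactive hA3A
deaminase edits a broader window, and the Y130F narrowing still leaves it
wider than BE3's), and `xCas9-BE` (relaxed PAMs NG/GAA/GAT). All windows and
PAM sets are overridable per call.

### Efficiency heuristic

Editing efficiency is scored by a fixed, documented heuristic rather than a
learned model (no published, implementable model exists for these editors):

```
score = Π_p  w_pos(p) · w_ctx(base 5' of p)  ·  0.8^(k−1)
```

over the k required positions, where `w_pos` is a triangular weight equal to
1 at the window centre and decaying linearly to (half-width)/(half-width+1)
at the edges, and `w_ctx` encodes the APOBEC-family dinucleotide preference
TC=1.0, CC=0.9, AC=0.8, GC=0.5 (0.8 when the 5' neighbour is unknown). The
score is clamped to [0,1] and the weight set is versioned
(`stopcall-heuristic-1`) so outputs are pinnable. Ranking is lexicographic:
fewer predicted off-targets at ≤2 mismatches, higher score, earlier
truncation, genomic coordinate.

## Off-target search

A full-scan Hamming search (both strands, PAM matched exactly under IUPAC
semantics, no bulges, windows containing N skipped), vectorized with numpy
sliding windows. No index structure is used: at the intended desk scale
(≤ a few hundred kb) a complete scan runs in milliseconds and its
equivalence to a naive per-window oracle is checked directly in the tests.
Default mismatch ceiling 3.

## Amplicon quantification

Reads are aligned globally to the amplicon (match +2, mismatch −3, affine
gaps open −6 / extend −1, via Biopython's PairwiseAligner). Indels are
left-normalized after alignment so equivalent gap placements compare
identically. Equal-length read/reference pairs are scored column-wise
without gaps: with these scores a gap pair costs at least 14 while a
mismatch costs 5, so gapped alignments of equal-length pairs are never
optimal at the low mismatch densities of amplicon data; this fast path is a
documented numerical choice.

Within the quantification window (protospacer ± 5 nt by default):

* **indel rate** — reads with ≥1 insertion/deletion overlapping the window,
  over all reads; indels elsewhere in the amplicon are ignored as
  amplification artifacts.
* **conversion rate** — per target position, the fraction of *non-indel*
  reads carrying the intended C→T.
* **adjacent-site rate** — fraction of non-indel reads with ≥1 unintended
  substitution at a non-target window position. The term is used in the
  field without a formula; this operationalization (any unintended window
  substitution on a non-indel read) is the package's definition.

Reads partition into {indel, adjacent-mutated, intended-only, unedited};
"unedited" is the remainder class and also absorbs rare reads with an
unintended substitution at a target position.

Clone-based genotyping calls each blunt-cloned allele sequence
intended_stop / wildtype / other (window-restricted), then labels the
embryo: homozygous_stop if all clones intended; wildtype if all wildtype;
heterozygous if exactly two call classes each comprise ≥25 % of clones;
mosaic otherwise. The 13-clone minimum mirrors bench practice (>13 clones
sequenced per embryo); fewer clones lowers confidence but still yields a
label. Aggregation rounds percent-homozygous half-up to one decimal
(9/16 → 56.3); in multi-locus experiments an embryo counts only if
homozygous at every locus.

## Off-target burden test (GOIT statistic)

De-novo variants from three callers are intersected on
(contig, position, ref, alt) — SNVs and indels separately, indels after
left-normalization of their representation — with the consensus allele
frequency taken as the mean across callers. Filtering keeps variants with
AF strictly above 0.10 ("more than 10 %") that match no known-variant site
(dbSNP/MGP-style exclusion lists as BED intervals or site lists).

The burden test asks whether the filtered variants are enriched in
transcribed regions. Each of `n_sim` simulations (default 10,000) draws the
same number of loci uniformly without replacement over the non-N genome and
records the transcribed proportion. A two-sided Fisher's exact test then
compares

```
[[ observed transcribed, observed untranscribed ],
 [ pooled simulated transcribed, pooled simulated untranscribed ]]
```

where the second row pools all `n_sim × n` simulated loci. Pooling is
deliberate: the simulated row estimates the null expectation with ~n_sim
times the observed row's precision, and giving it its true weight makes the
test's type-I error near-nominal (measured 2–10 % at α=0.05 over seeded
replicates). Collapsing the simulations to an equal-n pseudo-count row
instead double-counts sampling variance and drives type-I below 1 %.
"Transcribed region" defaults to the transcript span (exons + introns);
exonic-only classification is a caller-side choice of interval set.

## WGBS summaries

Per-CpG methylation level = methylated/(methylated+unmethylated), defined
only at coverage ≥3X. Tiles are the fixed 1-kb grid; a tile's level is the
unweighted mean of its usable CpG levels and requires ≥3 usable CpGs
(undefined otherwise). Unweighted (rather than read-count-weighted) means
are used throughout — "mean methylation level" without weighting.

Sample similarity = 1 − min-max-normalized Euclidean distance over tiles
defined in every sample (listwise deletion); normalization uses off-diagonal
distances only and the diagonal is fixed at 1, so the most similar pair
(often a duplicate) scores 1 and the most distant pair scores exactly 0. If
all pairwise distances are equal the off-diagonal similarities are defined
as 1 with a warning.

Elements (promoters = TSS ± 2 kb, strand-aware; enhancers, TEs, CGIs or any
BED intervals) get the same ≥3-usable-CpG unweighted mean.
Hypermethylated-element calls compare two replicate groups per element with
a two-sided Welch t-test on replicate means ("multiple t-tests" read as
independent per-element tests; no correction is applied for the call, as in
the source analysis, though a Benjamini–Hochberg column is reported
alongside). An element is called hypermethylated when
mean_A − mean_B > 0.30 (strict) and raw p < 0.05 (strict). Degenerate
zero-variance cases: p = 1 when the group means are equal, p = 0 otherwise.

## Synthetic data generators

Every generator owns an RNG stream seeded with (seed, CRC32(name)), so
outputs are byte-identical for a fixed seed and adding a generator never
shifts another's stream.

* **Toy genomes** — random background at GC 0.42 with planted genes. Each
  gene's CDS is built codon-wise (ATG … TAA, no internal stops) with
  `planted_editable_codons` stop-convertible codons placed ≥8 codons apart.
  Reachability under the default profile is engineered: sense plants
  (CAA/CAG/CGA) put their C at protospacer position 6 by setting the codon
  five positions downstream to AGG (the NGG PAM); TGG plants put their
  second G at antisense position 6 by setting the codon five positions
  upstream to CCA (the PAM on the opposite strand). Genes are placed on
  either strand, optionally with GT…AG introns at codon boundaries kept
  clear of the planted regions. The truth table records each planted
  codon's expected protospacer interval and strand.
* **Amplicon reads** — per read: with p_indel a random 1–10 nt
  insertion/deletion in the protospacer window; otherwise the intended C→T
  with p_conversion and, independently, one extra window substitution with
  p_adjacent; uniform sequencing errors on top. The default error rate is
  0 — the recovery analyses estimate the editing rates themselves, and a
  uniform error floor would bias the adjacent-site estimator upward by
  ~window-size × error; a nonzero rate is available for robustness tests.
  Defaults (conversion 0.30, indel 0.10, adjacent 0.05, n=5000) are the
  conditions used by the recovery analyses.
* **Caller tables** — planted true variants (appearing in all three
  callers; the dropout knob defaults to 0, and consensus recovery is
  guaranteed only there) plus per-caller private false positives and
  per-caller AF jitter.
* **Methylomes** — per element a baseline level in [0.05, 0.45]; planted
  elements add Δ=0.45 in group A. Replicate means scatter with σ=0.05,
  per-CpG levels with σ=0.05 around them, and counts are binomial at
  coverage floor 3 + Poisson(12). 6–14 CpGs per 1-kb element.

What the generators do *not* emulate: sequencer-specific error profiles,
PCR duplicates, mapping artifacts, bisulfite non-conversion, and genuine
biological covariance between neighbouring elements. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to real-data artifacts.

## Problem sizes in the checks

The acceptance analyses use 200 toy genes for designer/oracle equivalence, a
100-kb genome with 20 guides at ≤3 mismatches for the off-target scan, 5000
reads × 100 seeds for amplicon recovery, 100 replicates × 500 simulations
for burden-test calibration, and 400 elements (20 % planted) for
hypermethylation recovery — sizes at which the brute-force oracles remain
exact and fast while the stochastic checks have enough replication to be
stable across seeds.

## Known limitations

* No bulge (gapped) off-target alignment and no CFD/MIT specificity scores.
* The efficiency heuristic is a transparent stand-in ranking, not a trained
  predictor; its absolute values carry no calibrated meaning.
* Genotype labels depend on the declared thresholds (all-clones rule,
  het fraction 0.25); real mosaic embryos form a continuum.
* The burden test's "transcribed region" interval set is caller-supplied;
  the package does not derive it from annotation databases.
* Linear-scan genome handling: suitable for toy/desk-scale genomes, not for
  mammalian-genome-scale design (out of scope).
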