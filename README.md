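# stopcall

Design and evaluation toolkit for **stop-codon-introducing cytosine base
editing** (CRISPR-STOP / iSTOP-style gene inactivation).

Cytosine base editors (nCas9–deaminase fusions) convert C·G to T·A within a
window of the protospacer without double-strand breaks. Four sense codons can
thereby become premature stop codons — CAA→TAA, CAG→TAG, CGA→TGA on the
coding strand, and TGG→TAA (plus the implied single-edit TAG/TGA) through
editing of the opposite strand. Knocking genes out this way in zygotes gives
cleaner genotypes than indel-based disruption, and multiplexing several
sgRNAs can inactivate an entire gene family in one injection.

`stopcall` is written for people running or analysing such screens. It
covers:

* **Guide design** (`stop_designer`) — enumerate every sgRNA whose editing
  window covers the cytosines that convert a CDS codon into a stop, over
  whole genes from FASTA + GFF3 (`annotation_io`); predict bystander
  amino-acid effects; score with a transparent position/context heuristic;
  rank by off-target burden, score and truncation position.
* **Off-target search** (`offtarget_search`) — exhaustive mismatch-tolerant
  protospacer+PAM scan of a genome (Cas-OFFinder-style; no bulges).
* **Editing outcomes** (`amplicon_quant`) — C→T conversion, indel and
  adjacent-site mutation rates from amplicon reads; clone-based embryo
  genotyping (homozygous / heterozygous / mosaic / wildtype) and cohort
  aggregation.
* **Genome-wide off-target burden** (`offtarget_burden`) — 3-caller
  consensus de-novo variants, AF >10 % and known-site filtering, and a
  Fisher's exact test of transcribed-region enrichment against 10,000
  random-loci simulations; overlap with predicted off-target sites.
* **WGBS summaries** (`methylation_summary`) — 1-kb tile methylation
  (≥3 CpGs at ≥3X), sample similarity (1 − min-max-normalized Euclidean
  distance), promoter/element methylation (TSS±2 kb), and
  hypermethylated-element calls (difference >30 %, p<0.05).
* **Synthetic data** (`sim_data`) — seeded generators for all of the above
  with planted ground truth, so every analysis runs end-to-end offline.

The scientific model, parameter defaults and validation strategy are
documented in [docs/methods.md](docs/methods.md).

## Worked example

Simulate a toy genome with planted convertible codons, design guides for one
gene, and scan for off-targets:

```console
$ stopcall simulate --preset design --seed 3 --out sim
preset design -> sim
$ stopcall design --fasta sim/genome.fa --gff sim/genes.gff3 --gene gene1 --out guides.tsv
3 candidates -> guides.tsv
$ head -3 guides.tsv | cut -f1-12
transcript_id  contig  start  end  strand  protospacer           pam  codon_index  source_codon  result_codon  required_positions  efficiency_score
tx1            chr1    69     89   +       TCTCTCAATCACTCACAAGC  AGG  8            CAA           TAA           6                   1.000000
tx1            chr1    93     113  +       AGCTACAAACTGCGAAACGA  AGG  16           CAA           TAA           6                   0.800000
```

The first candidate places a CAA codon's cytosine at protospacer position 6
(the centre of the default [4,8] editing window) in a TC dinucleotide
context, so the efficiency heuristic scores it 1.0; editing it converts
codon 8 of `tx1` to TAA, truncating the protein at 25 % of its length.

```console
$ stopcall offtarget --fasta sim/genome.fa --guides guides.tsv --mm 3 --out ot.tsv
off-target table -> ot.tsv
$ head -3 ot.tsv
guide                 contig  position  site                  strand  mismatches
TCTCTCAATCACTCACAAGC  chr1    69        TCTCTCAATCACTCACAAGC  +       0
AGCTACAAACTGCGAAACGA  chr1    93        AGCTACAAACTGCGAAACGA  +       0
```

Each guide's 0-mismatch self-hit at its design locus confirms the scan; any
additional rows would be candidate off-target sites at ≤3 mismatches.

The other subcommands follow the same pattern: `stopcall quantify` turns a
FASTQ of amplicon reads into conversion/indel/adjacent rates, `stopcall
goit` runs the consensus-and-burden pipeline on three caller VCFs, and
`stopcall methdiff` calls hypermethylated elements between two replicate
groups of CpG tables. `stopcall simulate --preset {design,amplicon,goit,meth}`
writes matching inputs for each.

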