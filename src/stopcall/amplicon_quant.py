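"""Quantification of base-editing outcomes from amplicon reads.

Three per-amplicon metrics are computed, mirroring how editing outcomes are
summarised from targeted deep sequencing of injected embryos:

* conversion rate — fraction of non-indel reads carrying the intended C->T
  at each target position;
* indel rate — fraction of reads with an insertion/deletion overlapping the
  quantification window (the protospacer padded by ``window_pad``);
* adjacent-site mutation rate — fraction of non-indel reads with at least one
  unintended substitution inside the window.

Clone (Sanger) sequences from blunt-cloned amplicons are called per clone and
combined into an embryo genotype label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

GENOTYPE_LABELS = ("homozygous_stop", "heterozygous", "mosaic", "wildtype")
CLONE_CALLS = ("intended_stop", "wildtype", "other")

#: Alignment scores: match +2, mismatch -3, affine gaps open -6 / extend -1.
#: In Biopython's convention the opening position also pays the extension, so
#: a length-k gap costs 6 + k.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -7, -1


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with the protospacer placement and target C(s).

    ``protospacer_interval`` is 0-based half-open in amplicon coordinates and
    ``target_positions`` are amplicon coordinates of the cytosines whose C->T
    conversion creates the stop codon (protospacer-strand orientation: the
    amplicon sequence is stored so that targets read 'C' and edits read 'T').
    """

    sequence: str
    protospacer_interval: tuple[int, int]
    target_positions: tuple[int, ...]
    contig: str | None = None
    offset: int | None = None
    expected_alt: str = "T"

    def __post_init__(self) -> None:
        start, end = self.protospacer_interval
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError("protospacer interval outside amplicon")
        for pos in self.target_positions:
            if not (start <= pos < end):
                raise ValueError(f"target position {pos} outside protospacer")
            if self.sequence[pos] != "C":
                raise ValueError(
                    f"reference base at target {pos} is {self.sequence[pos]!r}, "
                    "expected 'C'"
                )

    def window(self, pad: int) -> tuple[int, int]:
        start, end = self.protospacer_interval
        return max(0, start - pad), min(len(self.sequence), end + pad)


@dataclass(frozen=True)
class AlignedRead:
    """Alignment of one read to the amplicon, in reference coordinates.

    ``substitutions`` maps ref position -> read base; ``insertions`` holds
    (ref position before which bases were inserted, length); ``deletions``
    holds (ref start, length). Gaps are left-shifted (indel normalization).
    """

    substitutions: dict[int, str]
    insertions: tuple[tuple[int, int], ...]
    deletions: tuple[tuple[int, int], ...]

    @property
    def n_edits(self) -> int:
        return len(self.substitutions) + len(self.insertions) + len(self.deletions)

    def has_indel_in(self, window: tuple[int, int]) -> bool:
        lo, hi = window
        for pos, _length in self.insertions:
            if lo <= pos <= hi:  # insertion at the boundary touches the window
                return True
        for start, length in self.deletions:
            if start < hi and start + length > lo:
                return True
        return False


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner

_ALIGNER = _make_aligner()


def _left_shift(ops: list[list], ref: str, read: str) -> None:
    """Left-normalize indels in place: slide each gap left while the base
    entering from the left equals the base leaving on the right."""
    for op in ops:
        kind, pos, payload = op
        if kind == "D":
            length = payload
            while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
                pos -= 1
            op[1] = pos
        elif kind == "I":
            seq = payload
            while pos > 0 and ref[pos - 1] == seq[-1]:
                seq = ref[pos - 1] + seq[:-1]
                pos -= 1
            op[1], op[2] = pos, seq


def align_read(read: str, ref: AmpliconReference) -> AlignedRead:
    """Globally align one read to the amplicon reference.

    Equal-length pairs are compared column-wise without gaps (with the scores
    used here a gapped alignment of equal-length sequences is never optimal
    at realistic mismatch densities); unequal lengths run the affine-gap DP.
    Mismatch is preferred over a gap pair on ties and gaps are left-shifted.
    """
    if not read or not ref.sequence:
        raise ValueError("empty read or reference")
    refseq = ref.sequence
    read = read.upper()
    if len(read) == len(refseq):
        subs = {i: b for i, (a, b) in enumerate(zip(refseq, read)) if a != b}
        return AlignedRead(substitutions=subs, insertions=(), deletions=())

    aln = _ALIGNER.align(refseq, read)[0]
    ref_blocks, read_blocks = aln.aligned
    ops: list[list] = []
    subs: dict[int, str] = {}
    prev_ref_end, prev_read_end = 0, 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, read_blocks):
        if rs > prev_ref_end:
            ops.append(["D", prev_ref_end, rs - prev_ref_end])
        if qs > prev_read_end:
            ops.append(["I", prev_ref_end, read[prev_read_end:qs]])
        for i in range(re_ - rs):
            if refseq[rs + i] != read[qs + i]:
                subs[rs + i] = read[qs + i]
        prev_ref_end, prev_read_end = re_, qe
    if prev_ref_end < len(refseq):
        ops.append(["D", prev_ref_end, len(refseq) - prev_ref_end])
    if prev_read_end < len(read):
        ops.append(["I", prev_ref_end, read[prev_read_end:]])
    _left_shift(ops, refseq, read)
    insertions = tuple((pos, len(seq)) for kind, pos, seq in ops if kind == "I")
    deletions = tuple((pos, length) for kind, pos, length in ops if kind == "D")
    return AlignedRead(substitutions=subs, insertions=insertions, deletions=deletions)


@dataclass
class EditOutcome:
    """Per-amplicon editing metrics.

    Read classes {intended-only, adjacent-mutated, indel, unedited} partition
    the reads; conversion and adjacent rates are computed over non-indel
    reads only.
    """

    n_reads: int
    conversion_rate: dict[int, float]
    indel_rate: float
    adjacent_site_rate: float
    class_counts: dict[str, int]
    per_position: pd.DataFrame = field(repr=False, default=None)

    @property
    def mean_conversion(self) -> float:
        return float(np.mean(list(self.conversion_rate.values())))


def quantify_edits(
    reads: list[str], ref: AmpliconReference, window_pad: int = 5
) -> EditOutcome:
    """Quantify editing outcomes over a read set.

    Indel reads (>=1 insertion/deletion overlapping the padded window) are
    excluded from the conversion and adjacent-site denominators; indels
    elsewhere in the amplicon are ignored as amplification artifacts.
    """
    if not reads:
        raise ValueError("no reads to quantify")
    window = ref.window(window_pad)
    lo, hi = window
    targets = set(ref.target_positions)

    n_indel = 0
    n_adjacent = 0
    intended_counts = {pos: 0 for pos in ref.target_positions}
    n_intended_only = 0
    base_counts = np.zeros((hi - lo, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate("ACGT")}

    # Fast path: batch equal-length reads through one numpy comparison.
    refseq = ref.sequence
    ref_arr = np.frombuffer(refseq.encode(), dtype=np.uint8)
    equal_len = [r for r in reads if len(r) == len(refseq)]
    other = [r for r in reads if len(r) != len(refseq)]

    if equal_len:
        mat = np.frombuffer("".join(equal_len).encode(), dtype=np.uint8)
        mat = mat.reshape(len(equal_len), len(refseq))
        win = mat[:, lo:hi]
        for j, b in enumerate("ACGT"):
            base_counts[:, base_index[b]] += (win == ord(b)).sum(axis=0)
        diff = win != ref_arr[lo:hi]
        target_cols = np.array(sorted(targets)) - lo
        is_t = win[:, target_cols] == ord("T")
        intended_all = is_t.all(axis=1)
        for k, pos in enumerate(sorted(targets)):
            intended_counts[pos] += int(is_t[:, k].sum())
        nontarget_cols = np.array(
            [j for j in range(hi - lo) if j + lo not in targets], dtype=int
        )
        adjacent = (
            diff[:, nontarget_cols].any(axis=1)
            if nontarget_cols.size
            else np.zeros(len(equal_len), dtype=bool)
        )
        n_adjacent += int(adjacent.sum())
        n_intended_only += int((intended_all & ~adjacent).sum())

    for read in other:
        aln = align_read(read, ref)
        if aln.has_indel_in(window):
            n_indel += 1
            continue
        intended_all = True
        adjacent = False
        for pos in range(lo, hi):
            if pos in aln.substitutions:
                base = aln.substitutions[pos]
            else:
                base = refseq[pos]
            if base in base_index:
                base_counts[pos - lo, base_index[base]] += 1
            if pos in targets:
                if base == ref.expected_alt:
                    intended_counts[pos] += 1
                else:
                    intended_all = False
            elif pos in aln.substitutions:
                adjacent = True
        if adjacent:
            n_adjacent += 1
        elif intended_all:
            n_intended_only += 1

    n_reads = len(reads)
    n_non_indel = n_reads - n_indel
    if n_non_indel == 0:
        conversion = {pos: float("nan") for pos in ref.target_positions}
        adjacent_rate = float("nan")
    else:
        conversion = {
            pos: intended_counts[pos] / n_non_indel for pos in ref.target_positions
        }
        adjacent_rate = n_adjacent / n_non_indel

    per_position = pd.DataFrame(
        base_counts, index=pd.RangeIndex(lo, hi, name="position"),
        columns=list("ACGT"),
    )
    class_counts = {
        "indel": n_indel,
        "adjacent_mutated": n_adjacent,
        "intended_only": n_intended_only,
        "unedited": n_non_indel - n_adjacent - n_intended_only,
    }
    assert sum(class_counts.values()) == n_reads
    return EditOutcome(
        n_reads=n_reads,
        conversion_rate=conversion,
        indel_rate=n_indel / n_reads,
        adjacent_site_rate=adjacent_rate,
        class_counts=class_counts,
        per_position=per_position,
    )


@dataclass
class EmbryoGenotype:
    """Genotype of one embryo derived from blunt-cloned allele sequences."""

    n_clones: int
    clone_calls: list[str]
    label: str
    low_confidence: bool = False


def call_clone(seq: str, ref: AmpliconReference, window_pad: int = 5) -> str:
    """Call one clone: intended_stop / wildtype / other.

    intended_stop: the intended C->T at every target and nothing else in the
    window; wildtype: window identical to the reference; other: anything else
    (extra substitutions, partial conversion, indels).
    """
    aln = align_read(seq, ref)
    window = ref.window(window_pad)
    lo, hi = window
    if aln.has_indel_in(window):
        return "other"
    window_subs = {p: b for p, b in aln.substitutions.items() if lo <= p < hi}
    targets = set(ref.target_positions)
    if not window_subs:
        return "wildtype"
    if set(window_subs) == targets and all(
        window_subs[p] == ref.expected_alt for p in targets
    ):
        return "intended_stop"
    return "other"


def classify_genotype(
    clone_seqs: list[str],
    ref: AmpliconReference,
    min_clones: int = 13,
    het_min_frac: float = 0.25,
    window_pad: int = 5,
) -> EmbryoGenotype:
    """Combine clone calls into an embryo genotype label.

    homozygous_stop: all clones intended_stop; wildtype: all wildtype;
    heterozygous: exactly two call classes, each >= ``het_min_frac`` of
    clones; otherwise mosaic. Fewer than ``min_clones`` clones yields a
    low-confidence label with a warning (the bench protocol sequences >13
    clones per embryo).
    """
    if not clone_seqs:
        raise ValueError("no clone sequences")
    calls = [call_clone(s, ref, window_pad) for s in clone_seqs]
    n = len(calls)
    low_confidence = n < min_clones
    if low_confidence:
        logger.warning("only %d clones (<%d): low-confidence genotype", n, min_clones)
    counts = {c: calls.count(c) for c in set(calls)}
    if counts.get("intended_stop", 0) == n:
        label = "homozygous_stop"
    elif counts.get("wildtype", 0) == n:
        label = "wildtype"
    elif len(counts) == 2 and all(v / n >= het_min_frac for v in counts.values()):
        label = "heterozygous"
    else:
        label = "mosaic"
    return EmbryoGenotype(
        n_clones=n, clone_calls=calls, label=label, low_confidence=low_confidence
    )


def aggregate_genotypes(
    embryos: list[EmbryoGenotype | list[EmbryoGenotype]],
) -> dict:
    """Summarise embryo genotypes.

    Each element is either one EmbryoGenotype or, for multi-locus
    experiments, a list of per-locus genotypes; an embryo counts as
    homozygous only if homozygous_stop at every locus. percent_homozygous is
    rounded half-up to one decimal (9 of 16 -> 56.3).
    """
    if not embryos:
        raise ValueError("no embryos to aggregate")
    counts = {label: 0 for label in GENOTYPE_LABELS}
    n_hom = 0
    for item in embryos:
        loci = item if isinstance(item, (list, tuple)) else [item]
        labels = {g.label for g in loci}
        if labels == {"homozygous_stop"}:
            n_hom += 1
            counts["homozygous_stop"] += 1
        elif labels == {"wildtype"}:
            counts["wildtype"] += 1
        elif labels <= {"homozygous_stop", "heterozygous", "wildtype"} and (
            "heterozygous" in labels
        ):
            counts["heterozygous"] += 1
        else:
            counts["mosaic"] += 1
    n = len(embryos)
    percent = float(
        (Decimal(100) * Decimal(n_hom) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )
    return {
        "n_embryos": n,
        "counts": counts,
        "n_homozygous": n_hom,
        "percent_homozygous": percent,
    }


def read_fastq(path) -> list[str]:
    """Read sequences from FASTQ (or one-sequence-per-line text)."""
    from Bio import SeqIO

    path = str(path)
    if path.endswith((".fastq", ".fq")):
        return [str(rec.seq).upper() for rec in SeqIO.parse(path, "fastq")]
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]
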