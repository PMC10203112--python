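"""Enumeration and ranking of stop-codon-introducing base-editor sgRNAs.

A cytosine base editor (CBE) converts C·G to T·A within a window of the
protospacer counted from its PAM-distal (5') end. Four sense codons can be
converted into premature stops this way:

    CAA -> TAA and CAG -> TAG and CGA -> TGA   (C->T on the coding strand)
    TGG -> TAG / TGA / TAA                     (G->A, i.e. C->T on the
                                                opposite strand)

The designer enumerates every genomic protospacer placement (with a matching
PAM) whose editing window covers all cytosines required for one such
conversion, predicts bystander consequences for the other window cytosines,
scores each guide with a transparent positional/context heuristic, and ranks
candidates by predicted off-target burden, score and truncation position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .annotation_io import (
    CodingSequence,
    GenomeAssembly,
    TranscriptModel,
    reverse_complement,
    spliced_cds,
    translate,
)

logger = logging.getLogger(__name__)

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Dinucleotide-context weights for the base 5' of an edited C (deaminase
#: preference: TC > CC > AC >> GC).
CONTEXT_WEIGHTS = {"T": 1.0, "C": 0.9, "A": 0.8, "G": 0.5}
#: Context weight used when the 5' neighbour is unknown (N or contig edge).
DEFAULT_CONTEXT_WEIGHT = 0.8
#: Per-additional-required-edit penalty.
MULTI_EDIT_PENALTY = 0.8
#: Version tag for the scoring configuration so outputs are pinnable.
SCORE_VERSION = "stopcall-heuristic-1"

#: Guides truncating within the final fraction of the protein are flagged.
LATE_TRUNCATION_FRACTION = 0.95


def matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    try:
        return all(base in IUPAC[p] for base, p in zip(seq, pattern))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern {pattern!r}") from exc


@dataclass(frozen=True)
class BaseEditorProfile:
    """Editor geometry: guide length, PAM patterns, editing window.

    ``window`` is an inclusive [lo, hi] pair of protospacer positions counted
    1-based from the PAM-distal (5') end.
    """

    name: str = "BE3"
    guide_length: int = 20
    pam_patterns: tuple[str, ...] = ("NGG",)
    window: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (1 <= lo <= hi <= self.guide_length):
            raise ValueError(f"invalid editing window {self.window}")
        if not self.pam_patterns:
            raise ValueError("pam_patterns must be non-empty")
        for pat in self.pam_patterns:
            if not pat or not set(pat) <= set(IUPAC):
                raise ValueError(f"invalid PAM pattern {pat!r}")


#: Named editor profiles. Windows/PAMs are package configuration: the BE3
#: family uses the canonical positions 4-8 window; the hyperactive hA3A
#: deaminase (Y130F-narrowed) is given a wider 3-10 window; xCas9 editors
#: accept relaxed PAMs.
PROFILES = {
    "BE3": BaseEditorProfile("BE3"),
    "BE4": BaseEditorProfile("BE4"),
    "hA3A-eBE3-Y130F": BaseEditorProfile("hA3A-eBE3-Y130F", window=(3, 10)),
    "xCas9-BE": BaseEditorProfile("xCas9-BE", pam_patterns=("NG", "GAA", "GAT")),
}

DEFAULT_PROFILE = PROFILES["BE3"]


@dataclass(frozen=True)
class StopConversionRule:
    """One way a sense codon becomes a stop codon under C->T editing.

    ``edit_strand`` is 'sense' when the protospacer lies on the coding strand
    (CDS C->T) and 'antisense' when it lies opposite (CDS G->A).
    ``canonical`` marks the conversions of the published CAA/CAG/CGA/TGG ->
    TAA/TAG/TGA/TAA table; the single-edit TGG variants are chemically implied
    extras users may filter out.
    """

    source_codon: str
    edit_strand: str
    edited_offsets: frozenset[int]
    result_codon: str
    canonical: bool = True

    def apply(self, codon: str) -> str:
        out = list(codon)
        for o in self.edited_offsets:
            out[o] = "T" if self.edit_strand == "sense" else "A"
        return "".join(out)


STOP_RULES: tuple[StopConversionRule, ...] = (
    StopConversionRule("CAA", "sense", frozenset({0}), "TAA"),
    StopConversionRule("CAG", "sense", frozenset({0}), "TAG"),
    StopConversionRule("CGA", "sense", frozenset({0}), "TGA"),
    StopConversionRule("TGG", "antisense", frozenset({1, 2}), "TAA"),
    StopConversionRule("TGG", "antisense", frozenset({1}), "TAG", canonical=False),
    StopConversionRule("TGG", "antisense", frozenset({2}), "TGA", canonical=False),
)

_RULES_BY_CODON: dict[str, tuple[StopConversionRule, ...]] = {}
for _rule in STOP_RULES:
    _RULES_BY_CODON.setdefault(_rule.source_codon, ())
    _RULES_BY_CODON[_rule.source_codon] += (_rule,)


@dataclass(frozen=True)
class BystanderEffect:
    """Consequence of editing a non-required window cytosine."""

    window_position: int
    genomic_position: tuple[str, int]
    cds_index: int | None
    codon_change: tuple[str, str] | None
    aa_change: tuple[str, str, str]  # (ref_aa, alt_aa, category)


@dataclass
class GuideCandidate:
    """A protospacer+PAM placement that introduces a premature stop codon."""

    protospacer: str
    pam: str
    contig: str
    interval: tuple[int, int]
    strand: str
    transcript_id: str
    codon_index: int
    rule: StopConversionRule
    required_window_positions: tuple[int, ...]
    truncation_fraction: float
    bystanders: list[BystanderEffect] = field(default_factory=list)
    efficiency_score: float = 0.0
    offtarget_counts: dict[int, int] = field(default_factory=dict)
    late_truncation: bool = False

    @property
    def key(self) -> tuple:
        return (self.contig, self.interval, self.strand, self.rule)

    def genomic_position(self, window_position: int) -> int:
        """Genomic coordinate of 1-based protospacer position ``window_position``."""
        start, end = self.interval
        if self.strand == "+":
            return start + window_position - 1
        return end - window_position


def enumerate_stop_codons(
    cds: CodingSequence,
) -> list[tuple[int, StopConversionRule]]:
    """List every (codon_index, rule) that can create a premature stop.

    The start codon and the native stop are excluded; codons containing N
    are skipped with a warning.
    """
    if cds.n_codons < 2:
        logger.warning("%s: CDS shorter than 2 codons", cds.transcript_id)
        return []
    out: list[tuple[int, StopConversionRule]] = []
    for idx in range(1, cds.n_codons - 1):
        codon = cds.codon(idx)
        if "N" in codon:
            logger.warning(
                "%s: skipping codon %d containing N", cds.transcript_id, idx
            )
            continue
        for rule in _RULES_BY_CODON.get(codon, ()):
            out.append((idx, rule))
    return out


def _protospacer_strand(rule: StopConversionRule, transcript_strand: str) -> str:
    if rule.edit_strand == "sense":
        return transcript_strand
    return "-" if transcript_strand == "+" else "+"


def _pam_at(genome: GenomeAssembly, contig: str, start: int, end: int, strand: str,
            patterns: tuple[str, ...]) -> str | None:
    """Observed PAM immediately 3' of protospacer [start,end) on ``strand``.

    Returns the PAM string (protospacer-strand orientation) or None.
    """
    seq = genome[contig]
    for pat in patterns:
        plen = len(pat)
        if strand == "+":
            if end + plen > len(seq):
                continue
            pam = seq[end : end + plen]
        else:
            if start - plen < 0:
                continue
            pam = reverse_complement(seq[start - plen : start])
        if "N" in pam:
            continue
        if matches_iupac(pam, pat):
            return pam
    return None


def find_guides(
    t: TranscriptModel,
    genome: GenomeAssembly,
    profile: BaseEditorProfile = DEFAULT_PROFILE,
    cds: CodingSequence | None = None,
    with_bystanders: bool = True,
) -> list[GuideCandidate]:
    """Enumerate all guide candidates for one transcript.

    For each convertible codon and rule, every protospacer placement on the
    rule's strand is reported where the adjacent PAM matches a profile pattern
    and *all* genomic positions of the rule's edited bases fall inside the
    editing window. The protospacer is genomic DNA and may cross intron
    sequence when a codon spans an exon junction.
    """
    if cds is None:
        cds = spliced_cds(t, genome)
    glen = profile.guide_length
    w_lo, w_hi = profile.window
    contig_seq = genome[t.contig]
    out: list[GuideCandidate] = []
    seen: set[tuple] = set()
    n_codons = cds.n_codons

    for codon_index, rule in enumerate_stop_codons(cds):
        strand = _protospacer_strand(rule, t.strand)
        positions = [cds.coord_map[3 * codon_index + o][1] for o in rule.edited_offsets]
        # Feasible protospacer starts where every edited base sits in-window.
        if strand == "+":
            lo = max(p - w_hi + 1 for p in positions)
            hi = min(p - w_lo + 1 for p in positions)
        else:
            lo = max(p + w_lo - glen for p in positions)
            hi = min(p + w_hi - glen for p in positions)
        for start in range(max(lo, 0), min(hi, len(contig_seq) - glen) + 1):
            end = start + glen
            window_seq = contig_seq[start:end]
            if strand == "-":
                proto = reverse_complement(window_seq)
            else:
                proto = window_seq
            if "N" in proto:
                logger.warning(
                    "%s: skipping protospacer with N at %s:%d",
                    t.transcript_id, t.contig, start,
                )
                continue
            pam = _pam_at(
                genome, t.contig, start, end, strand, profile.pam_patterns
            )
            if pam is None:
                continue
            # Dedup key includes the codon: adjacent TGG codons can share a
            # placement+rule while being distinct editing targets.
            key = (t.contig, (start, end), strand, rule, codon_index)
            if key in seen:
                continue
            seen.add(key)
            if strand == "+":
                req = tuple(sorted(p - start + 1 for p in positions))
            else:
                req = tuple(sorted(end - p for p in positions))
            assert all(w_lo <= p <= w_hi for p in req)
            assert all(proto[p - 1] == "C" for p in req)
            cand = GuideCandidate(
                protospacer=proto,
                pam=pam,
                contig=t.contig,
                interval=(start, end),
                strand=strand,
                transcript_id=t.transcript_id,
                codon_index=codon_index,
                rule=rule,
                required_window_positions=req,
                truncation_fraction=codon_index / (n_codons - 1),
            )
            cand.late_truncation = cand.truncation_fraction > LATE_TRUNCATION_FRACTION
            if with_bystanders:
                cand.bystanders = predict_bystanders(
                    cand, cds, genome, t, window=profile.window
                )
            cand.efficiency_score = score_guide(cand, profile)
            out.append(cand)
    return out


def _classify_noncoding(t: TranscriptModel, pos: int) -> str:
    span_lo, span_hi = t.span
    in_exon = any(s <= pos < e for s, e in t.exons)
    if in_exon:
        return "UTR"
    if span_lo <= pos < span_hi:
        return "splice/intronic"
    return "splice/intronic"  # outside the transcript span: treated alike


def predict_bystanders(
    cand: GuideCandidate,
    cds: CodingSequence,
    genome: GenomeAssembly | None = None,
    t: TranscriptModel | None = None,
    window: tuple[int, int] | None = None,
) -> list[BystanderEffect]:
    """Predict consequences of the non-required window cytosines.

    Each window position carrying a C on the protospacer strand (other than
    the required positions) is assumed co-edited; coding consequences are
    computed by substituting the edited base into the CDS and re-translating
    the affected codon. Positions outside the CDS are labelled UTR (exonic)
    or splice/intronic. ``window`` defaults to the default profile's window.
    """
    if window is None:
        window = DEFAULT_PROFILE.window
    w_lo, w_hi = window
    required = set(cand.required_window_positions)
    effects: list[BystanderEffect] = []
    for p in range(w_lo, w_hi + 1):
        if p in required:
            continue
        if cand.protospacer[p - 1] != "C":
            continue
        gpos = cand.genomic_position(p)
        key = (cand.contig, gpos)
        cds_index = cds.back_map.get(key)
        if cds_index is None:
            category = _classify_noncoding(t, gpos) if t is not None else "non-coding"
            effects.append(
                BystanderEffect(p, key, None, None, ("", "", category))
            )
            continue
        codon_i = cds_index // 3
        offset = cds_index % 3
        ref_codon = cds.codon(codon_i)
        # Protospacer strand equals the coding strand iff the CDS base is C.
        alt_base = "T" if ref_codon[offset] == "C" else "A"
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        ref_aa = translate(ref_codon)
        alt_aa = translate(alt_codon)
        if alt_aa == ref_aa:
            category = "silent"
        elif alt_aa == "*":
            category = "nonsense"
        else:
            category = "missense"
        effects.append(
            BystanderEffect(p, key, cds_index, (ref_codon, alt_codon),
                            (ref_aa, alt_aa, category))
        )
    return effects


def score_guide(
    cand: GuideCandidate, profile: BaseEditorProfile = DEFAULT_PROFILE
) -> float:
    """Deterministic editing-efficiency heuristic in [0, 1].

    score = prod over required positions of
                position_weight(p) * context_weight(5' neighbour)
            * MULTI_EDIT_PENALTY ** (k - 1)

    where position_weight is a triangular weight peaking at the window centre
    and context_weight encodes the deaminase's dinucleotide preference
    (TC=1.0, CC=0.9, AC=0.8, GC=0.5).
    """
    w_lo, w_hi = profile.window
    centre = (w_lo + w_hi) / 2.0
    half = (w_hi - w_lo) / 2.0
    score = 1.0
    for p in cand.required_window_positions:
        score *= 1.0 - abs(p - centre) / (half + 1.0)
        if p >= 2:
            neighbour = cand.protospacer[p - 2]
            score *= CONTEXT_WEIGHTS.get(neighbour, DEFAULT_CONTEXT_WEIGHT)
        else:
            score *= DEFAULT_CONTEXT_WEIGHT
    k = len(cand.required_window_positions)
    score *= MULTI_EDIT_PENALTY ** (k - 1)
    return max(0.0, min(1.0, score))


def rank_guides(cands: list[GuideCandidate]) -> list[GuideCandidate]:
    """Stable sort: fewest off-targets at <=2 mismatches, then higher score,
    then earlier truncation, then genomic coordinate."""

    def sort_key(c: GuideCandidate):
        close_ot = sum(n for mm, n in c.offtarget_counts.items() if mm <= 2)
        return (
            close_ot,
            -c.efficiency_score,
            c.truncation_fraction,
            c.contig,
            c.interval,
            c.strand,
        )

    return sorted(cands, key=sort_key)


def pick_design_transcript(
    transcripts: list[TranscriptModel], gene_id: str
) -> TranscriptModel:
    """Default isoform policy: the transcript with the longest CDS."""
    cands = [t for t in transcripts if t.gene_id == gene_id]
    if not cands:
        raise ValueError(f"no transcripts for gene {gene_id!r}")
    return max(cands, key=lambda t: (t.cds_length, t.transcript_id))


def design_gene(
    genome: GenomeAssembly,
    transcripts: list[TranscriptModel],
    gene_id: str,
    profile: BaseEditorProfile = DEFAULT_PROFILE,
    all_isoforms: bool = False,
) -> list[GuideCandidate]:
    """Design guides for a gene (longest-CDS transcript unless all_isoforms)."""
    if all_isoforms:
        targets = [t for t in transcripts if t.gene_id == gene_id]
    else:
        targets = [pick_design_transcript(transcripts, gene_id)]
    out: list[GuideCandidate] = []
    for t in targets:
        out.extend(find_guides(t, genome, profile))
    return out


def guides_to_tsv(cands: list[GuideCandidate], path) -> None:
    cols = (
        "transcript_id\tcontig\tstart\tend\tstrand\tprotospacer\tpam\t"
        "codon_index\tsource_codon\tresult_codon\trequired_positions\t"
        "efficiency_score\ttruncation_fraction\tcanonical\tn_bystanders\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in cands:
            fh.write(
                f"{c.transcript_id}\t{c.contig}\t{c.interval[0]}\t{c.interval[1]}\t"
                f"{c.strand}\t{c.protospacer}\t{c.pam}\t{c.codon_index}\t"
                f"{c.rule.source_codon}\t{c.rule.result_codon}\t"
                f"{','.join(map(str, c.required_window_positions))}\t"
                f"{c.efficiency_score:.6f}\t{c.truncation_fraction:.6f}\t"
                f"{int(c.rule.canonical)}\t{len(c.bystanders)}\n"
            )


def guides_to_bed(cands: list[GuideCandidate], path) -> None:
    """BED6; score = round(1000 * efficiency_score)."""
    with open(path, "w") as fh:
        for c in cands:
            name = f"{c.transcript_id}:{c.codon_index}:{c.rule.result_codon}"
            score = round(1000 * c.efficiency_score)
            fh.write(
                f"{c.contig}\t{c.interval[0]}\t{c.interval[1]}\t{name}\t"
                f"{score}\t{c.strand}\n"
            )
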