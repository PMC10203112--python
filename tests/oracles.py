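"""Independent brute-force oracles and tiny locus builders for the tests.

These deliberately avoid the package's search/placement arithmetic: the
designer oracle enumerates every protospacer window on both strands and every
codon-offset subset whose C->T (or antisense G->A) edit yields a stop codon;
the off-target oracle is a plain Hamming scan with its own IUPAC table.
"""

from __future__ import annotations

import itertools

from stopcall.annotation_io import (
    GenomeAssembly,
    TranscriptModel,
    spliced_cds,
)

STOPS = {"TAA", "TAG", "TGA"}

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC_SETS[p] for b, p in zip(seq, pattern)
    )


def pam_of(seq: str, s: int, e: int, strand: str, patterns) -> str | None:
    for pat in patterns:
        plen = len(pat)
        if strand == "+":
            if e + plen > len(seq):
                continue
            pam = seq[e : e + plen]
        else:
            if s - plen < 0:
                continue
            pam = reverse_complement(seq[s - plen : s])
        if "N" not in pam and iupac_match(pam, pat):
            return pam
    return None


def brute_force_guides(
    t: TranscriptModel,
    genome: GenomeAssembly,
    guide_length: int = 20,
    window: tuple[int, int] = (4, 8),
    pam_patterns=("NGG",),
) -> set[tuple]:
    """All (contig, start, end, strand, codon_index, offsets, stop) placements.

    For every genomic window with a valid PAM, every internal codon and every
    non-empty subset of its in-window editable bases (C on the protospacer
    strand), record the placement if the edit produces a stop codon.
    """
    cds = spliced_cds(t, genome)
    seq = genome.contigs[t.contig]
    n = len(seq)
    w_lo, w_hi = window
    expected: set[tuple] = set()
    for strand in "+-":
        for s in range(0, n - guide_length + 1):
            e = s + guide_length
            proto = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
            if "N" in proto:
                continue
            if pam_of(seq, s, e, strand, pam_patterns) is None:
                continue
            for ci in range(1, cds.n_codons - 1):
                codon = cds.codon(ci)
                if "N" in codon or codon in STOPS:
                    continue
                editable = []
                for o in range(3):
                    _, pos = cds.coord_map[3 * ci + o]
                    wp = pos - s + 1 if strand == "+" else e - pos
                    if not (w_lo <= wp <= w_hi):
                        continue
                    if strand == t.strand and codon[o] == "C":
                        editable.append((o, "T"))
                    elif strand != t.strand and codon[o] == "G":
                        editable.append((o, "A"))
                for r in range(1, len(editable) + 1):
                    for subset in itertools.combinations(editable, r):
                        new = list(codon)
                        for o, b in subset:
                            new[o] = b
                        if "".join(new) in STOPS:
                            expected.add(
                                (
                                    t.contig, s, e, strand, ci,
                                    frozenset(o for o, _ in subset),
                                    "".join(new),
                                )
                            )
    return expected


def guides_as_tuples(cands) -> set[tuple]:
    return {
        (
            c.contig, c.interval[0], c.interval[1], c.strand, c.codon_index,
            c.rule.edited_offsets, c.rule.result_codon,
        )
        for c in cands
    }


def brute_force_offtargets(
    guide: str,
    genome: GenomeAssembly,
    max_mismatches: int,
    pam_patterns=("NGG",),
) -> set[tuple]:
    """All (contig, position, strand, mismatches) sites by plain scanning."""
    glen = len(guide)
    out: set[tuple] = set()
    for contig, seq in genome.contigs.items():
        n = len(seq)
        for strand in "+-":
            for s in range(0, n - glen + 1):
                e = s + glen
                if pam_of(seq, s, e, strand, pam_patterns) is None:
                    continue
                site = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
                if "N" in site:
                    continue
                mm = 0
                for a, b in zip(site, guide):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    out.add((contig, s, strand, mm))
    return out


def build_locus(
    cds_seq: str,
    flank5: str = "",
    flank3: str = "",
    strand: str = "+",
    contig: str = "c1",
    introns: list[tuple[int, str]] | None = None,
) -> tuple[GenomeAssembly, TranscriptModel]:
    """One-transcript genome: CDS with optional introns, placed on a strand.

    ``introns`` is a list of (codon boundary index, intron sequence) inserted
    between codons on the forward-built cassette.
    """
    codons = [cds_seq[i : i + 3] for i in range(0, len(cds_seq), 3)]
    parts: list[str] = []
    cds_rel: list[tuple[int, int]] = []
    cursor = 0
    prev = 0
    cuts = sorted(introns or [])
    for cut, intron in cuts + [(len(codons), "")]:
        exon = "".join(codons[prev:cut])
        cds_rel.append((cursor, cursor + len(exon)))
        parts.append(exon)
        cursor += len(exon)
        if intron:
            parts.append(intron)
            cursor += len(intron)
        prev = cut
    cassette = "".join(parts)
    if strand == "+":
        seq = flank5 + cassette + flank3
        off = len(flank5)
        cds_iv = [(off + s, off + e) for s, e in cds_rel]
    else:
        seq = flank5 + reverse_complement(cassette) + flank3
        off = len(flank5)
        L = len(cassette)
        cds_iv = sorted((off + L - e, off + L - s) for s, e in cds_rel)
    genome = GenomeAssembly({contig: seq})
    t = TranscriptModel(
        transcript_id="t1", gene_id="g1", contig=contig, strand=strand,
        exons=list(cds_iv), cds=list(cds_iv),
    )
    return genome, t
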