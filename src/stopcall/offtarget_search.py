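"""Mismatch-tolerant genome search for sgRNA off-target sites.

A Cas-OFFinder-style exhaustive scan: every genomic window on both strands
with a matching 3' PAM is compared to the guide by Hamming distance (PAM
excluded, no bulges). The scan is a vectorized sliding-window comparison —
at desk scale a full scan is fast and trivially correct.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .annotation_io import GenomeAssembly, reverse_complement
from .stop_designer import IUPAC

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site within the mismatch budget of a guide.

    ``position`` is the 0-based start of the protospacer interval on the
    forward genomic coordinate system; ``site``/``pam`` are reported in
    protospacer-strand orientation; ``mismatch_positions`` are 1-based from
    the 5' end of the protospacer.
    """

    contig: str
    position: int
    strand: str
    site: str
    pam: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.site))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _pam_mask(arr: np.ndarray, pattern: str, offset: int) -> np.ndarray:
    """Boolean mask over window starts whose PAM (starting at start+offset)
    matches ``pattern`` on the given encoded strand array."""
    n = arr.size
    plen = len(pattern)
    starts = n - offset - plen + 1
    if starts <= 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(starts, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = IUPAC[code]
        col = arr[offset + j : offset + j + starts]
        ok = np.zeros(starts, dtype=bool)
        for base in allowed:
            ok |= col == ord(base)
        mask &= ok
    return mask


def _scan_strand(
    seq: str,
    contig: str,
    strand: str,
    contig_len: int,
    guide: str,
    max_mismatches: int,
    pam_patterns: tuple[str, ...],
) -> list[OffTargetHit]:
    glen = len(guide)
    arr = _encode(seq)
    if arr.size < glen + min(len(p) for p in pam_patterns):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, glen)
    guide_arr = _encode(guide)
    mm = (windows != guide_arr).sum(axis=1)
    has_n = (windows == ord("N")).any(axis=1)

    hits: list[OffTargetHit] = []
    seen_starts: set[int] = set()
    for pattern in pam_patterns:
        plen = len(pattern)
        pam_ok = _pam_mask(arr, pattern, glen)
        limit = min(pam_ok.size, mm.size)
        # PAM windows containing N are skipped like site windows.
        pam_view = np.lib.stride_tricks.sliding_window_view(arr, plen)
        pam_has_n = (pam_view == ord("N")).any(axis=1)
        cand = np.flatnonzero(
            pam_ok[:limit]
            & (mm[:limit] <= max_mismatches)
            & ~has_n[:limit]
            & ~pam_has_n[glen : glen + limit]
        )
        for i in cand:
            i = int(i)
            if i in seen_starts:
                continue
            seen_starts.add(i)
            site = seq[i : i + glen]
            pam = seq[i + glen : i + glen + plen]
            mismatches = tuple(
                j + 1 for j in range(glen) if site[j] != guide[j]
            )
            if strand == "+":
                position = i
            else:
                position = contig_len - (i + glen)
            hits.append(
                OffTargetHit(
                    contig=contig,
                    position=position,
                    strand=strand,
                    site=site,
                    pam=pam,
                    mismatch_count=int(mm[i]),
                    mismatch_positions=mismatches,
                )
            )
    return hits


def find_offtargets(
    guide: str,
    genome: GenomeAssembly,
    max_mismatches: int = 3,
    pam_patterns: tuple[str, ...] = ("NGG",),
    guide_length: int | None = None,
) -> list[OffTargetHit]:
    """Report every genomic site within ``max_mismatches`` of ``guide``.

    Both strands are scanned; the PAM must match one pattern exactly under
    IUPAC semantics (no PAM mismatches); windows containing N are skipped.
    The 0-mismatch hit at the design locus is the on-target and is included.
    """
    guide = guide.upper()
    if guide_length is not None and len(guide) != guide_length:
        raise ValueError(
            f"guide length {len(guide)} != profile guide_length {guide_length}"
        )
    if not set(guide) <= set("ACGT"):
        raise ValueError(f"guide contains non-ACGT characters: {guide!r}")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    hits: list[OffTargetHit] = []
    for contig, seq in genome.contigs.items():
        clen = len(seq)
        hits.extend(
            _scan_strand(seq, contig, "+", clen, guide, max_mismatches, pam_patterns)
        )
        hits.extend(
            _scan_strand(
                reverse_complement(seq), contig, "-", clen, guide,
                max_mismatches, pam_patterns,
            )
        )
    hits.sort(key=lambda h: (h.contig, h.position, h.strand))
    return hits


def offtarget_summary(
    hits: list[OffTargetHit],
    design_locus: tuple[str, int, str] | None = None,
) -> dict[int, int]:
    """Per-mismatch-count site counts for one guide, on-target excluded.

    ``design_locus`` is (contig, position, strand) of the designed placement;
    when omitted, every 0-mismatch hit is treated as the on-target.
    """
    if len(set(hits)) != len(hits):
        raise ValueError("duplicate off-target hit records")
    counts: Counter[int] = Counter()
    for h in hits:
        if design_locus is None:
            if h.mismatch_count == 0:
                continue
        elif (h.contig, h.position, h.strand) == design_locus and h.mismatch_count == 0:
            continue
        counts[h.mismatch_count] += 1
    return dict(sorted(counts.items()))


def offtargets_to_tsv(guide: str, hits: list[OffTargetHit], path) -> None:
    """Cas-OFFinder-style column order: guide, contig, position, site, strand,
    mismatches."""
    with open(path, "w") as fh:
        fh.write("guide\tcontig\tposition\tsite\tstrand\tmismatches\n")
        for h in hits:
            fh.write(
                f"{guide}\t{h.contig}\t{h.position}\t{h.site}\t{h.strand}\t"
                f"{h.mismatch_count}\n"
            )
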