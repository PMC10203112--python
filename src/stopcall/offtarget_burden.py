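"""Genome-wide off-target burden statistics (GOIT-style).

De-novo variants called independently by three callers are intersected into a
consensus set, filtered on allele frequency (> 10%) and against known-variant
databases, classified into transcribed vs untranscribed regions, and compared
with the proportion of transcribed hits expected for the same number of loci
drawn uniformly at random from the genome (10,000 simulations by default,
Fisher's exact test). The consensus set can also be intersected with
predicted off-target sites from the mismatch search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from scipy.stats import fisher_exact

from .annotation_io import GenomeAssembly
from .offtarget_search import OffTargetHit


@dataclass(frozen=True)
class VariantRecord:
    """One called variant. ``pos`` is 0-based internally (1-based at VCF I/O)."""

    contig: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0,1]")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


def left_normalize(contig: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonicalize an indel representation: trim shared suffix, then shared
    prefix (keeping one anchor base), advancing the position."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (contig, pos, ref, alt)


@dataclass
class ConsensusVariantSet:
    """Variants present in all contributing call sets."""

    variants: list[VariantRecord]
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple]:
        return {v.key for v in self.variants}


def consensus(
    callsets: list[list[VariantRecord]],
    names: tuple[str, ...] | None = None,
) -> ConsensusVariantSet:
    """Intersect three call sets on (contig, pos, ref, alt).

    SNVs and indels are intersected separately (they come from different
    caller trios); indel representations are left-normalized before matching.
    The consensus allele frequency is the mean across callers.
    """
    if len(callsets) != 3:
        raise ValueError(f"expected exactly 3 call sets, got {len(callsets)}")
    if names is None:
        names = tuple(f"caller{i + 1}" for i in range(3))

    def norm_key(v: VariantRecord) -> tuple:
        if v.vtype == "indel":
            return left_normalize(v.contig, v.pos, v.ref, v.alt)
        return v.key

    maps = []
    for cs in callsets:
        m: dict[tuple, VariantRecord] = {}
        for v in cs:
            m[norm_key(v)] = v
        maps.append(m)
    shared = set(maps[0]) & set(maps[1]) & set(maps[2])
    out = []
    for key in sorted(shared):
        contig, pos, ref, alt = key
        af = float(np.mean([m[key].allele_frequency for m in maps]))
        out.append(VariantRecord(contig, pos, ref, alt, af))
    return ConsensusVariantSet(variants=out, provenance=tuple(names))


@dataclass
class KnownSites:
    """Known-variant exclusion lists (dbSNP/MGP-style): exact sites and/or
    BED intervals."""

    sites: set[tuple[str, int]] = field(default_factory=set)
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __contains__(self, item: tuple[str, int]) -> bool:
        contig, pos = item
        if (contig, pos) in self.sites:
            return True
        for start, end in self.intervals.get(contig, ()):
            if start <= pos < end:
                return True
        return False

    @classmethod
    def from_bed(cls, path) -> "KnownSites":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                contig, start, end = line.split("\t")[:3]
                intervals.setdefault(contig, []).append((int(start), int(end)))
        return cls(intervals=intervals)

    @classmethod
    def from_site_tsv(cls, path) -> "KnownSites":
        """Two-column TSV: contig, 1-based position."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return cls(sites={(str(c), int(p) - 1) for c, p in zip(df[0], df[1])})


def filter_variants(
    s: ConsensusVariantSet,
    af_min: float = 0.10,
    known_sites: KnownSites | None = None,
) -> ConsensusVariantSet:
    """Keep variants with allele frequency strictly above ``af_min`` ("more
    than 10%") that do not match any known site."""
    if not (0.0 <= af_min <= 1.0):
        raise ValueError("af_min must be in [0,1]")
    kept = []
    for v in s.variants:
        if v.allele_frequency <= af_min:
            continue
        if known_sites is not None and (v.contig, v.pos) in known_sites:
            continue
        kept.append(v)
    return ConsensusVariantSet(variants=kept, provenance=s.provenance)


@dataclass
class BurdenTestResult:
    """Transcribed-region enrichment test against random-loci simulations."""

    n_variants: int
    n_transcribed: int
    observed_proportion: float
    expected_proportions: np.ndarray
    fisher_p: float
    seed: int | None

    @property
    def expected_proportion(self) -> float:
        return float(np.mean(self.expected_proportions))


def _merged_bounds(intervals: dict[str, list[tuple[int, int]]]):
    """Merge intervals per contig and return sorted flat boundary arrays."""
    out = {}
    for contig, ivs in intervals.items():
        merged: list[tuple[int, int]] = []
        for start, end in sorted(ivs):
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
            else:
                merged.append((start, end))
        bounds = np.array([b for iv in merged for b in iv], dtype=np.int64)
        out[contig] = bounds
    return out


def _in_intervals(bounds: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Membership of positions in merged half-open intervals, vectorized."""
    if bounds.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    idx = np.searchsorted(bounds, positions, side="right")
    return idx % 2 == 1


def _sample_unique(rng: np.random.Generator, n: int, total: int) -> np.ndarray:
    """Draw n distinct integers from [0, total) without an O(total) shuffle."""
    if n > total:
        raise ValueError("cannot draw more loci than genome positions")
    chosen = np.unique(rng.integers(0, total, size=int(n * 1.5) + 16))
    while chosen.size < n:
        extra = rng.integers(0, total, size=n)
        chosen = np.unique(np.concatenate([chosen, extra]))
    return rng.permutation(chosen)[:n]


def burden_test(
    s: ConsensusVariantSet,
    transcribed: dict[str, list[tuple[int, int]]],
    genome: GenomeAssembly,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> BurdenTestResult:
    """Test whether consensus variants are enriched in transcribed regions.

    Each simulation draws ``len(s)`` loci uniformly (without replacement,
    over non-N genome positions) and records the transcribed proportion; the
    expected proportion is the mean over simulations. A two-sided Fisher's
    exact test compares the observed counts against the pooled simulated
    counts: [[obs_tx, obs_untx], [sim_tx_total, sim_untx_total]] over all
    n_sim * n simulated loci, so the reference row carries the simulation's
    full precision and the test is calibrated near its nominal level.
    """
    n = len(s)
    if n == 0:
        raise ValueError("empty variant set: transcribed proportion undefined")
    bounds = _merged_bounds(transcribed)

    # Global coordinate space over non-N positions of all contigs.
    contig_names = list(genome.contigs)
    offsets = np.cumsum([0] + [len(genome.contigs[c]) for c in contig_names])
    total = int(offsets[-1])
    non_n: np.ndarray | None = None
    if any("N" in genome.contigs[c] for c in contig_names):
        mask = np.concatenate(
            [
                np.frombuffer(genome.contigs[c].encode(), dtype=np.uint8) != ord("N")
                for c in contig_names
            ]
        )
        non_n = np.flatnonzero(mask)
        total = int(non_n.size)

    n_tx = 0
    for v in s.variants:
        b = bounds.get(v.contig)
        if b is not None and _in_intervals(b, np.array([v.pos]))[0]:
            n_tx += 1
    observed = n_tx / n

    rng = np.random.default_rng(seed)
    expected = np.empty(n_sim, dtype=float)
    for i in range(n_sim):
        flat = _sample_unique(rng, n, total)
        if non_n is not None:
            flat = non_n[flat]
        cidx = np.searchsorted(offsets, flat, side="right") - 1
        inside = np.zeros(n, dtype=bool)
        for ci in np.unique(cidx):
            sel = cidx == ci
            b = bounds.get(contig_names[ci])
            if b is None:
                continue
            inside[sel] = _in_intervals(b, flat[sel] - offsets[ci])
        expected[i] = inside.mean()

    sim_total = n * n_sim
    sim_tx = int(round(float(expected.sum()) * n))  # sum of per-sim counts
    table = [[n_tx, n - n_tx], [sim_tx, sim_total - sim_tx]]
    _, p = fisher_exact(table, alternative="two-sided")
    return BurdenTestResult(
        n_variants=n,
        n_transcribed=n_tx,
        observed_proportion=observed,
        expected_proportions=expected,
        fisher_p=float(p),
        seed=seed,
    )


def overlap_predicted(
    s: ConsensusVariantSet,
    predicted: list[OffTargetHit],
    pad: int = 0,
) -> tuple[int, list[tuple[VariantRecord, OffTargetHit]]]:
    """Count variants falling within a predicted off-target protospacer
    interval padded by ``pad`` nt; returns (count, matched pairs)."""
    pairs = []
    matched_variants = set()
    for v in s.variants:
        for h in predicted:
            if h.contig != v.contig:
                continue
            lo, hi = h.interval
            if lo - pad <= v.pos < hi + pad:
                pairs.append((v, h))
                matched_variants.add(v.key)
    return len(matched_variants), pairs


def read_vcf(path) -> list[VariantRecord]:
    """Read a (minimal) VCF: CHROM POS REF ALT with AF in INFO or sample."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is None:
                raise ValueError(f"{path}: record without AF at {rec.chrom}:{rec.pos}")
            if isinstance(af, tuple):
                af = af[0]
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(rec.chrom, rec.pos - 1, rec.ref, alt, float(af))
                )
    return out


def read_variant_table(path) -> list[VariantRecord]:
    """Read a caller TSV: columns contig, pos (1-based), ref, alt, af."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    required = ["contig", "pos", "ref", "alt", "af"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        VariantRecord(
            str(row[cols["contig"]]), int(row[cols["pos"]]) - 1,
            str(row[cols["ref"]]), str(row[cols["alt"]]),
            float(row[cols["af"]]),
        )
        for _, row in df.iterrows()
    ]


def read_transcribed_bed(path) -> dict[str, list[tuple[int, int]]]:
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split("\t")[:3]
            intervals.setdefault(contig, []).append((int(start), int(end)))
    return intervals
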