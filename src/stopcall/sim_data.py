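"""Seeded generators for every input the toolkit consumes.

Each generator owns an isolated RNG stream keyed on (seed, generator name),
so adding a generator never shifts another's output and a fixed seed yields
byte-identical files across platforms. Ground truth is returned alongside
every simulated data set so recovery tests can compare estimates to the
planted values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon_quant import AmpliconReference
from .annotation_io import GenomeAssembly, TranscriptModel, reverse_complement

STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOPS
)
EDITABLE_SENSE = ("CAA", "CAG", "CGA")
EDITABLE_ALL = EDITABLE_SENSE + ("TGG",)

#: Planted sense codons sit with their C at protospacer position 6 and an
#: AGG codon five codons downstream supplies the NGG PAM; planted TGG codons
#: put their second G at antisense position 6 with an upstream CCA codon
#: supplying the PAM on the opposite strand.
PLANT_WINDOW_POSITION = 6


def stream(seed: int, name: str) -> np.random.Generator:
    """Isolated RNG stream for one generator."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


@dataclass
class GenomeSimConfig:
    n_contigs: int = 5
    contig_length: int = 3000
    gc_fraction: float = 0.42


@dataclass
class GeneSimConfig:
    n_genes: int = 5
    n_exons: tuple[int, int] = (1, 2)
    cds_codons: tuple[int, int] = (30, 50)
    planted_editable_codons: int = 2
    codon_choices: tuple[str, ...] = EDITABLE_ALL
    intron_length: tuple[int, int] = (24, 40)


@dataclass
class AmpliconSimConfig:
    conversion_rate: float = 0.30
    indel_rate: float = 0.10
    adjacent_rate: float = 0.05
    sequencing_error_rate: float = 0.0
    n_reads: int = 5000
    indel_max_len: int = 10


@dataclass
class VariantSimConfig:
    n_planted: int = 30
    indel_fraction: float = 0.2
    af_range: tuple[float, float] = (0.15, 0.90)
    fp_per_caller: int = 10
    af_jitter: float = 0.02
    dropout: float = 0.0


@dataclass
class MethylomeSimConfig:
    n_elements: int = 200
    element_length: int = 1000
    element_gap: int = 1000
    n_cpg_range: tuple[int, int] = (6, 14)
    n_replicates: int = 3
    planted_fraction: float = 0.2
    planted_delta: float = 0.45
    replicate_sigma: float = 0.05
    cpg_sigma: float = 0.05
    baseline_range: tuple[float, float] = (0.05, 0.45)
    coverage_mean: float = 15.0
    coverage_floor: int = 3


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)
    genes: GeneSimConfig = field(default_factory=GeneSimConfig)
    amplicon: AmpliconSimConfig = field(default_factory=AmpliconSimConfig)
    variants: VariantSimConfig = field(default_factory=VariantSimConfig)
    methylome: MethylomeSimConfig = field(default_factory=MethylomeSimConfig)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_codon(rng: np.random.Generator) -> str:
    return _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]


def _build_cds(
    rng: np.random.Generator, cfg: GeneSimConfig
) -> tuple[list[str], list[tuple[int, str]]]:
    """Build a CDS as a codon list with planted editable codons and their
    engineered PAM codons. Returns (codons, [(codon_index, codon_value)])."""
    n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    codons = ["ATG"] + [_random_codon(rng) for _ in range(n_codons - 2)] + ["TAA"]
    k = cfg.planted_editable_codons
    if k == 0:
        return codons, []
    # Sense plants need codons [idx+5] free; TGG plants need [idx-5]; keep
    # plants >= 8 codons from each other and clear of start/stop.
    slots = list(range(8, n_codons - 8, 8))
    if len(slots) < k:
        raise ValueError(
            f"CDS of {n_codons} codons too short for {k} planted codons"
        )
    idxs = sorted(rng.choice(len(slots), size=k, replace=False))
    planted = []
    for i in idxs:
        idx = slots[i]
        codon = cfg.codon_choices[rng.integers(len(cfg.codon_choices))]
        codons[idx] = codon
        if codon == "TGG":
            codons[idx - 5] = "CCA"  # upstream PAM on the antisense strand
        else:
            codons[idx + 5] = "AGG"  # downstream NGG PAM on the sense strand
        planted.append((idx, codon))
    return codons, planted


def _insert_introns(
    rng: np.random.Generator,
    codons: list[str],
    planted: list[tuple[int, str]],
    cfg: GeneSimConfig,
    gc: float,
) -> tuple[str, list[tuple[int, int]]]:
    """Serialize the CDS with 0..n introns at codon boundaries away from the
    planted regions. Returns (gene cassette sequence, CDS intervals relative
    to cassette start)."""
    n_exons = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    n_codons = len(codons)
    forbidden = set()
    for idx, _ in planted:
        forbidden.update(range(idx - 7, idx + 8))
    sites = [i for i in range(4, n_codons - 4) if i not in forbidden]
    cuts = sorted(
        rng.choice(len(sites), size=min(n_exons - 1, len(sites)), replace=False)
    ) if n_exons > 1 and sites else []
    cut_codons = [sites[c] for c in cuts]

    seq_parts: list[str] = []
    cds_intervals: list[tuple[int, int]] = []
    cursor = 0
    prev = 0
    for cut in cut_codons + [n_codons]:
        exon_seq = "".join(codons[prev:cut])
        cds_intervals.append((cursor, cursor + len(exon_seq)))
        seq_parts.append(exon_seq)
        cursor += len(exon_seq)
        if cut < n_codons:
            ilen = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            intron = "GT" + _random_bases(rng, ilen - 4, gc) + "AG"
            seq_parts.append(intron)
            cursor += ilen
        prev = cut
    return "".join(seq_parts), cds_intervals


def make_toy_genome(
    cfg: SimConfig,
) -> tuple[GenomeAssembly, list[TranscriptModel], pd.DataFrame]:
    """Generate a toy genome with planted stop-convertible codons.

    Every planted codon is reachable by at least one guide under the default
    editor profile (window [4,8], NGG): the construction engineers a PAM at a
    compatible distance. The truth table lists per planted codon the gene,
    codon index, codon and the expected protospacer genomic interval/strand.
    """
    g, gn = cfg.genome, cfg.genes
    if gn.planted_editable_codons > 0 and g.gc_fraction == 0:
        raise ValueError("gc_fraction 0 admits no editable codons")
    rng = stream(cfg.seed, "toy_genome")
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    truth_rows = []

    contig_seqs = {
        f"chr{i + 1}": list(_random_bases(rng, g.contig_length, g.gc_fraction))
        for i in range(g.n_contigs)
    }
    cursors = {name: 50 for name in contig_seqs}

    for gi in range(gn.n_genes):
        codons, planted = _build_cds(rng, gn)
        cassette, cds_rel = _insert_introns(rng, codons, planted, gn, g.gc_fraction)
        strand = "+" if rng.integers(2) == 0 else "-"
        contig = f"chr{(gi % g.n_contigs) + 1}"
        offset = cursors[contig]
        if offset + len(cassette) + 50 > g.contig_length:
            raise ValueError(
                "contig_length too small for the configured genes; increase "
                "genome.contig_length or n_contigs"
            )
        cursors[contig] = offset + len(cassette) + int(rng.integers(60, 140))

        if strand == "+":
            placed = cassette
            cds_iv = [(offset + s, offset + e) for s, e in cds_rel]
        else:
            placed = reverse_complement(cassette)
            L = len(cassette)
            cds_iv = sorted(
                (offset + L - e, offset + L - s) for s, e in cds_rel
            )
        contig_seqs[contig][offset : offset + len(cassette)] = list(placed)

        tid, gid = f"tx{gi + 1}", f"gene{gi + 1}"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=list(cds_iv),
                cds=list(cds_iv),
            )
        )

        # Expected protospacer placement for each planted codon. Positions
        # are computed on the cassette then mirrored for '-' genes.
        cassette_pos_of_cds: dict[int, int] = {}
        ci = 0
        for s, e in cds_rel:
            for p in range(s, e):
                cassette_pos_of_cds[ci] = p
                ci += 1
        wp = PLANT_WINDOW_POSITION
        for idx, codon in planted:
            if codon == "TGG":
                # antisense protospacer: 5' end at the offset-2 G
                gpos = cassette_pos_of_cds[3 * idx + 2]
                start_rel = gpos + wp - 20  # interval [start, start+20)
                proto_strand_rel = "-"
            else:
                gpos = cassette_pos_of_cds[3 * idx]
                start_rel = gpos - wp + 1
                proto_strand_rel = "+"
            if strand == "+":
                g_start = offset + start_rel
                proto_strand = proto_strand_rel
            else:
                L = len(cassette)
                g_start = offset + L - (start_rel + 20)
                proto_strand = "+" if proto_strand_rel == "-" else "-"
            truth_rows.append(
                {
                    "gene_id": gid,
                    "transcript_id": tid,
                    "contig": contig,
                    "codon_index": idx,
                    "codon": codon,
                    "proto_start": g_start,
                    "proto_end": g_start + 20,
                    "proto_strand": proto_strand,
                }
            )

    contigs = {name: "".join(seq) for name, seq in contig_seqs.items()}
    truth = pd.DataFrame(truth_rows)
    return GenomeAssembly(contigs), transcripts, truth


def simulate_amplicon_reads(
    ref: AmpliconReference, cfg: AmpliconSimConfig, seed: int
) -> tuple[list[str], dict]:
    """Simulate amplicon reads with known editing outcome rates.

    Each read independently: with probability ``indel_rate`` receives one
    random 1..indel_max_len nt insertion or deletion inside the protospacer
    window; otherwise with probability ``conversion_rate`` carries the
    intended C->T at every target and, independently, with probability
    ``adjacent_rate`` one extra substitution at a non-target window position.
    Uniform sequencing errors are applied at ``sequencing_error_rate``.
    """
    for name in ("conversion_rate", "indel_rate", "adjacent_rate",
                 "sequencing_error_rate"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    rng = stream(seed, "amplicon_reads")
    refseq = ref.sequence
    lo, hi = ref.protospacer_interval
    targets = sorted(ref.target_positions)
    non_targets = [p for p in range(lo, hi) if p not in targets]
    reads: list[str] = []
    n_indel = n_conv = n_adj = 0
    bases = "ACGT"
    for _ in range(cfg.n_reads):
        seq = list(refseq)
        if rng.random() < cfg.indel_rate:
            n_indel += 1
            ilen = int(rng.integers(1, cfg.indel_max_len + 1))
            pos = int(rng.integers(lo, hi))
            if rng.random() < 0.5:
                del seq[pos : pos + ilen]
            else:
                ins = "".join(bases[rng.integers(4)] for _ in range(ilen))
                seq[pos:pos] = list(ins)
        else:
            if rng.random() < cfg.conversion_rate:
                n_conv += 1
                for t in targets:
                    seq[t] = ref.expected_alt
            if non_targets and rng.random() < cfg.adjacent_rate:
                n_adj += 1
                p = non_targets[rng.integers(len(non_targets))]
                current = seq[p]
                seq[p] = bases[(bases.index(current) + 1 + rng.integers(3)) % 4]
        if cfg.sequencing_error_rate > 0:
            err = rng.random(len(seq)) < cfg.sequencing_error_rate
            for i in np.flatnonzero(err):
                seq[i] = bases[(bases.index(seq[i]) + 1 + rng.integers(3)) % 4]
        reads.append("".join(seq))
    truth = {
        "conversion_rate": cfg.conversion_rate,
        "indel_rate": cfg.indel_rate,
        "adjacent_rate": cfg.adjacent_rate,
        "n_indel": n_indel,
        "n_converted": n_conv,
        "n_adjacent": n_adj,
    }
    return reads, truth


def simulate_callsets(
    genome: GenomeAssembly, cfg: VariantSimConfig, seed: int
) -> tuple[list[list], list]:
    """Three caller variant tables with a planted shared truth set.

    True variants appear in all three tables (at dropout 0, the default);
    each caller additionally reports private false positives; allele
    frequencies are jittered per caller.
    """
    from .offtarget_burden import VariantRecord

    rng = stream(seed, "callsets")
    contig_names = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contig_names])
    bases = "ACGT"

    def draw_variant() -> VariantRecord:
        ci = int(rng.choice(len(contig_names), p=lengths / lengths.sum()))
        contig = contig_names[ci]
        pos = int(rng.integers(0, lengths[ci] - 1))
        refbase = genome.contigs[contig][pos]
        if refbase == "N":
            return draw_variant()
        af = float(rng.uniform(*cfg.af_range))
        if rng.random() < cfg.indel_fraction:
            if rng.random() < 0.5:  # deletion
                dlen = int(rng.integers(1, 4))
                ref = genome.contigs[contig][pos : pos + 1 + dlen]
                if "N" in ref or len(ref) < 1 + dlen:
                    return draw_variant()
                return VariantRecord(contig, pos, ref, ref[0], af)
            ins = "".join(bases[rng.integers(4)] for _ in range(rng.integers(1, 4)))
            return VariantRecord(contig, pos, refbase, refbase + ins, af)
        alt = bases[(bases.index(refbase) + 1 + rng.integers(3)) % 4]
        return VariantRecord(contig, pos, refbase, alt, af)

    truth: list = []
    seen = set()
    while len(truth) < cfg.n_planted:
        v = draw_variant()
        if (v.contig, v.pos) in seen:
            continue
        seen.add((v.contig, v.pos))
        truth.append(v)

    callsets: list[list] = []
    for _ci in range(3):
        calls = []
        for v in truth:
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                continue
            af = float(np.clip(v.allele_frequency + rng.normal(0, cfg.af_jitter),
                               0.0, 1.0))
            calls.append(VariantRecord(v.contig, v.pos, v.ref, v.alt, af))
        for _ in range(cfg.fp_per_caller):
            while True:
                fp = draw_variant()
                if (fp.contig, fp.pos) not in seen:
                    break
            seen.add((fp.contig, fp.pos))  # keep false positives private
            calls.append(fp)
        callsets.append(calls)
    return callsets, truth


def make_toy_elements(cfg: MethylomeSimConfig) -> pd.DataFrame:
    """Non-overlapping elements on a single virtual contig."""
    rows = []
    step = cfg.element_length + cfg.element_gap
    for i in range(cfg.n_elements):
        rows.append(
            {
                "element_id": f"el{i + 1}",
                "contig": "chrM1",
                "start": i * step,
                "end": i * step + cfg.element_length,
                "class": "custom",
            }
        )
    return pd.DataFrame(rows)


def simulate_methylomes(
    elements: pd.DataFrame | None, cfg: MethylomeSimConfig, seed: int
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], set, pd.DataFrame]:
    """Per-replicate CpG count tables for two groups with planted hyper
    elements in group A.

    Per element a baseline level is drawn; planted elements get +delta in
    group A. Replicate means scatter around the group mean (sd
    ``replicate_sigma``), per-CpG levels around the replicate mean (sd
    ``cpg_sigma``), and counts are binomial at a coverage of floor +
    Poisson(mean - floor). Returns (group A replicates, group B replicates,
    planted element ids, element table).
    """
    rng = stream(seed, "methylomes")
    if elements is None:
        elements = make_toy_elements(cfg)
    n = len(elements)
    n_planted = int(round(cfg.planted_fraction * n))
    planted_idx = set(
        rng.choice(n, size=n_planted, replace=False).tolist()
    ) if n_planted else set()
    baseline = rng.uniform(*cfg.baseline_range, size=n)

    cpg_positions = []
    for el in elements.to_dict("records"):
        k = int(rng.integers(cfg.n_cpg_range[0], cfg.n_cpg_range[1] + 1))
        pos = np.sort(
            rng.choice(np.arange(el["start"], el["end"]), size=k, replace=False)
        )
        cpg_positions.append(pos)

    def make_rep(group: str) -> pd.DataFrame:
        rows = []
        for i, el in enumerate(elements.to_dict("records")):
            mean = baseline[i] + (
                cfg.planted_delta if group == "A" and i in planted_idx else 0.0
            )
            rep_mean = float(np.clip(rng.normal(mean, cfg.replicate_sigma), 0, 1))
            for pos in cpg_positions[i]:
                level = float(np.clip(rng.normal(rep_mean, cfg.cpg_sigma), 0, 1))
                cov = cfg.coverage_floor + int(
                    rng.poisson(max(cfg.coverage_mean - cfg.coverage_floor, 0))
                )
                meth = int(rng.binomial(cov, level))
                rows.append(
                    {
                        "contig": el["contig"],
                        "pos": int(pos),
                        "meth": meth,
                        "unmeth": cov - meth,
                    }
                )
        return pd.DataFrame(rows)

    group_a = [make_rep("A") for _ in range(cfg.n_replicates)]
    group_b = [make_rep("B") for _ in range(cfg.n_replicates)]
    planted_ids = {elements.iloc[i]["element_id"] for i in planted_idx}
    return group_a, group_b, planted_ids, elements


# ---------------------------------------------------------------------------
# File writers so every CLI command can run end-to-end offline.

def write_fastq(reads: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_vcf(variants: list, path, contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
            fh.write(
                f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"AF={v.allele_frequency:.4f}\n"
            )


def write_bed(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(intervals):
            for start, end in sorted(intervals[contig]):
                fh.write(f"{contig}\t{start}\t{end}\n")


def write_cpg_table(cpgs: pd.DataFrame, path) -> None:
    cpgs[["contig", "pos", "meth", "unmeth"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_elements_bed(elements: pd.DataFrame, path) -> None:
    elements[["contig", "start", "end", "element_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
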