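"""Genome and gene-model I/O.

Reads multi-record FASTA genomes and GFF3 gene models (gene/mRNA/exon/CDS
dialect), assembles spliced coding sequences and keeps a bidirectional map
between CDS indices and genomic coordinates so downstream modules can reason
about edits in either coordinate system.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
from/to the 1-based closed convention of the format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Malformed input file (FASTA/GFF3)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a model invariant."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


@dataclass
class GenomeAssembly:
    """A set of named contigs over the ACGTN alphabet (uppercase)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValidationError("assembly has no contigs")
        for name, seq in self.contigs.items():
            if not name:
                raise ValidationError("empty contig name")
            if not seq:
                raise ValidationError(f"contig {name!r} has empty sequence")
            if not set(seq) <= VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValidationError(f"contig {name!r} has invalid characters {bad}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice a contig; raises if the interval leaves the contig."""
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise ValidationError(
                f"interval [{start},{end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def reverse_complemented(self) -> "GenomeAssembly":
        """Mirror assembly used by strand-symmetry checks."""
        return GenomeAssembly(
            {name: reverse_complement(seq) for name, seq in self.contigs.items()}
        )


@dataclass
class TranscriptModel:
    """Exon/CDS intervals and strand defining a spliced reading frame.

    ``exons`` and ``cds`` are ordered lists of 0-based half-open genomic
    intervals, sorted by genomic start regardless of strand.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            if not ivs:
                raise ValidationError(f"{self.transcript_id}: no {name}")
            prev_end = None
            for start, end in ivs:
                if start >= end:
                    raise ValidationError(
                        f"{self.transcript_id}: empty/inverted {name} interval "
                        f"[{start},{end})"
                    )
                if prev_end is not None and start < prev_end:
                    raise ValidationError(
                        f"{self.transcript_id}: {name} intervals unsorted or overlapping"
                    )
                prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start: leftmost coordinate on '+', rightmost-1 on '-'."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1

    def validate(self, genome: GenomeAssembly, permissive: bool = False) -> None:
        """Check CDS frame and start/stop codons against the genome.

        ``permissive`` skips the frame/start/stop checks (partial models),
        keeping only the bounds checks.
        """
        if self.contig not in genome:
            raise ValidationError(f"{self.transcript_id}: unknown contig {self.contig!r}")
        clen = len(genome[self.contig])
        for start, end in self.exons + self.cds:
            if start < 0 or end > clen:
                raise ValidationError(
                    f"{self.transcript_id}: interval [{start},{end}) outside contig"
                )
        if permissive:
            return
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )
        seq = spliced_cds(self, genome, permissive=True).seq
        if seq[:3] != "ATG":
            raise ValidationError(f"{self.transcript_id}: CDS does not start with ATG")
        if seq[-3:] not in STOP_CODONS:
            raise ValidationError(f"{self.transcript_id}: CDS does not end with a stop")
        internal = {seq[i : i + 3] for i in range(0, len(seq) - 3, 3)}
        if internal & STOP_CODONS:
            raise ValidationError(f"{self.transcript_id}: internal stop codon in CDS")


@dataclass
class CodingSequence:
    """Spliced CDS in sense orientation with a genomic coordinate map.

    ``coord_map[i]`` is the (contig, genomic position) of CDS base ``i``;
    ``back_map`` is its inverse. For minus-strand transcripts the genomic
    positions decrease along the CDS.
    """

    transcript_id: str
    strand: str
    seq: str
    coord_map: list[tuple[str, int]]
    back_map: dict[tuple[str, int], int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.coord_map):
            raise ValidationError("coord_map length mismatch")
        if not self.back_map:
            self.back_map = {key: i for i, key in enumerate(self.coord_map)}
        if len(self.back_map) != len(self.coord_map):
            raise ValidationError("coord_map is not injective")

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codon(self, index: int) -> str:
        return self.seq[3 * index : 3 * index + 3]


def read_fasta(path) -> GenomeAssembly:
    """Read a (multi-record) FASTA file into a GenomeAssembly.

    Lowercase input is normalized to uppercase; record order is preserved.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig name {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeAssembly(contigs)


def write_fasta(genome: GenomeAssembly, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path, permissive: bool = False) -> list[TranscriptModel]:
    """Parse a GFF3 file (gene/mRNA/exon/CDS features) into TranscriptModels.

    1-based closed GFF coordinates are converted to 0-based half-open. CDS
    features must point at an mRNA via Parent. Unless ``permissive`` is set,
    a CDS whose total length is not divisible by 3 raises ValidationError.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # sqlite/parse failures
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc

    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    transcripts: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons and cds:
            exons = list(cds)
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene_id,
            contig=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
            cds=cds,
        )
        if not permissive and model.cds_length % 3 != 0:
            raise ValidationError(
                f"{model.transcript_id}: CDS length {model.cds_length} "
                "not divisible by 3"
            )
        transcripts.append(model)

    for cds_feat in db.features_of_type("CDS"):
        parents = cds_feat.attributes.get("Parent", [])
        if not parents or not set(parents) & mrna_ids:
            raise FormatError(f"CDS feature {cds_feat.id!r} has no parent mRNA")
    if not transcripts:
        raise FormatError(f"no mRNA features in {path}")
    return transcripts


def write_gff3(transcripts: list[TranscriptModel], path) -> None:
    """Write TranscriptModels as GFF3 (gene/mRNA/exon/CDS, 1-based closed)."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    for gene_id, models in by_gene.items():
        start = min(t.span[0] for t in models)
        end = max(t.span[1] for t in models)
        contig, strand = models[0].contig, models[0].strand
        buf.write(
            f"{contig}\tstopcall\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
            f"ID={gene_id}\n"
        )
        for t in models:
            s, e = t.span
            buf.write(
                f"{t.contig}\tstopcall\tmRNA\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};Parent={gene_id}\n"
            )
            for i, (xs, xe) in enumerate(t.exons, 1):
                buf.write(
                    f"{t.contig}\tstopcall\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )
            for i, (cs, ce) in enumerate(t.cds, 1):
                buf.write(
                    f"{t.contig}\tstopcall\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t0\t"
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def spliced_cds(
    t: TranscriptModel, genome: GenomeAssembly, permissive: bool = False
) -> CodingSequence:
    """Assemble the spliced CDS of ``t`` in sense orientation.

    For minus-strand transcripts the sequence is reverse-complemented and the
    coordinate map runs over strictly decreasing genomic positions.
    """
    t.validate(genome, permissive=True)
    pieces: list[str] = []
    coords: list[tuple[str, int]] = []
    for start, end in t.cds:
        pieces.append(genome.fetch(t.contig, start, end))
        coords.extend((t.contig, pos) for pos in range(start, end))
    seq = "".join(pieces)
    if t.strand == "-":
        seq = reverse_complement(seq)
        coords = coords[::-1]
    cds = CodingSequence(
        transcript_id=t.transcript_id, strand=t.strand, seq=seq, coord_map=coords
    )
    if not permissive:
        t.validate(genome, permissive=False)
    return cds
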