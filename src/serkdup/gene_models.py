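"""Sequence and gene-model handling: FASTA/GFF3 I/O, intron extraction, splicing.

Coordinates are GFF3-style 1-based inclusive at the file boundary and 0-based
half-open internally; the conversion happens only in the readers/writers.
Minus-strand genes are normalized at load time (the stored sequence is the
reverse complement of the genomic reference, with exon coordinates remapped),
so every downstream computation can treat genes as plus-strand.

Exons are numbered 1..n in transcription order; intron i is the genomic gap
between exon i and exon i+1 (so intron 5 immediately precedes exon 6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_NT = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    """Raised for malformed FASTA/GFF3 input or invalid gene structures."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence (stored uppercase, IUPAC alphabet)."""

    seq_id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"sequence {self.seq_id!r} is empty")
        up = self.residues.upper()
        bad = set(up) - IUPAC_NT
        if bad:
            raise FormatError(
                f"sequence {self.seq_id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A gene's exon structure on a (normalized, plus-strand) sequence.

    exons: list of (start, end), 0-based half-open, sorted, non-overlapping.
    cds_start_offset: 0-based offset of the ATG within the spliced transcript.
    """

    gene_id: str
    seq_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start_offset: int = 0
    strand: str = "+"

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    def intron_intervals(self) -> list[tuple[int, int]]:
        """(start, end) of intron i (1-based index i ↦ list position i-1)."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(self.n_exons - 1)
        ]

    def validate(self, sequence: GenomeSequence | None = None) -> None:
        if self.n_exons < 1:
            raise FormatError(f"gene {self.gene_id!r} has no exons")
        prev_end = None
        for k, (s, e) in enumerate(self.exons, start=1):
            if s >= e:
                raise FormatError(
                    f"gene {self.gene_id!r}: exon {k} has start >= end"
                )
            if prev_end is not None:
                if s < prev_end:
                    raise FormatError(
                        f"gene {self.gene_id!r}: exon {k} overlaps exon {k-1}"
                    )
                if s == prev_end:
                    raise FormatError(
                        f"gene {self.gene_id!r}: intron {k-1} has zero length"
                    )
            prev_end = e
        if sequence is not None:
            if self.exons[-1][1] > len(sequence):
                raise FormatError(
                    f"gene {self.gene_id!r}: exon end {self.exons[-1][1]} "
                    f"beyond sequence {sequence.seq_id!r} "
                    f"of length {len(sequence)}"
                )
            if self.exons[0][0] < 0:
                raise FormatError(f"gene {self.gene_id!r}: negative coordinate")


@dataclass(frozen=True)
class TranscriptStructure:
    """Which exons a transcript keeps and which introns it retains (1-based)."""

    kept_exons: tuple[int, ...]
    retained_introns: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "kept_exons", tuple(self.kept_exons))
        object.__setattr__(
            self, "retained_introns", tuple(sorted(self.retained_introns))
        )
        if not self.kept_exons:
            raise FormatError("transcript structure keeps no exons")
        if list(self.kept_exons) != sorted(set(self.kept_exons)):
            raise FormatError("kept_exons must be strictly increasing")

    def validate(self, model: GeneModel) -> None:
        if self.kept_exons[-1] > model.n_exons or self.kept_exons[0] < 1:
            raise FormatError("kept exon index out of range")
        kept = set(self.kept_exons)
        for i in self.retained_introns:
            if not 1 <= i <= model.n_introns:
                raise FormatError(f"retained intron {i} out of range")
            if i not in kept or (i + 1) not in kept:
                raise FormatError(
                    f"retained intron {i} requires exons {i} and {i+1} kept"
                )

    @property
    def is_canonical_for(self) -> bool:  # pragma: no cover - sugar
        return not self.retained_introns

    def skipped_exons(self, model: GeneModel) -> tuple[int, ...]:
        kept = set(self.kept_exons)
        return tuple(i for i in range(1, model.n_exons + 1) if i not in kept)


def canonical_structure(model: GeneModel) -> TranscriptStructure:
    return TranscriptStructure(tuple(range(1, model.n_exons + 1)), ())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects (order kept)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            out.append(GenomeSequence(rec.id, str(rec.seq)))
        except FormatError as exc:
            raise FormatError(f"record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(path, sequences: list[GenomeSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.seq_id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(gff_path, sequences: list[GenomeSequence]) -> list[GeneModel]:
    """Read gene/mRNA/exon features into GeneModels, one per mRNA.

    Minus-strand genes are normalized: the model's sequence becomes the
    reverse complement of the reference and exon coordinates are remapped,
    so splicing/intron logic downstream never needs to know the strand.
    The normalized per-gene sequence is attached as ``model._sequence``.
    """
    import gffutils

    seq_by_id = {s.seq_id: s for s in sequences}
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        if "Parent" not in mrna.attributes:
            raise FormatError(f"mRNA {mrna.id!r} has no Parent attribute")
        if mrna.seqid not in seq_by_id:
            raise FormatError(
                f"mRNA {mrna.id!r} references unknown sequence {mrna.seqid!r}"
            )
        seq = seq_by_id[mrna.seqid]
        exons = []
        for ex in db.children(mrna, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))  # to 0-based half-open
        if not exons:
            raise FormatError(f"mRNA {mrna.id!r} has no exon children")
        cds_off = int(mrna.attributes.get("cds_start_offset", ["0"])[0])
        if mrna.strand == "-":
            n = len(seq)
            exons = sorted((n - e, n - s) for s, e in exons)
            gene_seq = GenomeSequence(seq.seq_id, reverse_complement(seq.residues))
        else:
            gene_seq = seq
        model = GeneModel(
            gene_id=mrna.id,
            seq_id=seq.seq_id,
            exons=sorted(exons),
            cds_start_offset=cds_off,
            strand=mrna.strand or "+",
        )
        model.validate(gene_seq)
        model._sequence = gene_seq  # normalized sequence for this gene
        models.append(model)
    if not models:
        raise FormatError(f"no mRNA features found in {gff_path}")
    return models


def write_gff3(path, models: list[GeneModel]) -> None:
    """Write plus-strand (normalized) GeneModels as gene/mRNA/exon GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = m.exons[0][0] + 1
            end = m.exons[-1][1]
            gid = f"{m.gene_id}.gene"
            fh.write(
                f"{m.seq_id}\tserkdup\tgene\t{start}\t{end}\t.\t+\t.\t"
                f"ID={gid}\n"
            )
            fh.write(
                f"{m.seq_id}\tserkdup\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                f"ID={m.gene_id};Parent={gid};"
                f"cds_start_offset={m.cds_start_offset}\n"
            )
            for k, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.seq_id}\tserkdup\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Intron extraction and splicing


def extract_introns(
    model: GeneModel, sequence: GenomeSequence
) -> list[tuple[int, str]]:
    """Return [(intron_index, intron_sequence)] for introns 1..n_exons-1."""
    model.validate(sequence)
    out = []
    for i, (s, e) in enumerate(model.intron_intervals(), start=1):
        if e <= s:
            raise FormatError(f"gene {model.gene_id!r}: intron {i} zero length")
        out.append((i, sequence.residues[s:e]))
    return out


def splice(
    model: GeneModel,
    sequence: GenomeSequence,
    structure: TranscriptStructure | None = None,
) -> str:
    """Assemble a transcript: kept exons in genomic order, each retained
    intron inserted verbatim between its flanking exons."""
    if structure is None:
        structure = canonical_structure(model)
    structure.validate(model)
    model.validate(sequence)
    retained = set(structure.retained_introns)
    introns = model.intron_intervals()
    parts = []
    for idx, i in enumerate(structure.kept_exons):
        s, e = model.exons[i - 1]
        parts.append(sequence.residues[s:e])
        if i in retained and idx + 1 < len(structure.kept_exons):
            js, je = introns[i - 1]
            parts.append(sequence.residues[js:je])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Tandem cluster geometry


def tandem_cluster_span(
    gene_positions: list[tuple[float, float]],
    gene_names: list[str] | None = None,
):
    """Span (max end − min start) of a tandem gene cluster, in Kb.

    Positions are (start, end) in the same Kb unit as Table-style chromosome
    coordinates. Returns (span_kb_rounded, order, gaps): gene order by start,
    and inter-gene gaps (start of next − end of previous; negative = overlap,
    which triggers a warning, not an error).
    """
    if len(gene_positions) < 2:
        raise ValueError("need at least 2 genes for a cluster span")
    names = gene_names or [f"gene{i+1}" for i in range(len(gene_positions))]
    order = sorted(range(len(gene_positions)), key=lambda i: gene_positions[i][0])
    ordered_names = [names[i] for i in order]
    gaps = []
    for a, b in zip(order, order[1:]):
        gap = gene_positions[b][0] - gene_positions[a][1]
        if gap < 0:
            warnings.warn(
                f"genes {names[a]} and {names[b]} overlap by {-gap:.1f} Kb",
                stacklevel=2,
            )
        gaps.append(gap)
    span = max(e for _, e in gene_positions) - min(s for s, _ in gene_positions)
    return int(round(span)), ordered_names, gaps
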