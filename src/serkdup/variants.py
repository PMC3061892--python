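"""Splice-variant analysis: transcript mapping, event classification,
ORF/protein prediction and grouping of variants by encoded protein.

Transcripts are assumed error-free relative to the genome (clean synthetic
or curated data), so mapping is exact-segment matching: walking the ordered
genomic segments (exon 1, intron 1, exon 2, …), each exon is either matched
in full or skipped in full, and an intron matched in full is retained. The
two alternative-splicing event classes this covers are intron retention and
exon skipping.

The primary ORF always starts at the gene's annotated start codon; a stop
upstream of the canonical stop position (in genomic terms) is a premature
termination codon (PTC). For PTC transcripts the longest ATG-initiated ORF
downstream of the premature stop is reported as a secondary ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .gene_models import (
    FormatError,
    GeneModel,
    GenomeSequence,
    TranscriptStructure,
    canonical_structure,
    splice,
)

STOP_CODONS = ("TAA", "TAG", "TGA")


class MappingError(ValueError):
    pass


@dataclass
class VariantReport:
    variant_id: str
    structure: TranscriptStructure
    canonical: bool
    retained_introns: tuple[int, ...]
    skipped_exons: tuple[int, ...]
    events: list[str] = field(default_factory=list)
    orf: str | None = None          # predicted protein (no stop symbol)
    protein_length: int | None = None
    ptc: bool = False
    ptc_intron: int | None = None
    secondary_orf: str | None = None
    secondary_orf_offset: int | None = None  # transcript offset of its ATG


@dataclass(frozen=True)
class ProteinGrouping:
    groups: dict[str, tuple[str, ...]]  # protein text -> variant ids
    n_distinct: int


def _segments(model: GeneModel, genome: GenomeSequence):
    """Ordered genomic segments: ('exon', 1, seq), ('intron', 1, seq), ..."""
    segs = []
    introns = model.intron_intervals()
    for k, (s, e) in enumerate(model.exons, start=1):
        segs.append(("exon", k, genome.residues[s:e]))
        if k <= len(introns):
            js, je = introns[k - 1]
            segs.append(("intron", k, genome.residues[js:je]))
    return segs


def map_transcript(
    model: GeneModel, genome: GenomeSequence, transcript_seq: str
) -> TranscriptStructure:
    """Recover the unique exon/intron structure of an error-free transcript.

    Greedy left-to-right: at each genomic segment in order, an exon that
    matches the transcript in full is kept (else skipped); an intron that
    matches in full — only considered between two kept exons — is retained.
    Raises MappingError (with the failing transcript offset) when no
    consistent structure exists.
    """
    t = transcript_seq.upper()
    pos = 0
    kept: list[int] = []
    retained: list[int] = []
    last_kept = None
    for kind, idx, seg in _segments(model, genome):
        if pos == len(t):
            break
        if kind == "exon":
            if t.startswith(seg, pos):
                kept.append(idx)
                last_kept = idx
                pos += len(seg)
            # else: exon skipped in full
        else:  # intron idx, between exon idx and exon idx+1
            if last_kept == idx and t.startswith(seg, pos):
                # candidate retention: only valid if exon idx+1 also matches
                nxt = model.exons[idx]  # exon idx+1, 0-based list
                nxt_seq = genome.residues[nxt[0]:nxt[1]]
                if t.startswith(nxt_seq, pos + len(seg)):
                    retained.append(idx)
                    pos += len(seg)
    if pos != len(t) or not kept:
        raise MappingError(
            f"transcript does not map onto gene {model.gene_id!r}: "
            f"mismatch at transcript offset {pos} of {len(t)}"
        )
    structure = TranscriptStructure(tuple(kept), tuple(retained))
    structure.validate(model)
    # mapping must reproduce the transcript exactly
    if splice(model, genome, structure) != t:
        raise MappingError(
            f"inconsistent structure recovered for gene {model.gene_id!r}"
        )
    return structure


def classify(
    structure: TranscriptStructure, model: GeneModel, variant_id: str = "variant"
) -> VariantReport:
    """Label a transcript structure with its alternative-splicing events."""
    structure.validate(model)
    skipped = structure.skipped_exons(model)
    retained = structure.retained_introns
    events = [f"intron_retention:{i}" for i in retained]
    events += [f"exon_skipping:{i}" for i in skipped]
    return VariantReport(
        variant_id=variant_id,
        structure=structure,
        canonical=not skipped and not retained,
        retained_introns=retained,
        skipped_exons=skipped,
        events=events,
    )


def _transcript_offset_of_cds_start(
    model: GeneModel, structure: TranscriptStructure
) -> int | None:
    """Offset of the annotated ATG within a variant transcript, or None if
    the exon carrying the start is skipped."""
    # locate the start within the canonical transcript's exons
    exon_lens = model.exon_lengths()
    remaining = model.cds_start_offset
    start_exon = None
    within = 0
    for k, L in enumerate(exon_lens, start=1):
        if remaining < L:
            start_exon, within = k, remaining
            break
        remaining -= L
    if start_exon is None or start_exon not in structure.kept_exons:
        return None
    intron_lens = [e - s for s, e in model.intron_intervals()]
    off = 0
    for idx, i in enumerate(structure.kept_exons):
        if i == start_exon:
            return off + within
        off += exon_lens[i - 1]
        if i in structure.retained_introns:
            off += intron_lens[i - 1]
    return None  # pragma: no cover


def _genomic_position(
    model: GeneModel, structure: TranscriptStructure, t_off: int
) -> int:
    """Map a transcript offset to its genomic coordinate (0-based)."""
    introns = model.intron_intervals()
    pieces = []
    for idx, i in enumerate(structure.kept_exons):
        s, e = model.exons[i - 1]
        pieces.append((s, e))
        if i in structure.retained_introns and idx + 1 < len(structure.kept_exons):
            pieces.append(introns[i - 1])
    for s, e in pieces:
        if t_off < e - s:
            return s + t_off
        t_off -= e - s
    raise MappingError(f"transcript offset {t_off} beyond transcript end")


def _canonical_stop_genomic(model: GeneModel, genome: GenomeSequence) -> int:
    """Genomic coordinate of the canonical stop codon's first base."""
    canon = canonical_structure(model)
    mrna = splice(model, genome, canon)
    cds = mrna[model.cds_start_offset:]
    cds = cds[: len(cds) - len(cds) % 3]
    prot = Seq(cds).translate(to_stop=True)
    stop_t = model.cds_start_offset + 3 * len(prot)
    return _genomic_position(model, canon, stop_t)


def predict_orf(
    model: GeneModel,
    genome: GenomeSequence,
    structure: TranscriptStructure,
    variant_id: str = "variant",
    transcript_seq: str | None = None,
) -> VariantReport:
    """Predict the variant's protein from the annotated start codon.

    Translation runs in frame from the annotated ATG to the first stop.
    ``ptc`` is set when that stop lies strictly upstream (genomically) of the
    canonical stop codon; ``ptc_intron`` names the retained intron containing
    the stop's first base, when there is one. For PTC transcripts, the
    longest ATG-initiated downstream ORF is reported as ``secondary_orf``.
    """
    report = classify(structure, model, variant_id)
    t = transcript_seq or splice(model, genome, structure)
    start = _transcript_offset_of_cds_start(model, structure)
    if start is None or not t.startswith("ATG", start):
        report.orf = None
        report.events.append("start_codon_absent")
        return report
    cds = t[start:]
    cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate(to_stop=True))
    report.orf = prot
    report.protein_length = len(prot)
    stop_t = start + 3 * len(prot)
    has_stop = stop_t + 3 <= len(cds) + start and cds[3 * len(prot):3 * len(prot) + 3] in STOP_CODONS
    if has_stop:
        stop_g = _genomic_position(model, structure, stop_t)
        canon_stop_g = _canonical_stop_genomic(model, genome)
        report.ptc = stop_g < canon_stop_g
        if report.ptc:
            introns = model.intron_intervals()
            for i in structure.retained_introns:
                s, e = introns[i - 1]
                if s <= stop_g < e:
                    report.ptc_intron = i
                    break
            sec = _longest_downstream_orf(t, stop_t + 3)
            if sec is not None:
                report.secondary_orf, report.secondary_orf_offset = sec
    return report


def _longest_downstream_orf(transcript: str, from_off: int):
    """Longest ATG-initiated ORF (to a stop codon) at or after ``from_off``.

    Ties go to the leftmost start. Returns (protein_text, atg_offset) or None.
    """
    best: tuple[str, int] | None = None
    pos = transcript.find("ATG", from_off)
    while pos != -1:
        orf_region = transcript[pos:]
        orf_region = orf_region[: len(orf_region) - len(orf_region) % 3]
        prot = str(Seq(orf_region).translate(to_stop=True))
        # require a real stop codon inside the transcript
        end = pos + 3 * len(prot)
        if transcript[end:end + 3] in STOP_CODONS:
            if best is None or len(prot) > len(best[0]):
                best = (prot, pos)
        pos = transcript.find("ATG", pos + 1)
    return best


def analyse_transcripts(
    model: GeneModel,
    genome: GenomeSequence,
    transcripts: dict[str, str],
) -> list[VariantReport]:
    """Full per-transcript pipeline: map → classify → predict ORF."""
    reports = []
    for vid in transcripts:
        structure = map_transcript(model, genome, transcripts[vid])
        reports.append(
            predict_orf(model, genome, structure, vid, transcripts[vid].upper())
        )
    return reports


def group_by_protein(reports: list[VariantReport]) -> ProteinGrouping:
    """Partition variants by exact predicted-protein equality."""
    if not reports:
        raise FormatError("no variant reports to group")
    groups: dict[str, list[str]] = {}
    for r in reports:
        key = r.orf if r.orf is not None else f"<no-orf:{r.variant_id}>"
        groups.setdefault(key, []).append(r.variant_id)
    frozen = {k: tuple(v) for k, v in groups.items()}
    return ProteinGrouping(frozen, len(frozen))
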