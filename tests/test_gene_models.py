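import numpy as np
import pytest

from serkdup import (
    GeneModel,
    GenomeSequence,
    TranscriptStructure,
    canonical_structure,
    extract_introns,
    read_fasta,
    read_gff3,
    splice,
    tandem_cluster_span,
)
from serkdup.gene_models import FormatError, reverse_complement, write_fasta, write_gff3


class TestReadFasta:
    def test_single_record_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgt\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert (recs[0].seq_id, recs[0].residues) == ("a", "ACGT")

    def test_two_records_order_preserved(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">x\nAA\n>y\nCC\n")
        assert [r.seq_id for r in read_fasta(p)] == ["x", "y"]

    def test_invalid_alphabet_names_offender(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACGX\n")
        with pytest.raises(FormatError, match="X"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        seqs = [GenomeSequence("a", "ACGTN" * 40), GenomeSequence("b", "GGG")]
        p = tmp_path / "rt.fasta"
        write_fasta(p, seqs)
        back = read_fasta(p)
        assert [(s.seq_id, s.residues) for s in back] == [
            (s.seq_id, s.residues) for s in seqs
        ]


def _write_gff(path, seqid, exons_1based, strand="+", gene="g1", mrna="m1"):
    start = min(s for s, _ in exons_1based)
    end = max(e for _, e in exons_1based)
    lines = ["##gff-version 3"]
    lines.append(f"{seqid}\t.\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gene}")
    lines.append(
        f"{seqid}\t.\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={mrna};Parent={gene}"
    )
    for k, (s, e) in enumerate(exons_1based, 1):
        lines.append(
            f"{seqid}\t.\texon\t{s}\t{e}\t.\t{strand}\t.\t"
            f"ID={mrna}.e{k};Parent={mrna}"
        )
    path.write_text("\n".join(lines) + "\n")


class TestReadGff3:
    def test_three_exon_gene(self, tmp_path):
        gff = tmp_path / "g.gff3"
        _write_gff(gff, "chr", [(1, 3), (6, 8), (11, 13)])
        models = read_gff3(gff, [GenomeSequence("chr", "AAATTGGGTTCCC")])
        assert len(models) == 1
        m = models[0]
        assert m.n_exons == 3 and m.n_introns == 2
        assert splice(m, m._sequence) == "AAAGGGCCC"

    def test_strand_symmetry(self, tmp_path):
        """A gene annotated on the minus strand of the mirrored sequence
        yields the identical spliced transcript after normalization."""
        fwd_seq = "AAATTGGGTTCCC"
        gff_f = tmp_path / "f.gff3"
        _write_gff(gff_f, "chr", [(1, 3), (6, 8), (11, 13)], strand="+")
        m_f = read_gff3(gff_f, [GenomeSequence("chr", fwd_seq)])[0]

        rc = reverse_complement(fwd_seq)
        n = len(fwd_seq)
        mirrored = sorted((n - e + 1, n - s + 1) for s, e in [(1, 3), (6, 8), (11, 13)])
        gff_r = tmp_path / "r.gff3"
        _write_gff(gff_r, "chr", mirrored, strand="-")
        m_r = read_gff3(gff_r, [GenomeSequence("chr", rc)])[0]

        assert splice(m_f, m_f._sequence) == splice(m_r, m_r._sequence)

    def test_exon_beyond_sequence_rejected(self, tmp_path):
        gff = tmp_path / "g.gff3"
        _write_gff(gff, "chr", [(1, 3), (6, 99)])
        with pytest.raises(FormatError, match="beyond"):
            read_gff3(gff, [GenomeSequence("chr", "AAATTGGGTTCCC")])

    def test_gff3_roundtrip(self, tmp_path, sv_fixture):
        out = tmp_path / "rt.gff3"
        write_gff3(out, [sv_fixture.model])
        models = read_gff3(out, [sv_fixture.genome])
        assert models[0].exons == sv_fixture.model.exons
        assert models[0].cds_start_offset == sv_fixture.model.cds_start_offset


class TestExtractIntrons:
    def test_simple_intron(self):
        genome = GenomeSequence("s", "AAATTTGGG")
        model = GeneModel("g", "s", [(0, 3), (6, 9)])
        assert extract_introns(model, genome) == [(1, "TTT")]

    def test_eleven_exon_fixture_has_ten_introns(self, sv_fixture):
        introns = extract_introns(sv_fixture.model, sv_fixture.genome)
        assert [i for i, _ in introns] == list(range(1, 11))

    def test_single_exon_no_introns(self):
        genome = GenomeSequence("s", "AAAT")
        model = GeneModel("g", "s", [(0, 4)])
        assert extract_introns(model, genome) == []

    def test_zero_length_intron_rejected(self):
        genome = GenomeSequence("s", "AAATTT")
        model = GeneModel("g", "s", [(0, 3), (3, 6)])
        with pytest.raises(FormatError, match="intron"):
            extract_introns(model, genome)


class TestSplice:
    def test_canonical_is_exon_concatenation(self, toy_gene):
        genome, model = toy_gene
        assert splice(model, genome) == "AAAGGGCCC"

    def test_retained_intron_inserted_verbatim(self, toy_gene):
        genome, model = toy_gene
        s = TranscriptStructure((1, 2), (1,))
        assert splice(model, genome, s) == "AAATTGGG"

    def test_exon3_skip_shortens_by_exon3_length(self, sv_fixture):
        canon = splice(sv_fixture.model, sv_fixture.genome)
        sv3 = sv_fixture.transcripts["SV3"]
        exon3_len = sv_fixture.model.exon_lengths()[2]
        assert exon3_len == 72
        assert len(canon) - len(sv3) == exon3_len

    def test_retained_intron_with_skipped_flank_rejected(self, toy_gene):
        genome, model = toy_gene
        with pytest.raises(FormatError, match="retained intron"):
            TranscriptStructure((1, 3), (1,)).validate(model)

    def test_length_identity_over_random_structures(self, sv_fixture):
        """len(variant) = len(canonical) + Σ retained introns − Σ skipped exons."""
        rng = np.random.default_rng(7)
        model, genome = sv_fixture.model, sv_fixture.genome
        exon_lens = model.exon_lengths()
        intron_lens = [e - s for s, e in model.intron_intervals()]
        canon_len = len(splice(model, genome))
        for _ in range(25):
            kept = sorted(
                set(rng.choice(range(1, 12), size=rng.integers(1, 12), replace=False))
            )
            kept_set = set(kept)
            candidates = [
                i for i in range(1, 11) if i in kept_set and i + 1 in kept_set
            ]
            retained = [i for i in candidates if rng.random() < 0.5]
            t = splice(model, genome, TranscriptStructure(tuple(kept), tuple(retained)))
            expected = (
                canon_len
                + sum(intron_lens[i - 1] for i in retained)
                - sum(exon_lens[i - 1] for i in range(1, 12) if i not in kept_set)
            )
            assert len(t) == expected


class TestTandemClusterSpan:
    def test_five_gene_cluster_spans_33kb(self):
        positions = [
            (1603.3, 1609.6),
            (1610.0, 1616.1),
            (1615.7, 1621.4),
            (1622.7, 1628.9),
            (1629.2, 1636.2),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            span, order, gaps = tandem_cluster_span(
                positions, ["MtSERK2", "MtSERK3", "MtSERK4", "MtSERK5", "MtSERK6"]
            )
        assert span == 33
        assert order == ["MtSERK2", "MtSERK3", "MtSERK4", "MtSERK5", "MtSERK6"]
        assert len(gaps) == 4 and gaps[1] < 0  # MtSERK3/MtSERK4 loci overlap

    def test_duplicated_interval(self):
        with pytest.warns(UserWarning, match="overlap"):
            span, _, _ = tandem_cluster_span([(0, 10), (0, 10)])
        assert span == 10

    def test_three_intervals(self):
        span, _, gaps = tandem_cluster_span([(0, 1), (5, 6), (9, 12)])
        assert span == 12
        assert gaps == [4, 3]

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            tandem_cluster_span([(0, 10)])
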