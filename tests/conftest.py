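import pytest

from serkdup import (
    GeneModel,
    GenomeSequence,
    analyse_transcripts,
    make_sv_fixture,
)


@pytest.fixture(scope="session")
def sv_fixture():
    """Default 11-exon splice-variant fixture (deterministic, seed 0)."""
    return make_sv_fixture(seed=0)


@pytest.fixture(scope="session")
def sv_reports(sv_fixture):
    """Full variant pipeline (map → classify → ORF) on the seven transcripts."""
    return analyse_transcripts(
        sv_fixture.model, sv_fixture.genome, sv_fixture.transcripts
    )


@pytest.fixture()
def toy_gene():
    """Three-exon toy gene: exons AAA, GGG, CCC with TT introns."""
    genome = GenomeSequence("chr", "AAATTGGGTTCCC")
    model = GeneModel("toy", "chr", [(0, 3), (5, 8), (10, 13)])
    return genome, model
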