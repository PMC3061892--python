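import numpy as np
import pytest

from serkdup import (
    make_sv_fixture,
    simulate_duplication_history,
    simulate_qpcr,
)
from serkdup.simulate import SV_EXON_LENGTHS, SV_STRUCTURES, SimulationError


class TestSimulateDuplicationHistory:
    def test_single_gene_no_divergence(self):
        genes, truth = simulate_duplication_history(event_times=[], seed=1)
        assert list(genes) == ["G1"]
        assert truth.true_age_matrix.shape == (1, 1)

    def test_near_zero_time_gives_identical_introns(self):
        genes, _ = simulate_duplication_history(
            event_times=[1.0], intron_lengths=[500] * 4, n_introns=4, seed=2
        )
        assert genes["G1"] == genes["G2"]

    def test_byte_reproducible_under_seed(self):
        g1, t1 = simulate_duplication_history(seed=9)
        g2, t2 = simulate_duplication_history(seed=9)
        assert g1 == g2
        assert np.array_equal(t1.true_age_matrix, t2.true_age_matrix)

    def test_default_five_gene_family(self):
        genes, truth = simulate_duplication_history(seed=0)
        assert len(genes) == 5
        assert all(len(v) == 10 for v in genes.values())
        assert truth.event_times_years == (3.25e6, 3.05e6, 2.65e6, 2.2e6)
        # MRCA ages: gene Gi vs later genes diverged at event i
        A = truth.true_age_matrix
        assert A[0, 4] == 3.25e6 and A[3, 4] == 2.2e6
        assert np.allclose(A, A.T) and np.allclose(np.diag(A), 0)

    def test_expected_divergence_matches_clock(self):
        """Mean pairwise p-distance approaches 2·mu·T.

        Checked on 1 Mb of pooled intron sequence, where the binomial
        relative SD is 1/sqrt(2·mu·T·L) ≈ 2.3%, so the 5% tolerance sits
        at ~2.2 sigma.
        """
        T, mu, L = 3.25e6, 3e-10, 1_000_000
        genes, _ = simulate_duplication_history(
            event_times=[T], mu=mu, n_introns=10,
            intron_lengths=[L // 10] * 10, seed=13,
        )
        diffs = total = 0
        for a, b in zip(genes["G1"], genes["G2"]):
            arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
            arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
            diffs += int((arr_a != arr_b).sum())
            total += len(a)
        p = diffs / total
        assert p == pytest.approx(2 * mu * T, rel=0.05)

    def test_unsorted_times_rejected(self):
        with pytest.raises(SimulationError, match="descending"):
            simulate_duplication_history(event_times=[1e6, 2e6])

    def test_negative_rate_rejected(self):
        with pytest.raises(SimulationError):
            simulate_duplication_history(mu=-1)

    def test_indels_change_lengths(self):
        genes, _ = simulate_duplication_history(
            event_times=[3e6], intron_lengths=[2000] * 5, n_introns=5,
            indel_rate=1e-9, seed=3,
        )
        lens1 = [len(s) for s in genes["G1"]]
        lens2 = [len(s) for s in genes["G2"]]
        assert lens1 != lens2

    def test_truth_newick_is_ultrametric_caterpillar(self):
        import dendropy

        _, truth = simulate_duplication_history(seed=4)
        tree = dendropy.Tree.get(data=truth.newick, schema="newick")
        depths = {
            l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()
        }
        assert all(d == pytest.approx(3.25e6) for d in depths.values())


class TestSvFixture:
    def test_exon_lengths_match_design(self, sv_fixture):
        assert tuple(sv_fixture.model.exon_lengths()) == SV_EXON_LENGTHS
        assert sv_fixture.model.exon_lengths()[2] % 3 == 0  # exon 3 in-frame

    def test_designed_stops_in_introns_5_and_8(self, sv_fixture):
        from serkdup import extract_introns

        introns = dict(extract_introns(sv_fixture.model, sv_fixture.genome))
        assert introns[5][12:15] == "TGA"
        assert introns[8][3:6] == "TAA"
        # designed stops are the only in-frame stops at the start of each
        for i, seq in introns.items():
            codons = [seq[k : k + 3] for k in range(0, len(seq) - 2, 3)]
            stops = [k for k, c in enumerate(codons) if c in ("TAA", "TAG", "TGA")]
            if i == 5:
                assert stops == [4]
            elif i == 8:
                assert stops == [1]
            else:
                assert stops == []

    def test_introns_carry_no_atg(self, sv_fixture):
        from serkdup import extract_introns

        for _, seq in extract_introns(sv_fixture.model, sv_fixture.genome):
            assert "ATG" not in seq

    def test_seven_transcripts_per_design(self, sv_fixture):
        assert set(sv_fixture.transcripts) == set(SV_STRUCTURES)

    def test_table_length_relations(self, sv_reports):
        by_id = {r.variant_id: r.protein_length for r in sv_reports}
        assert by_id["SV1"] - by_id["SV3"] == 24
        assert by_id["SV2"] - by_id["SV4"] == 24

    def test_byte_reproducible(self):
        a, b = make_sv_fixture(seed=5), make_sv_fixture(seed=5)
        assert a.genome.residues == b.genome.residues
        assert a.transcripts == b.transcripts

    def test_canonical_cds_starts_atg_ends_stop(self, sv_fixture):
        from serkdup import splice

        mrna = splice(sv_fixture.model, sv_fixture.genome)
        assert mrna.startswith("ATG")
        assert mrna[-3:] == "TAA"
        assert len(mrna) % 3 == 0


class TestSimulateQpcr:
    def test_deterministic_under_seed(self):
        a = simulate_qpcr(noise_sd=0.02, n_wells=2, seed=7)
        b = simulate_qpcr(noise_sd=0.02, n_wells=2, seed=7)
        assert a == b

    def test_exponential_regime_recovers_e_true(self):
        from serkdup import estimate_efficiency

        curve = simulate_qpcr(e_true=1.8, f0=1e-6, plateau=1e9, seed=1)[0]
        assert estimate_efficiency(curve).efficiency == pytest.approx(1.8, abs=0.01)

    def test_e_of_one_is_flat_boundary(self):
        from serkdup import estimate_efficiency
        from serkdup.qpcr import QpcrError

        curve = simulate_qpcr(e_true=1.0, seed=2)[0]
        with pytest.raises(QpcrError, match="no amplification"):
            estimate_efficiency(curve)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            simulate_qpcr(e_true=2.5)
        with pytest.raises(SimulationError):
            simulate_qpcr(f0=-1)
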