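import numpy as np
import pytest

import orthosplice as osp
from orthosplice.diff_events import EventKey, MasterRecord
from orthosplice.ortho_match import match_events_for_gene_pair

from oracles import (
    biopython_global_score,
    make_gene_instance,
    mutate_dna,
    random_dna,
    sorted_sweep_matching,
)


class TestGlobalAlign:
    def test_identical_sequences(self):
        score, identity = osp.global_align("ACGTACGT", "ACGTACGT")
        assert score == 8.0 and identity == 1.0

    def test_all_mismatch_identity_zero(self):
        _, identity = osp.global_align("AAAA", "TTTT")
        assert identity == 0.0

    def test_single_substitution(self):
        score, identity = osp.global_align("ACGTACGTAC", "ACGTTCGTAC")
        assert score == 8.0 and identity == pytest.approx(0.9)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            osp.global_align("", "ACGT")

    def test_n_never_matches(self):
        score, identity = osp.global_align("ANAT", "ANAT")
        assert identity == pytest.approx(3 / 4)
        assert score == 2.0   # 3 matches, N-vs-N mismatch

    def test_gap_cost_convention(self):
        # deleting one base: 7 matches + single gap (open -2 + extend -1)
        score, _ = osp.global_align("ACGTACGT", "ACGTCGT")
        assert score == 7 - 3

    def test_identity_mode_shorter(self):
        params = osp.AlignmentParams(identity_mode="shorter")
        _, identity = osp.global_align("ACGTACGT", "ACGT", params)
        assert identity == 1.0

    def test_score_matches_independent_reference(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 41)))
            b = random_dna(rng, int(rng.integers(1, 41)))
            score, _ = osp.global_align(a, b)
            assert score == biopython_global_score(a, b)


class TestExtractTriplet:
    def test_plus_strand_roles(self, toy_genome):
        key = EventKey("m", "g", "chr1", "+", (6, 9), (0, 3), (12, 15))
        trip = osp.extract_triplet(key, toy_genome)
        assert trip.target_seq == "CCC"
        assert trip.fiveprime_adjacent_seq == "AAA"
        assert trip.threeprime_adjacent_seq == "GGG"

    def test_minus_strand_reverse_complements_and_swaps(self, toy_genome):
        key = EventKey("m", "g", "chr1", "-", (6, 9), (0, 3), (12, 15))
        trip = osp.extract_triplet(key, toy_genome)
        assert trip.target_seq == "GGG"
        assert trip.fiveprime_adjacent_seq == "CCC"
        assert trip.threeprime_adjacent_seq == "TTT"

    def test_out_of_bounds_names_event(self, toy_genome):
        key = EventKey("m", "g", "chr1", "+", (6, 9), (0, 3), (12, 99))
        with pytest.raises(IndexError, match="chr1"):
            osp.extract_triplet(key, toy_genome)


class TestScoreEventPair:
    def trip(self, seqs):
        return osp.ExonTripletSeqs(*seqs)

    def test_identical_triplets_eligible(self):
        t = self.trip(("A" * 30 + "C" * 0, "ACGT" * 20, "GGCC" * 10))
        ps = osp.score_event_pair(t, t)
        assert ps.eligible and ps.identities == (1.0, 1.0, 1.0)
        assert ps.total_score == 30 + 80 + 40

    def test_one_low_identity_exon_disqualifies(self):
        a = self.trip(("ACGTACGTAC", "ACGT" * 10, "GGCC" * 10))
        b = self.trip(("TTTTTTTTTT", "ACGT" * 10, "GGCC" * 10))
        ps = osp.score_event_pair(a, b)
        assert ps.identities[1] == 1.0 and ps.identities[2] == 1.0
        assert not ps.eligible

    def test_exactly_seventy_percent_is_eligible(self):
        # 10 aligned columns with 7 matches on each exon
        a = "ACGTACGTAC"
        b = "ACGTTCGAAT"   # substitutions at positions 4, 7 and 9
        score, identity = osp.global_align(a, b)
        assert identity == pytest.approx(0.7)
        ps = osp.score_event_pair(self.trip((a, a, a)),
                                  self.trip((b, b, b)))
        assert ps.eligible


class TestMatching:
    def test_single_identical_pair(self):
        rng = np.random.default_rng(0)
        ev_a, ev_b, genomes = make_gene_instance(rng, 1, 1, divergence=0.0)
        matches = match_events_for_gene_pair(ev_a, ev_b, genomes)
        assert len(matches) == 1
        assert matches[0].match_round == 1
        assert matches[0].pair_score.identities == (1.0, 1.0, 1.0)

    def test_all_below_threshold_yields_nothing(self):
        # divergence 0.5 puts expected identity ~0.5, far below 0.70
        rng = np.random.default_rng(1)
        ev_a, ev_b, genomes = make_gene_instance(rng, 2, 2, divergence=0.5)
        matches = match_events_for_gene_pair(ev_a, ev_b, genomes)
        assert matches == []

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_sorted_sweep_reference(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_a, n_b = int(rng.integers(1, 7)), int(rng.integers(1, 7))
        ev_a, ev_b, genomes = make_gene_instance(rng, n_a, n_b)
        matches = match_events_for_gene_pair(ev_a, ev_b, genomes)
        scored = []
        for ka in ev_a:
            ta = osp.extract_triplet(ka, genomes["mouse"])
            for kb in ev_b:
                tb = osp.extract_triplet(kb, genomes["human"])
                ps = osp.score_event_pair(ta, tb)
                if ps.eligible:
                    scored.append((ka, kb, ps))
        expected = sorted_sweep_matching(scored)
        got = {(m.event_key_a, m.event_key_b) for m in matches}
        assert got == expected
        # injectivity and the conjunctive identity rule
        keys = [k for m in matches for k in (m.event_key_a, m.event_key_b)]
        assert len(keys) == len(set(keys))
        assert all(
            min(m.pair_score.identities) >= 0.70 for m in matches
        )

    def test_per_event_mode_is_injective_and_eligible(self):
        rng = np.random.default_rng(7)
        ev_a, ev_b, genomes = make_gene_instance(rng, 4, 4)
        matches = match_events_for_gene_pair(ev_a, ev_b, genomes,
                                             mode="per_event")
        keys = [k for m in matches for k in (m.event_key_a, m.event_key_b)]
        assert len(keys) == len(set(keys))
        assert all(m.pair_score.eligible for m in matches)


class TestMatchAll:
    @staticmethod
    def _master(keys):
        return [MasterRecord(key=k, gene_symbol=k.gene_id) for k in keys]

    def test_one_to_two_homology_keeps_best(self):
        rng = np.random.default_rng(3)
        five, target, three = (random_dna(rng, 40) for _ in range(3))
        near = [mutate_dna(rng, s, 0.02) for s in (five, target, three)]
        far = [mutate_dna(rng, s, 0.25) for s in (five, target, three)]

        def lay(seqs, chrom, gene, species):
            l, t, r = (0, 40), (60, 100), (120, 160)
            contig = list("A" * 160)
            for (s, e), seq in zip((l, t, r), seqs):
                contig[s:e] = list(seq)
            key = EventKey(species, gene, chrom, "+", t, l, r)
            return key, "".join(contig)

        key_a, contig_a = lay((five, target, three), "cA", "gA", "mouse")
        key_b0, contig_b0 = lay(near, "cB0", "gB0", "human")
        key_b1, contig_b1 = lay(far, "cB1", "gB1", "human")
        genomes = {
            "mouse": osp.GenomeSource("A", {"cA": contig_a}),
            "human": osp.GenomeSource("B", {"cB0": contig_b0,
                                            "cB1": contig_b1}),
        }
        homologs = [osp.HomologPair("gA", "gB0"),
                    osp.HomologPair("gA", "gB1")]
        matches = osp.match_all(
            self._master([key_a, key_b0, key_b1]), homologs, genomes
        )
        assert len(matches) == 1
        assert matches[0].event_key_b == key_b0   # the closer paralog wins

    def test_gene_without_events_on_one_side_skipped(self):
        rng = np.random.default_rng(4)
        ev_a, _, genomes = make_gene_instance(rng, 2, 0)
        matches = osp.match_all(self._master(ev_a),
                                [osp.HomologPair("gA", "gB")], genomes)
        assert matches == []

    def test_self_match_against_identical_copy(self):
        """Zero divergence: every event pairs with itself at identity 1."""
        config = osp.SimConfig(seed=21, n_genes=30, n_planted_conserved=10,
                               n_decoy_events=10, divergence=0.0)
        pair = osp.simulate_genome_pair(config)
        keys = []
        for gene in pair.genes:
            if gene.role != "null":
                keys.append(gene.key_a)
                keys.append(gene.key_b)
        matches = osp.match_all(self._master(keys), pair.homologs,
                                pair.genomes)
        matched_genes = {m.event_key_a.gene_id for m in matches}
        expected = {g.gene_id_a for g in pair.genes if g.role != "null"}
        assert matched_genes == expected
        for m in matches:
            assert m.pair_score.identities == (1.0, 1.0, 1.0)


def test_eligibility_degrades_with_divergence():
    """More substitutions never help: eligible pair counts fall with d."""
    totals = {0.05: 0, 0.25: 0, 0.45: 0}
    for seed in (0, 1, 2):
        for d in totals:
            rng = np.random.default_rng(seed)
            ev_a, ev_b, genomes = make_gene_instance(rng, 3, 3,
                                                     divergence=d)
            totals[d] += len(
                match_events_for_gene_pair(ev_a, ev_b, genomes)
            )
    assert totals[0.05] >= totals[0.25] >= totals[0.45]
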