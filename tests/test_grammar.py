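import numpy as np
import pytest

from conftest import build_motif
from oracles import brute_force_matches, random_protein
from ringkit.grammar import (
    RingGrammar,
    classify_proteins,
    default_grammar,
    enumerate_matches,
    resolve_hits,
)
from ringkit.seqio import ProteinRecord
from ringkit.synthetic import PlantedCohortSpec, make_protein_cohort


class TestDefaultGrammar:
    def test_eight_types_with_fixed_short_gaps(self, grammar):
        assert len(grammar) == 8
        for spec in grammar:
            assert spec.gaps[0] == frozenset({2})  # ml1-ml2
            assert spec.gaps[2] == frozenset({1})  # ml3-ml4
            assert spec.gaps[4] == frozenset({2})  # ml5-ml6

    def test_ring_v_has_seven_residue_ml4_ml5_gap(self, grammar):
        assert grammar.spec("RING-v").gaps[3] == frozenset({7})

    def test_ring_hcb_has_four_residue_ml7_ml8_gap(self, grammar):
        assert grammar.spec("RING-HCb").gaps[6] == frozenset({4})

    def test_variable_loop_bounds(self, grammar):
        g2 = set().union(*(s.gaps[1] for s in grammar))
        g6 = set().union(*(s.gaps[5] for s in grammar))
        assert min(g2) == 9 and max(g2) == 28
        assert min(g6) == 6 and max(g6) == 45

    def test_json_roundtrip(self, grammar, tmp_path):
        path = tmp_path / "grammar.json"
        grammar.to_json(path)
        back = RingGrammar.from_json(path)
        assert back == grammar


class TestEnumerateMatches:
    def test_worked_example_single_ring_h2(self, grammar, ghzfrg1_like_sequence):
        rec = ProteinRecord(id="GhZFRG1", sequence=ghzfrg1_like_sequence)
        hits = enumerate_matches(rec, grammar)
        assert len(hits) == 1
        assert hits[0].type_name == "RING-H2"
        assert hits[0].spacers == (2, 15, 1, 2, 2, 12, 2)

    def test_all_alanine_has_no_matches(self, grammar):
        rec = ProteinRecord(id="a", sequence="A" * 200)
        assert enumerate_matches(rec, grammar) == []

    def test_domain_may_touch_sequence_ends(self, grammar):
        seq = build_motif("CCCHHCCC", (2, 15, 1, 2, 2, 12, 2))
        hits = enumerate_matches(ProteinRecord(id="e", sequence=seq), grammar)
        assert len(hits) == 1
        assert hits[0].start == 1 and hits[0].end == len(seq)

    def test_case_insensitive(self, grammar, ghzfrg1_like_sequence):
        rec = ProteinRecord(id="lc", sequence=ghzfrg1_like_sequence.lower())
        assert len(enumerate_matches(rec, grammar)) == 1

    def test_nonstandard_residue_never_a_ligand(self, grammar):
        seq = build_motif("CCCHHCCC", (2, 15, 1, 2, 2, 12, 2))
        # replace ml1 C with X: no match survives
        broken = "X" + seq[1:]
        assert enumerate_matches(
            ProteinRecord(id="x", sequence=broken), grammar
        ) == []

    @pytest.mark.parametrize("seed,n_seqs", [(0, 120)])
    def test_matches_brute_force_oracle(self, grammar, seed, n_seqs):
        rng = np.random.default_rng(seed)
        for _ in range(n_seqs):
            seq = random_protein(rng, 300)
            rec = ProteinRecord(id="r", sequence=seq)
            ours = {
                (h.type_name, h.ml_positions)
                for h in enumerate_matches(rec, grammar)
            }
            assert ours == brute_force_matches(seq, grammar)

    def test_every_hit_satisfies_its_grammar(self, grammar):
        rng = np.random.default_rng(1)
        # enrich in ligand residues to provoke many overlapping matches
        alphabet = "CCHHSTGA"
        for _ in range(50):
            seq = random_protein(rng, 150, alphabet)
            rec = ProteinRecord(id="r", sequence=seq)
            for h in enumerate_matches(rec, grammar):
                spec = grammar.spec(h.type_name)
                for pos, allowed in zip(h.ml_positions, spec.residues):
                    assert seq[pos - 1] in allowed
                for gap, gset in zip(h.spacers, spec.gaps):
                    assert gap in gset

    def test_deterministic_ordering(self, grammar):
        rng = np.random.default_rng(2)
        seq = random_protein(rng, 200, "CCHHSTGA")
        rec = ProteinRecord(id="r", sequence=seq)
        first = enumerate_matches(rec, grammar)
        second = enumerate_matches(rec, grammar)
        assert first == second
        starts = [h.start for h in first]
        assert starts == sorted(starts)


class TestResolveHits:
    def test_non_overlapping_hits_both_retained(self, grammar):
        spec = PlantedCohortSpec(counts={"RING-H2": 2}, n_two_domain=1, seed=5)
        records, _ = make_protein_cohort(spec)
        hits = enumerate_matches(records[0], grammar)
        assert len(resolve_hits(hits, grammar)) == 2

    def test_ring_d_wins_over_hca_on_identical_positions(self, grammar):
        # RING-D's fixed gaps lie inside RING-HCa's ranges, so a sequence
        # built on RING-D's pattern matches both; precedence keeps RING-D
        seq = build_motif("CCCHCCCC", (2, 12, 1, 2, 2, 10, 2))
        rec = ProteinRecord(id="d", sequence=seq)
        raw = enumerate_matches(rec, grammar)
        assert {h.type_name for h in raw} == {"RING-D", "RING-HCa"}
        resolved = resolve_hits(raw, grammar)
        assert [h.type_name for h in resolved] == ["RING-D"]

    def test_policy_all_returns_input(self, grammar):
        seq = build_motif("CCCHCCCC", (2, 12, 1, 2, 2, 10, 2))
        raw = enumerate_matches(ProteinRecord(id="d", sequence=seq), grammar)
        assert resolve_hits(raw, grammar, policy="all") == raw

    def test_unknown_policy_rejected(self, grammar):
        with pytest.raises(ValueError, match="policy"):
            resolve_hits([], grammar, policy="bogus")

    def test_resolved_hits_never_overlap(self, grammar):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = random_protein(rng, 200, "CCHHSTGA")
            raw = enumerate_matches(
                ProteinRecord(id="r", sequence=seq), grammar
            )
            resolved = resolve_hits(raw, grammar)
            for a, b in zip(resolved, resolved[1:]):
                assert a.end < b.start


class TestClassifyProteins:
    def test_planted_cohort_counts(self, grammar):
        spec = PlantedCohortSpec(
            counts={"RING-H2": 55, "RING-HCa": 28, "RING-v": 7}, seed=0
        )
        records, truth = make_protein_cohort(spec)
        _, per_type, _ = classify_proteins(records, grammar)
        assert per_type["RING-H2"] == 55
        assert per_type["RING-HCa"] == 28
        assert per_type["RING-v"] == 7
        assert per_type.sum() == len(truth)

    def test_multi_domain_protein_counts(self, grammar):
        spec = PlantedCohortSpec(
            counts={"RING-H2": 30}, n_two_domain=9, n_three_domain=2, seed=1
        )
        records, _ = make_protein_cohort(spec)
        per_protein, _, _ = classify_proteins(records, grammar)
        counts = per_protein["n_domains"].value_counts().to_dict()
        assert counts == {1: 6, 2: 9, 3: 2}

    def test_empty_input(self, grammar):
        per_protein, per_type, hits = classify_proteins([], grammar)
        assert per_protein.empty
        assert per_type.sum() == 0
        assert hits == []
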