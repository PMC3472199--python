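"""Intron extraction, splice-site checks, homologization, parsimony."""

import numpy as np
import pytest

from ppofam.alignment_core import MultipleAlignment, build_coordinate_maps
from ppofam.benchmarks import brute_force_parsimony, random_rooted_tree
from ppofam.domain_annotation import DomainArchitecture
from ppofam.intron_evolution import (check_splice_dinucleotides, dollo_events,
                                     enumerate_equally_parsimonious,
                                     extract_introns, fitch_changes,
                                     homologize_introns, label_regions,
                                     replay_events)
from ppofam.io_formats import GeneModel
from ppofam.tree import Node, from_newick


class TestExtractIntrons:
    def test_phase_zero_intron_after_300_nt(self):
        m = GeneModel("g", "c", "+", ((0, 300), (450, 750)))
        rec, = extract_introns(m)
        assert (rec.codon_index, rec.phase) == (100, 0)
        assert rec.genomic_interval == (300, 450)
        assert rec.length_nt == 150

    def test_phase_one_intron_after_301_nt(self):
        m = GeneModel("g", "c", "+", ((0, 301), (400, 699)))
        rec, = extract_introns(m)
        assert (rec.codon_index, rec.phase) == (100, 1)

    def test_minus_strand_hand_worked_toy(self):
        # 60-nt toy, '-' strand: transcription starts with exon (46,58)
        # (12 nt), then exon (10,40); the intron is genomic (40,46),
        # 12 exonic nt 5' of it -> codon 4, phase 0.
        m = GeneModel("g", "c", "-", ((10, 40), (46, 58)))
        rec, = extract_introns(m)
        assert rec.genomic_interval == (40, 46)
        assert (rec.codon_index, rec.phase) == (4, 0)

    def test_single_exon_has_no_introns(self):
        assert extract_introns(GeneModel("g", "c", "+", ((0, 90),))) == []


class TestSpliceDinucleotides:
    def test_canonical_gt_ag(self):
        genome = {"c": "XXGTAAGTTTCAGXX".replace("X", "A")}
        assert check_splice_dinucleotides(genome, "c", (2, 13), "+")

    def test_gc_donor_is_not_canonical(self):
        genome = {"c": "AAGCAAGTTTCAGAA"}
        assert not check_splice_dinucleotides(genome, "c", (2, 13), "+")

    def test_minus_strand_reads_reverse_complement(self):
        # genomic CT..AC on '-' strand is GT..AG in transcription orientation
        genome = {"c": "AACTTTTTACAA"}
        assert check_splice_dinucleotides(genome, "c", (2, 10), "-")

    def test_too_short_interval(self):
        with pytest.raises(ValueError):
            check_splice_dinucleotides({"c": "ACGT"}, "c", (0, 3), "+")


def _fake_records(entries):
    from ppofam.intron_evolution import IntronRecord

    return [IntronRecord(g, i, (0, 100), codon, phase)
            for i, (g, codon, phase) in enumerate(entries)]


class TestHomologize:
    def test_same_column_same_phase_pools(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        maps = build_coordinate_maps(msa)
        recs = _fake_records([("a", 2, 0), ("b", 2, 0)])
        chars = homologize_introns(recs, maps, ["a", "b"])
        assert len(chars) == 1
        assert chars[0].members == ["a", "b"]
        assert chars[0].presence == {"a": 1, "b": 1}

    def test_same_column_different_phase_splits(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        maps = build_coordinate_maps(msa)
        recs = _fake_records([("a", 2, 0), ("b", 2, 1)])
        assert len(homologize_introns(recs, maps, ["a", "b"])) == 2

    def test_gap_shifted_residues_still_pool(self):
        msa = MultipleAlignment(["a", "b"], ["AC-DEF", "ACCDEF"])
        maps = build_coordinate_maps(msa)
        # residue 2 of 'a' and residue 3 of 'b' share column 3
        recs = _fake_records([("a", 2, 0), ("b", 3, 0)])
        assert len(homologize_introns(recs, maps, ["a", "b"])) == 1

    def test_column_tolerance_merges_near_columns(self):
        msa = MultipleAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        maps = build_coordinate_maps(msa)
        recs = _fake_records([("a", 2, 0), ("b", 3, 0)])
        assert len(homologize_introns(recs, maps, ["a", "b"])) == 2
        merged = homologize_introns(recs, maps, ["a", "b"], column_tolerance=1)
        assert len(merged) == 1

    def test_no_introns_gives_empty_list(self):
        msa = MultipleAlignment(["a"], ["ACDEF"])
        assert homologize_introns([], build_coordinate_maps(msa), ["a"]) == []


class TestLabelRegions:
    def _arch(self, gid, n):
        # six equal segments of 10 residues over a 60-residue protein
        segs = {}
        names = ("NTERM", "CUA", "LINKER", "CUB", "DWL", "KFDV")
        for i, nm in enumerate(names):
            segs[nm] = (10 * i, 10 * (i + 1))
        return DomainArchitecture(gid, segs, ())

    def test_codes_and_ordinals_follow_columns(self):
        row = "A" * 60
        msa = MultipleAlignment(["a"], [row])
        maps = build_coordinate_maps(msa)
        archs = {"a": self._arch("a", 60)}
        recs = _fake_records([("a", 5, 0), ("a", 25, 0), ("a", 22, 1),
                              ("a", 45, 0), ("a", 55, 2)])
        chars = homologize_introns(recs, maps, ["a"])
        label_regions(chars, archs, maps)
        labels = {c.alignment_column: c.label for c in chars}
        assert labels == {5: "N1", 22: "L1", 25: "L2", 45: "D1", 55: "K1"}

    def test_intron_before_any_cua_column_is_n(self):
        msa = MultipleAlignment(["a"], ["A" * 60])
        maps = build_coordinate_maps(msa)
        chars = homologize_introns(_fake_records([("a", 0, 0)]), maps, ["a"])
        label_regions(chars, {"a": self._arch("a", 60)}, maps)
        assert chars[0].label == "N1"


class TestFitch:
    def test_all_present_needs_no_changes(self):
        tree = from_newick("((A,B),(C,D));")
        mc, _ = fitch_changes(tree, {x: 1 for x in "ABCD"})
        assert mc == 0

    def test_one_clade_present_is_one_change(self):
        tree = from_newick("((A,B),(C,D));")
        mc, _ = fitch_changes(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert mc == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            tree = random_rooted_tree(n, rng)
            presence = {f"T{i}": int(rng.random() < 0.5) for i in range(n)}
            mc, labelling = fitch_changes(tree, presence)
            oracle_mc, _ = brute_force_parsimony(tree, presence)
            assert mc == oracle_mc

    def test_leaf_mismatch_rejected(self):
        tree = from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_changes(tree, {"A": 1, "B": 0})


class TestDollo:
    def test_presence_confined_to_clade(self):
        tree = from_newick("((A,B),(C,D));")
        rec = dollo_events(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert rec.min_changes == 1
        assert rec.events == [("mrca(A,B)", "GAIN")]

    def test_all_present_gain_at_root(self):
        tree = from_newick("((A,B),(C,D));")
        rec = dollo_events(tree, {x: 1 for x in "ABCD"})
        assert rec.events == [("mrca(A,B,C,D)", "GAIN")]

    def test_straddling_presence_costs_losses(self):
        tree = from_newick("((A,B),(C,D));")
        rec = dollo_events(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert rec.min_changes == 3  # gain at root + losses on B and D
        assert replay_events(tree, rec.root_state, rec.events) == {
            "A": 1, "B": 0, "C": 1, "D": 0}

    def test_never_cheaper_than_fitch(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            tree = random_rooted_tree(n, rng)
            presence = {f"T{i}": int(rng.random() < 0.5) for i in range(n)}
            if not any(presence.values()):
                continue
            mc, _ = fitch_changes(tree, presence)
            assert mc <= dollo_events(tree, presence).min_changes


class TestEnumeration:
    def test_quartet_has_two_scenarios(self):
        tree = from_newick("((A,B),(C,D));")
        scen = enumerate_equally_parsimonious(
            tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert len(scen) == 2
        assert {tuple(s.events) for s in scen} == {
            (("mrca(A,B)", "GAIN"),), (("mrca(C,D)", "LOSS"),)}

    def test_constant_character_single_empty_scenario(self):
        tree = from_newick("((A,B),(C,D));")
        scen = enumerate_equally_parsimonious(tree, {x: 1 for x in "ABCD"},
                                              allow_root_state="1")
        assert len(scen) == 1 and scen[0].events == []

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            tree = random_rooted_tree(n, rng)
            presence = {f"T{i}": int(rng.random() < 0.5) for i in range(n)}
            scen = enumerate_equally_parsimonious(tree, presence)
            _, oracle_count = brute_force_parsimony(tree, presence)
            assert scen[0].n_equally_parsimonious == oracle_count
            assert len(scen) == oracle_count

    def test_every_scenario_replays_to_the_leaves(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            tree = random_rooted_tree(n, rng)
            presence = {f"T{i}": int(rng.random() < 0.5) for i in range(n)}
            for s in enumerate_equally_parsimonious(tree, presence):
                assert replay_events(tree, s.root_state, s.events) == presence

    def test_cap_truncates_but_reports_true_count(self):
        # star-ish deep tree with an alternating pattern has many optima
        tree = random_rooted_tree(8, np.random.default_rng(0))
        presence = {f"T{i}": i % 2 for i in range(8)}
        scen = enumerate_equally_parsimonious(tree, presence, cap=2)
        assert len(scen) == 2
        assert scen[0].n_equally_parsimonious >= 2
        assert all(s.truncated for s in scen)


def test_end_to_end_character_recovery_matches_truth():
    """Planted shared/unique introns are recovered as characters with the
    correct members and region labels (one seeded run; the 100-run study is
    in the acceptance suite)."""
    from ppofam.benchmarks import intron_recovery_study

    result = intron_recovery_study(n_runs=2, seed=77)
    assert result["partition_recovered"] == 2
    assert result["canonical_flags_ok"] == 2
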