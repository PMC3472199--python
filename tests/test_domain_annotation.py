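"""Motif scanning, copper-domain location, segmentation, targeting, logos."""

import math

import numpy as np
import pytest

from ppofam.domain_annotation import (column_information, classify_targeting,
                                      locate_cu_domains, parse_targetp,
                                      scan_motifs, segment_architecture)
from ppofam.io_formats import ProteinSequence
from ppofam.synthetic_family import ArchetypeParams, build_archetype_protein


def motifs(seq, name=None):
    hits = scan_motifs(ProteinSequence("t", seq))
    return [h for h in hits if name is None or h.motif_name == name]


class TestScanMotifs:
    def test_hxxxc_common_and_rare_variants(self):
        assert motifs("HCAYC", "HXXXC")[0].start == 0
        assert motifs("HQSYC", "HXXXC")
        assert motifs("HEAYC", "HXXXC")

    def test_hxxxh_requires_hydrophobic_fourth_position(self):
        assert not motifs("HLTGH", "HXXXH")
        hit, = motifs("HLTMH", "HXXXH")
        assert hit.matched_text == "HLTMH"

    def test_literal_and_window_motifs(self):
        seq = "KFDVGGEFAGSFGGEEEEEVLVIGG"
        assert motifs(seq, "KFDV")[0].start == 0
        assert motifs(seq, "EFAGSF")[0].start == 6
        assert any(h.matched_text == "EEEEEVLVI" for h in motifs(seq, "GLU_RICH"))

    def test_his_run_is_maximal(self):
        hit, = motifs("GGHHHHG", "HIS_RUN")
        assert (hit.start, hit.matched_text) == (2, "HHHH")

    def test_overlapping_hits_sorted_by_start(self):
        hits = motifs("AYAXA")  # AxA at 0 and 2
        starts = [h.start for h in hits if h.motif_name == "AXA"]
        assert starts == [0, 2]

    def test_matched_text_equals_protein_substring(self, archetype):
        seq, _, _ = archetype
        for h in motifs(seq):
            assert seq[h.start:h.start + len(h.matched_text)] == h.matched_text


class TestLocateCuDomains:
    def test_archetype_spans_equal_truth(self, archetype):
        seq, bounds, _ = archetype
        cua, cub = locate_cu_domains(ProteinSequence("a", seq))
        assert cua.span == bounds["CUA"]
        assert cub.span == bounds["CUB"]

    def test_protein_without_hxxxc_fails_cua(self):
        p = ProteinSequence("t", "G" * 200)
        cua, cub = locate_cu_domains(p)
        assert not cua.found_anchor and cua.n_his == 0

    def test_second_anchor_chosen_when_first_lacks_histidines(self):
        # first HxxxC at 0 has no further His nearby; second at 70 does
        seq = ("HAAAC" + "G" * 65
               + "HCAYC" + "G" * 17 + "H" + "G" * 22 + "H" + "G" * 60)
        cua, _ = locate_cu_domains(ProteinSequence("t", seq))
        assert cua.located and cua.span[0] == 70

    def test_invariant_phenylalanine_required_for_cub(self):
        # constructed: valid CuA, candidate HxxxH at the right distance but
        # with no F in its window -> CuB not located
        seq = ("HCAYC" + "G" * 17 + "H" + "G" * 22 + "H"
               + "G" * 60 + "HRVMH" + "G" * 20 + "H" + "G" * 40)
        cua, cub = locate_cu_domains(ProteinSequence("t", seq))
        assert cua.located
        assert cub.found_anchor and not cub.located


class TestSegmentation:
    def test_archetype_boundaries_exact(self, archetype):
        seq, bounds, _ = archetype
        p = ProteinSequence("a", seq)
        cua, cub = locate_cu_domains(p)
        arch = segment_architecture(p, cua, cub)
        assert arch.segments == bounds
        # segments tile the protein
        spans = [arch.segments[k] for k in
                 ("NTERM", "CUA", "LINKER", "CUB", "DWL", "KFDV")]
        assert spans[0][0] == 0 and spans[-1][1] == len(seq)
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c

    def test_his_positions_inside_spans(self, archetype):
        seq, _, _ = archetype
        p = ProteinSequence("a", seq)
        cua, cub = locate_cu_domains(p)
        for pos in cua.his_positions:
            assert cua.span[0] <= pos < cua.span[1]
        for pos in cub.his_positions:
            assert cub.span[0] <= pos < cub.span[1]

    def test_late_yxy_extends_dwl(self):
        seq = ("HCAYC" + "G" * 17 + "H" + "G" * 22 + "H" + "G" * 60
               + "HRVMH" + "GGF" + "G" * 37 + "H"
               + "G" * 55 + "YDY" + "G" * 60)
        p = ProteinSequence("t", seq)
        cua, cub = locate_cu_domains(p)
        arch = segment_architecture(p, cua, cub)
        yxy_start = cub.span[1] + 55
        assert arch.segments["DWL"][1] == yxy_start + 3

    def test_protein_ending_inside_dwl_window_flags_empty_kfdv(self):
        seq = ("HCAYC" + "G" * 17 + "H" + "G" * 22 + "H" + "G" * 60
               + "HRVMH" + "GGF" + "G" * 37 + "H" + "G" * 30)
        p = ProteinSequence("t", seq)
        cua, cub = locate_cu_domains(p)
        arch = segment_architecture(p, cua, cub)
        assert arch.kfdv_empty
        s, e = arch.segments["KFDV"]
        assert s == e


class TestTargeting:
    def test_ctp_variant(self):
        rng = np.random.default_rng(4)
        seq, _, _ = build_archetype_protein(ArchetypeParams(targeting="CTP"), rng)
        cls, score = classify_targeting(ProteinSequence("t", seq))
        assert cls == "CTP" and score >= 0.15

    def test_sp_variant(self):
        rng = np.random.default_rng(4)
        seq, _, _ = build_archetype_protein(ArchetypeParams(targeting="SP"), rng)
        cls, score = classify_targeting(ProteinSequence("t", seq))
        assert cls == "SP" and score >= 2.5

    def test_mature_core_is_unknown(self):
        rng = np.random.default_rng(4)
        seq, bounds, _ = build_archetype_protein(ArchetypeParams(), rng)
        core = seq[bounds["CUA"][0]:]
        cls, _ = classify_targeting(ProteinSequence("t", core))
        assert cls == "UNKNOWN"

    def test_short_protein_unknown(self):
        cls, _ = classify_targeting(ProteinSequence("t", "MSSSS"))
        assert cls == "UNKNOWN"

    def test_external_table_overrides(self, tmp_path):
        table = tmp_path / "targetp.txt"
        table.write_text("# name code score\ng1 C 0.93\ng2 S 0.88\ng3 _ 0.1\n")
        ext = parse_targetp(table)
        assert ext == {"g1": ("CTP", 0.93), "g2": ("SP", 0.88),
                       "g3": ("UNKNOWN", 0.1)}
        cls, score = classify_targeting(
            ProteinSequence("g1", "G" * 50), external=ext)
        assert (cls, score) == ("CTP", 0.93)


class TestColumnInformation:
    def test_fully_conserved_column(self):
        bits = column_information(["H"] * 20)
        assert bits[0] == pytest.approx(math.log2(20), abs=1e-9)

    def test_two_residue_even_split(self):
        bits = column_information(["E"] * 10 + ["D"] * 10)
        assert bits[0] == pytest.approx(math.log2(20) - 1, abs=1e-9)

    def test_uniform_column_is_zero(self):
        bits = column_information(list("ARNDCQEGHILKMFPSTWYV"))
        assert bits[0] == pytest.approx(0.0, abs=1e-9)

    def test_gappy_column_reported_missing(self):
        rows = ["A-", "A-", "AA", "A-"]
        bits = column_information(rows)
        assert bits[0] is not None and bits[1] is None

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            column_information(["AA", "A"])
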