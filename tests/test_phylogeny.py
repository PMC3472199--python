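"""Distances, Dayhoff correction, NJ, rooting, bootstrap."""

import numpy as np
import pytest

from ppofam.alignment_core import MultipleAlignment
from ppofam.benchmarks import random_binary_tree, tree_distance_matrix
from ppofam.pam import SaturationError
from ppofam.phylogeny import (DistanceMatrix, bootstrap_support,
                              dayhoff_distance, dayhoff_distances,
                              neighbor_joining, pairwise_pdistance,
                              root_with_outgroup)
from ppofam.tree import from_newick, to_newick


class TestPDistance:
    def test_identical_rows(self):
        msa = MultipleAlignment(["a", "b"], ["ACDE", "ACDE"])
        assert pairwise_pdistance(msa).values[0, 1] == 0.0

    def test_half_differing(self):
        msa = MultipleAlignment(["a", "b"], ["A" * 10, "A" * 5 + "C" * 5])
        dm = pairwise_pdistance(msa)
        assert dm.values[0, 1] == 0.5
        assert dm.n_sites_used[0, 1] == 10

    def test_pairwise_deletion_hand_count(self):
        msa = MultipleAlignment(["a", "b"], ["AC-D", "ACE-"])
        dm = pairwise_pdistance(msa, "pairwise")
        assert dm.n_sites_used[0, 1] == 2
        assert dm.values[0, 1] == 0.0

    def test_complete_deletion_drops_gapped_columns(self):
        msa = MultipleAlignment(["a", "b", "c"],
                                ["ACDE", "AC-E", "GCDE"])
        dm = pairwise_pdistance(msa, "complete")
        # column 2 removed everywhere
        assert dm.n_sites_used[0, 1] == 3

    def test_zero_overlap_pair_is_an_error_naming_the_pair(self):
        msa = MultipleAlignment(["a", "b"], ["A--", "-CC"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            pairwise_pdistance(msa)


class TestDayhoffDistance:
    def test_zero_maps_to_zero(self):
        assert dayhoff_distance(0.0) == 0.0

    def test_monotone_and_inflating(self):
        grid = np.linspace(0.01, 0.85, 40)
        values = [dayhoff_distance(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert all(d > p for p, d in zip(grid, values))

    def test_saturation_flagged(self):
        with pytest.raises(SaturationError):
            dayhoff_distance(0.95)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D,
                                               np.ones((3, 3), dtype=int)))
        lengths = {n.name: n.length for n in tree.children}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_two_taxa_degenerate(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B"], D,
                                               np.ones((2, 2), dtype=int)))
        assert [n.length for n in tree.children] == [0.2, 0.2]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_additive_matrix_recovers_tree_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"T{i}" for i in range(int(rng.integers(5, 9)))]
        true = random_binary_tree(names, rng)
        tnames, D = tree_distance_matrix(true)
        nj = neighbor_joining(DistanceMatrix(tnames, D,
                                             np.ones_like(D, dtype=int)))
        assert nj.bipartitions() == true.bipartitions()
        _, D2 = tree_distance_matrix(nj)
        perm = [nj.leaf_names().index(x) for x in tnames]
        assert np.abs(D - D2[np.ix_(perm, perm)]).max() < 1e-9

    def test_bipartitions_invariant_under_leaf_permutation(self):
        rng = np.random.default_rng(7)
        names = [f"T{i}" for i in range(6)]
        true = random_binary_tree(names, rng)
        tnames, D = tree_distance_matrix(true)
        ref = neighbor_joining(DistanceMatrix(
            tnames, D, np.ones_like(D, dtype=int))).bipartitions()
        perm = list(rng.permutation(len(tnames)))
        pnames = [tnames[i] for i in perm]
        pD = D[np.ix_(perm, perm)]
        permuted = neighbor_joining(DistanceMatrix(
            pnames, pD, np.ones_like(pD, dtype=int))).bipartitions()
        assert permuted == ref

    def test_tie_break_joins_lexicographically_smallest_pair(self):
        # perfectly symmetric quartet: every off-diagonal Q is tied
        D = np.full((4, 4), 1.0)
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(["D", "C", "B", "A"], D,
                                               np.ones((4, 4), dtype=int)))
        assert frozenset({"C", "D"}) in tree.bipartitions()


class TestRooting:
    def test_outgroup_pendant_edge_split_in_half(self):
        tree = from_newick("((A:1,B:2):1,(C:1,D:1):2,O:4);")
        rooted = root_with_outgroup(tree, "O")
        og = next(l for l in rooted.leaves() if l.name == "O")
        assert og.length == 2.0
        assert og.parent is rooted
        ingroup = next(c for c in rooted.children if c is not og)
        assert set(ingroup.leaf_names()) == {"A", "B", "C", "D"}

    def test_rooting_preserves_bipartitions(self):
        tree = from_newick("((A:1,B:2):1,(C:1,D:1):2,O:4);")
        rooted = root_with_outgroup(tree, "O")
        assert rooted.bipartitions() == tree.bipartitions()

    def test_missing_outgroup(self):
        tree = from_newick("(A:1,B:2,C:1);")
        with pytest.raises(ValueError, match="outgroup"):
            root_with_outgroup(tree, "Z")


@pytest.fixture(scope="module")
def family_msa(default_family, family_proteins):
    from ppofam.alignment_core import progressive_align

    valid = sorted(default_family.truth.valid_ids)
    return progressive_align(
        {g: family_proteins[g][1].residues for g in valid})


class TestBootstrap:
    def test_single_replicate_gives_binary_supports(self, family_msa):
        _, supports = bootstrap_support(family_msa, reps=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_supports_reproducible_given_seed(self, family_msa):
        _, s1 = bootstrap_support(family_msa, reps=20, seed=5)
        _, s2 = bootstrap_support(family_msa, reps=20, seed=5)
        assert s1 == s2

    def test_tree_labels_are_integer_percent(self, family_msa):
        tree, supports = bootstrap_support(family_msa, reps=10, seed=1)
        for node in tree.postorder():
            if node is not tree and not node.is_leaf() and node.label:
                assert node.label == str(int(node.label))


def test_dayhoff_distances_on_simulated_divergence():
    """Corrected distance between sequences a known number of PAM steps apart
    is close to truth (single long pair; the full bias study lives in the
    acceptance suite)."""
    from ppofam import pam

    rng = np.random.default_rng(0)
    anc = pam.sample_equilibrium(5000, rng)
    der = pam.evolve(anc, 50, rng)
    msa = MultipleAlignment(["anc", "der"],
                            [pam.indices_to_str(anc), pam.indices_to_str(der)])
    d = dayhoff_distances(msa).values[0, 1]
    assert d == pytest.approx(0.5, rel=0.1)
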