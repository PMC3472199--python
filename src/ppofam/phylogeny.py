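"""Distance phylogeny: Dayhoff-corrected distances, neighbor joining,
outgroup rooting, and bootstrap bipartition support.

This implements the classic protein distance workflow (NJ on a Dayhoff-model
corrected distance matrix) at the model level: observed p-distances
are corrected by numerically inverting the Dayhoff PAM expected-difference
curve (:mod:`ppofam.pam`), trees are built with Saitou & Nei's Q-criterion,
and support values are bootstrap proportions of bipartitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import pam
from .alignment_core import MultipleAlignment
from .pam import SaturationError, dayhoff_distance
from .tree import Node, reroot_above

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "pairwise_pdistance", "dayhoff_distance",
    "dayhoff_distances", "neighbor_joining", "root_with_outgroup",
    "bootstrap_support", "SaturationError",
]


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray        # symmetric, zero diagonal
    n_sites_used: np.ndarray  # per-pair comparable sites

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any() or (v < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")


def _encode_rows(msa: MultipleAlignment) -> np.ndarray:
    code = {a: i for i, a in enumerate("ARNDCQEGHILKMFPSTWYVX")}
    out = np.full((len(msa.rows), msa.column_count), -1, dtype=np.int16)
    for i, row in enumerate(msa.matrix):
        for j, ch in enumerate(row):
            out[i, j] = code.get(ch, -1) if ch != "-" else -1
    return out


def pairwise_pdistance(msa: MultipleAlignment,
                       deletion_mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing sites among comparable sites.

    ``pairwise`` compares, per pair, only columns where both rows hold a
    residue; ``complete`` first drops every column containing a gap anywhere.
    A pair with zero comparable sites is an error naming the pair.
    """
    if deletion_mode not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    M = _encode_rows(msa)
    if deletion_mode == "complete":
        M = M[:, (M >= 0).all(axis=0)]
    n = len(msa.rows)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = (M[i] >= 0) & (M[j] >= 0)
            ns = int(both.sum())
            if ns == 0:
                raise ValueError(
                    f"no comparable sites between {msa.rows[i]!r} and {msa.rows[j]!r}")
            p = float((M[i, both] != M[j, both]).sum() / ns)
            values[i, j] = values[j, i] = p
            sites[i, j] = sites[j, i] = ns
    return DistanceMatrix(list(msa.rows), values, sites)


def dayhoff_distances(msa: MultipleAlignment,
                      deletion_mode: str = "pairwise") -> DistanceMatrix:
    """Dayhoff-corrected evolutionary distances (substitutions/site).

    Raises :class:`SaturationError` if any pair's p-distance lies beyond the
    PAM curve's invertible range.
    """
    pd = pairwise_pdistance(msa, deletion_mode)
    corrected = np.zeros_like(pd.values)
    n = len(pd.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = dayhoff_distance(pd.values[i, j])
            except SaturationError as e:
                raise SaturationError(
                    f"pair ({pd.taxa[i]}, {pd.taxa[j]}): {e}") from None
            corrected[i, j] = corrected[j, i] = d
    return DistanceMatrix(pd.taxa, corrected, pd.n_sites_used)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating
    root surrogate). Negative branch-length estimates are clamped to zero
    with the deficit moved to the sister branch. Tie-break on equal Q values:
    the pair whose (lexicographically smallest member, then other member)
    sorts first is joined.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]
    labels: list[str] = list(dm.taxa)  # min leaf name per cluster, for ties
    D = dm.values.astype(float).copy()
    if n == 2:
        log.warning("neighbor joining on 2 taxa: degenerate single-edge tree")
        root = Node()
        for node in nodes:
            node.length = D[0, 1] / 2.0
            root.add(node)
        return root

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                if Q[ai, aj] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((labels[active[ai]], labels[active[aj]])))
                    if best is None or key < best[0]:
                        best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2.0 + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # new cluster replaces i; distances by the standard reduction
        for m in active:
            if m in (i, j):
                continue
            D[i, m] = D[m, i] = (D[i, m] + D[j, m] - dij) / 2.0
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    root = Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return root


def root_with_outgroup(tree: Node, outgroup_id: str) -> Node:
    """Root at the midpoint of the outgroup's pendant edge (the ingroup
    becomes monophyletic relative to the new root)."""
    work = tree.copy()
    leaf = work.find_leaf(outgroup_id)
    if leaf is None:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    return reroot_above(leaf)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    msa: MultipleAlignment,
    reps: int,
    seed: int,
    deletion_mode: str = "pairwise",
) -> tuple[Node, dict[frozenset, float]]:
    """Column bootstrap of the distance+NJ pipeline.

    Resamples alignment columns with replacement, recomputes Dayhoff
    distances and the NJ tree, and reports for each internal edge of the
    original tree the percentage of replicates containing the same
    bipartition. Replicates with a saturated or zero-overlap pair are
    redrawn (at most ``10 * reps`` attempts in total). The returned tree's
    internal nodes carry integer percent labels.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = neighbor_joining(dayhoff_distances(msa, deletion_mode))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = msa.column_count
    done = attempts = 0
    while done < reps:
        if attempts >= 10 * reps:
            raise RuntimeError("too many degenerate bootstrap replicates")
        attempts += 1
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row[c] for c in cols) for row in msa.matrix]
        rep_msa = MultipleAlignment(list(msa.rows), rep_rows)
        try:
            rep_tree = neighbor_joining(dayhoff_distances(rep_msa, deletion_mode))
        except (SaturationError, ValueError):
            continue
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    supports = {s: 100.0 * c / reps for s, c in counts.items()}
    _annotate_supports(tree, supports)
    return tree, supports


def _annotate_supports(tree: Node, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    for node in tree.postorder():
        if node is tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.label = str(int(round(supports[side])))
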