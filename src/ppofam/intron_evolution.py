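"""Intron mapping, homologization and gain/loss reconstruction.

Introns are located from gene-model exon structure, given protein-level
coordinates (codon index + phase), checked for the canonical U2-type GT..AG
terminal dinucleotides, projected onto alignment columns, and pooled into
cross-gene homology classes (identical column AND identical phase). Gain and
loss events are reconstructed on the rooted gene tree by Fitch (minimum
changes, via unit-cost Sankoff so multifurcations are handled) and by Dollo
parsimony (single gain, minimal losses); all equally parsimonious scenarios
can be enumerated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .alignment_core import CoordinateMap
from .domain_annotation import DomainArchitecture
from .io_formats import GeneModel
from .tree import Node

log = logging.getLogger(__name__)

#: Figure-style region codes, 5' to 3' along the protein.
REGION_CODES = ("N", "A", "L", "D", "K", "C")

_SEGMENT_TO_CODE = {
    "NTERM": "N", "CUA": "A", "LINKER": "L",
    # the naming scheme has no CuB code; CuB introns fold into the
    # CuA..CuB "middle" label (see docs/methods.md)
    "CUB": "L",
    "DWL": "D", "KFDV": "K",
}


@dataclass
class IntronRecord:
    gene_id: str
    intron_index: int                 # 5'->3' order, 0-based
    genomic_interval: tuple[int, int]
    codon_index: int                  # complete codons 5' of the intron
    phase: int                        # CDS nucleotides 5' of the intron, mod 3
    canonical: bool | None = None

    @property
    def length_nt(self) -> int:
        s, e = self.genomic_interval
        return e - s


@dataclass
class IntronCharacter:
    character_id: str
    alignment_column: int
    phase: int
    region_code: str = "?"
    ordinal: int = 0
    members: list[str] = field(default_factory=list)
    presence: dict[str, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.region_code}{self.ordinal}"


@dataclass
class EventReconstruction:
    character_id: str
    method: str                       # FITCH or DOLLO
    min_changes: int
    events: list[tuple[str, str]]     # (edge = child-node id, GAIN|LOSS)
    n_equally_parsimonious: int = 1
    root_state: int = 0
    truncated: bool = False


# ---------------------------------------------------------------------------
# physical introns


def extract_introns(model: GeneModel) -> list[IntronRecord]:
    """Introns = gaps between consecutive exons, in transcription order.

    ``codon_index`` and ``phase`` come from the cumulative exonic length 5'
    of each intron (on the transcript). Single-exon models yield no introns.
    """
    exons = list(model.exons)
    if model.strand == "-":
        exons = exons[::-1]
    records = []
    cum = 0
    for k in range(len(exons) - 1):
        cum += exons[k][1] - exons[k][0]
        if model.strand == "+":
            interval = (exons[k][1], exons[k + 1][0])
        else:
            interval = (exons[k + 1][1], exons[k][0])
        records.append(IntronRecord(
            gene_id=model.gene_id, intron_index=k, genomic_interval=interval,
            codon_index=cum // 3, phase=cum % 3,
        ))
    return records


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def check_splice_dinucleotides(genome: dict[str, str], seq_id: str,
                               interval: tuple[int, int], strand: str) -> bool:
    """True iff the intron, read in transcription orientation, starts GT and
    ends AG (canonical U2-type)."""
    s, e = interval
    if e - s < 4:
        raise ValueError(f"intron interval ({s},{e}) too short to splice")
    seq = genome[seq_id][s:e].upper()
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq.startswith("GT") and seq.endswith("AG")


def annotate_canonical(records: list[IntronRecord], genome: dict[str, str],
                       models: dict[str, GeneModel]) -> None:
    for rec in records:
        m = models[rec.gene_id]
        rec.canonical = check_splice_dinucleotides(
            genome, m.seq_id, rec.genomic_interval, m.strand)


# ---------------------------------------------------------------------------
# homologization


def homologize_introns(
    records: list[IntronRecord],
    maps: dict[str, CoordinateMap],
    gene_ids: list[str],
    column_range: tuple[int, int] | None = None,
    column_tolerance: int = 0,
) -> list[IntronCharacter]:
    """Pool introns into homology classes: identical alignment column and
    identical phase (``column_tolerance`` > 0 additionally merges classes
    whose columns differ by at most that many columns, same phase; default 0
    is the strict, reproducible criterion).

    The intron's protein-level position is the residue whose codon it
    interrupts (or precedes, for phase 0), projected through the gene's
    untrimmed coordinate map. ``column_range`` marks the core span; introns
    projecting outside it are still reported (their region label will come
    out N or C).
    """
    groups: dict[tuple[int, int], list[IntronRecord]] = {}
    for rec in records:
        if rec.gene_id not in maps:
            log.warning("%s: no alignment row; intron %d skipped",
                        rec.gene_id, rec.intron_index)
            continue
        r2c = maps[rec.gene_id].residue_to_column
        residue = min(rec.codon_index, len(r2c) - 1)
        col = int(r2c[residue])
        groups.setdefault((col, rec.phase), []).append(rec)

    if column_tolerance > 0:
        merged: dict[tuple[int, int], list[IntronRecord]] = {}
        for (col, phase) in sorted(groups):
            placed = False
            for (mc, mp) in list(merged):
                if mp == phase and abs(mc - col) <= column_tolerance:
                    merged[(mc, mp)].extend(groups[(col, phase)])
                    placed = True
                    break
            if not placed:
                merged[(col, phase)] = list(groups[(col, phase)])
        groups = merged

    characters = []
    for idx, (col, phase) in enumerate(sorted(groups), 1):
        members = sorted({r.gene_id for r in groups[(col, phase)]})
        characters.append(IntronCharacter(
            character_id=f"I{idx:02d}",
            alignment_column=col,
            phase=phase,
            members=members,
            presence={g: int(g in members) for g in gene_ids},
        ))
    return characters


def label_regions(
    characters: list[IntronCharacter],
    architectures: dict[str, DomainArchitecture],
    maps: dict[str, CoordinateMap],
) -> None:
    """Assign N/A/L/D/K/C region codes and per-code ordinals (1-based, by
    ascending column). The code is the majority segment of the character's
    column across member rows' architectures; a column 3' of a member's last
    residue counts as C."""
    for ch in characters:
        votes: dict[str, int] = {}
        for gid in ch.members:
            arch = architectures.get(gid)
            cmap = maps.get(gid)
            if arch is None or cmap is None:
                continue
            c2r = cmap.column_to_residue
            res = int(c2r[ch.alignment_column]) if ch.alignment_column < len(c2r) else -1
            if res < 0:
                # gap at this member's column: nearest following residue
                later = [r for r in c2r[ch.alignment_column:] if r >= 0]
                res = int(later[0]) if later else -1
            if res < 0 or res >= len(cmap.residue_to_column):
                code = "C"
            else:
                seg = arch.segment_of(res)
                code = _SEGMENT_TO_CODE.get(seg, "C") if seg else "C"
            votes[code] = votes.get(code, 0) + 1
        if votes:
            best = max(sorted(votes), key=lambda k: votes[k])
            ch.region_code = best
        else:
            ch.region_code = "?"
    for code in REGION_CODES:
        same = sorted((c for c in characters if c.region_code == code),
                      key=lambda c: c.alignment_column)
        for rank, c in enumerate(same, 1):
            c.ordinal = rank


# ---------------------------------------------------------------------------
# parsimony


def _node_ids(tree: Node) -> dict[Node, str]:
    """Stable node identifiers: leaf name, or mrca(...) over sorted leaves."""
    ids = {}
    for node in tree.postorder():
        if node.is_leaf():
            ids[node] = node.name
        else:
            ids[node] = "mrca(" + ",".join(sorted(node.leaf_names())) + ")"
    return ids


def _sankoff_costs(tree: Node, presence: dict[str, int]) -> dict[Node, list[int]]:
    """Unit-cost small parsimony DP for a binary character (handles
    multifurcating nodes, where classic Fitch set operations would not)."""
    INF = 10 ** 9
    cost: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            state = presence[node.name]
            cost[node] = [0 if s == state else INF for s in (0, 1)]
        else:
            c = [0, 0]
            for child in node.children:
                cc = cost[child]
                for s in (0, 1):
                    c[s] += min(cc[0] + (s != 0), cc[1] + (s != 1))
            cost[node] = c
    return cost


def fitch_changes(tree: Node, presence: dict[str, int]) -> tuple[int, dict[str, int]]:
    """Minimum number of gain/loss state changes and one optimal ancestral
    labelling (ties resolved toward state 0, absent)."""
    _check_leaves(tree, presence)
    cost = _sankoff_costs(tree, presence)
    labelling: dict[str, int] = {}
    ids = _node_ids(tree)

    def assign(node: Node, state: int) -> None:
        labelling[ids[node]] = state
        for child in node.children:
            cc = cost[child]
            best = min(cc[0] + (state != 0), cc[1] + (state != 1))
            child_state = 0 if cc[0] + (state != 0) == best else 1
            assign(child, child_state)

    root_cost = cost[tree]
    root_state = 0 if root_cost[0] <= root_cost[1] else 1
    assign(tree, root_state)
    return min(root_cost), labelling


def _check_leaves(tree: Node, presence: dict[str, int]) -> None:
    names = set(tree.leaf_names())
    if names != set(presence):
        raise ValueError("presence vector leaves do not match tree leaves")


def _events_from_labelling(tree: Node, labelling: dict[str, int]) -> list[tuple[str, str]]:
    ids = _node_ids(tree)
    events = []
    for node in tree.preorder():
        if node is tree:
            continue
        parent_state = labelling[ids[node.parent]]
        state = labelling[ids[node]]
        if state != parent_state:
            events.append((ids[node], "GAIN" if state == 1 else "LOSS"))
    return events


def dollo_events(tree: Node, presence: dict[str, int],
                 character_id: str = "") -> EventReconstruction:
    """Dollo parsimony: a single gain on the edge above the MRCA of the
    presence leaves, plus the minimal set of losses below it."""
    _check_leaves(tree, presence)
    present = [l for l in tree.leaves() if presence[l.name] == 1]
    if not present:
        raise ValueError("Dollo reconstruction requires presence in >= 1 leaf")
    ids = _node_ids(tree)

    # MRCA of presence leaves
    paths = []
    for leaf in present:
        path = []
        n: Node | None = leaf
        while n is not None:
            path.append(n)
            n = n.parent
        paths.append(path[::-1])
    mrca = None
    for level in zip(*paths):
        if all(x is level[0] for x in level):
            mrca = level[0]
        else:
            break

    events = [(ids[mrca], "GAIN")]
    losses = []

    def walk(node: Node) -> None:
        # maximal all-absent subtrees get one loss on their root edge
        for child in node.children:
            if all(presence[l.name] == 0 for l in child.leaves()):
                losses.append((ids[child], "LOSS"))
            else:
                walk(child)

    walk(mrca)
    return EventReconstruction(
        character_id=character_id, method="DOLLO",
        min_changes=1 + len(losses), events=events + losses,
        root_state=0,
    )


def enumerate_equally_parsimonious(
    tree: Node,
    presence: dict[str, int],
    allow_root_state: str = "either",
    character_id: str = "",
    cap: int = 10_000,
) -> list[EventReconstruction]:
    """All ancestral labellings achieving the parsimony minimum, decomposed
    into per-edge GAIN/LOSS events. ``allow_root_state`` restricts the root
    to '0', '1' or 'either'. Enumeration stops at ``cap`` scenarios (the
    returned reconstructions carry ``truncated=True`` past the cap, and
    ``n_equally_parsimonious`` always reports the true count)."""
    _check_leaves(tree, presence)
    cost = _sankoff_costs(tree, presence)
    ids = _node_ids(tree)
    root_states = {"0": (0,), "1": (1,), "either": (0, 1)}[allow_root_state]
    best = min(cost[tree][s] for s in root_states)

    # count optimal labellings by DP
    count: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf():
            count[node] = [1 if cost[node][s] == 0 else 0 for s in (0, 1)]
        else:
            cnt = [1, 1]
            for s in (0, 1):
                for child in node.children:
                    cc = cost[child]
                    opt = min(cc[0] + (s != 0), cc[1] + (s != 1))
                    ways = sum(count[child][t]
                               for t in (0, 1) if cc[t] + (s != t) == opt)
                    cnt[s] *= ways
            count[node] = cnt
    total = sum(count[tree][s] for s in root_states if cost[tree][s] == best)

    scenarios: list[dict[str, int]] = []

    def enumerate_labellings(root_state: int) -> None:
        stack_nodes = [n for n in tree.preorder()]

        def rec(idx: int, labelling: dict[str, int]) -> None:
            if len(scenarios) >= cap:
                return
            if idx == len(stack_nodes):
                scenarios.append(dict(labelling))
                return
            node = stack_nodes[idx]
            if node is tree:
                labelling[ids[node]] = root_state
                rec(idx + 1, labelling)
                return
            parent_state = labelling[ids[node.parent]]
            cc = cost[node]
            opt = min(cc[0] + (parent_state != 0), cc[1] + (parent_state != 1))
            for t in (0, 1):
                if cc[t] + (parent_state != t) == opt:
                    labelling[ids[node]] = t
                    rec(idx + 1, labelling)
            labelling.pop(ids[node], None)

        rec(0, {})

    for s in root_states:
        if cost[tree][s] == best and len(scenarios) < cap:
            enumerate_labellings(s)

    out = []
    truncated = total > len(scenarios)
    for lab in scenarios:
        out.append(EventReconstruction(
            character_id=character_id, method="FITCH",
            min_changes=best, events=_events_from_labelling(tree, lab),
            n_equally_parsimonious=total, root_state=lab[ids[tree]],
            truncated=truncated,
        ))
    return out


def replay_events(tree: Node, root_state: int,
                  events: list[tuple[str, str]]) -> dict[str, int]:
    """Replay per-edge events from the root state down to the leaves."""
    ids = _node_ids(tree)
    by_edge = {}
    for edge, kind in events:
        by_edge.setdefault(edge, []).append(kind)
    states: dict[str, int] = {}

    def walk(node: Node, state: int) -> None:
        for kind in by_edge.get(ids[node], []):
            state = 1 if kind == "GAIN" else 0
        states[ids[node]] = state
        for child in node.children:
            walk(child, state)

    walk(tree, root_state)
    return {l.name: states[l.name] for l in tree.leaves()}
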