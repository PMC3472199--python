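"""Truth-known synthetic PPO-like gene families.

The generator emulates the statistical structure a multi-species PPO survey
assumes: an archetype protein with the canonical domain architecture
(serine-rich transit peptide or hydrophobic signal peptide, HxxxC-anchored
CuA, ~100-residue linker, HxxxH-anchored CuB with its invariant
phenylalanine, DWL with the YxY processing motif, KFDV with the Glu-rich /
KFDV / EFAGSF motifs and a His run), a birth–death gene tree along a species
tree, Dayhoff(PAM)-chain sequence evolution with motif residues held
invariant (purifying selection on functional sites), spliceosomal introns at
a fixed menu of candidate positions with gain/loss events on tree edges, and
decoy gene models violating exactly one validation rule each.

Background (non-motif) sites avoid histidine and cysteine — both in the
initial draw and in the substitution process — so copper-domain anchors are
unambiguous in truth. Everything is reproducible: one seed, byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import pam
from .io_formats import GeneModel, write_fasta, write_gff3, write_tsv
from .tree import Node, from_newick, to_newick

DEFAULT_SPECIES_TREE = "((S1:0.2,S2:0.2):0.2,(S3:0.2,S4:0.2):0.2);"

DECOY_CLASSES = ("TOO_SHORT", "PREMATURE_STOP", "MISSING_HIS", "INCOMPLETE_DOMAIN")

#: background alphabet: everything but His and Cys (reserved for motifs)
_BG_MASK = np.array([aa not in "HC" for aa in pam.AA])

_STANDARD_CODONS = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}


# ---------------------------------------------------------------------------
# configuration and truth containers


@dataclass(frozen=True)
class ArchetypeParams:
    """Segment lengths (residues) of the archetype protein. Defaults follow
    the canonical PPO layout: ~50-aa copper domains separated by a ~100-aa
    linker, a 50-aa DWL and a 140–150-aa KFDV region."""

    nterm_len: int = 75      # 60–90 typical
    cua_len: int = 46        # HxxxC anchor .. third His inclusive
    linker_len: int = 100
    cub_len: int = 46        # HxxxH anchor .. third His inclusive
    dwl_len: int = 50
    kfdv_len: int = 145      # 140–150 typical
    targeting: str = "CTP"   # CTP or SP archetype
    ser_count: int = 11      # serines planted in the first 35 residues (CTP)

    @property
    def total(self) -> int:
        return (self.nterm_len + self.cua_len + self.linker_len
                + self.cub_len + self.dwl_len + self.kfdv_len)


@dataclass(frozen=True)
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    duplication_rate: float = 0.8    # events per gene per unit branch length
    loss_rate: float = 0.25
    root_gene_count: int = 1
    pam_scale: float = 1.0           # multiplier: branch length -> PAM steps/100
    intron_gain_rate: float = 0.3    # per absent slot per unit branch length
    intron_loss_rate: float = 0.3    # per present slot per unit branch length
    intron_length_range: tuple[int, int] = (60, 400)
    ancestral_introns: tuple[str, ...] = ("L1",)
    forced_intron_events: tuple = ()  # (kind, slot_id, (leaf, ...)) at the MRCA edge
    decoy_spec: dict = field(default_factory=dict)
    gc_decoy_intron: bool = False     # plant one GC..AG intron (non-canonical)
    archetype: ArchetypeParams = ArchetypeParams()
    spacer_min: int = 500
    seed: int = 0

    def __post_init__(self):
        for r in (self.duplication_rate, self.loss_rate, self.intron_gain_rate,
                  self.intron_loss_rate, self.pam_scale):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.intron_length_range[0] < 4:
            raise ValueError("minimum intron length must leave room for GT..AG")


@dataclass
class TruthGene:
    gene_id: str
    species: str
    validity_class: str              # VALID or a decoy class
    protein: str
    boundaries: dict[str, tuple[int, int]]
    targeting: str
    intron_slots: tuple[str, ...]


@dataclass
class TruthLog:
    genes: dict[str, TruthGene] = field(default_factory=dict)
    events: list[tuple[str, str, str, int, int]] = field(default_factory=list)
    gene_tree_newick: str = ""
    slots: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def valid_ids(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.validity_class == "VALID"}


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    genomes: dict[str, str]
    models: list[GeneModel]
    truth: TruthLog
    gene_tree: Node | None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genomes):
            write_fasta({sp: self.genomes[sp]}, out / f"{sp}.fasta")
        write_gff3(self.models, out / "family.gff3")
        write_tsv(out / "truth_genes.tsv",
                  ["gene_id", "species", "class", "targeting", "intron_slots",
                   "boundaries", "protein"],
                  [(t.gene_id, t.species, t.validity_class, t.targeting,
                    ",".join(t.intron_slots),
                    ";".join(f"{k}:{s}-{e}" for k, (s, e) in t.boundaries.items()),
                    t.protein)
                   for t in (self.truth.genes[g] for g in sorted(self.truth.genes))])
        write_tsv(out / "truth_intron_events.tsv",
                  ["edge", "type", "slot", "codon_index", "phase"],
                  self.truth.events)
        (out / "gene_tree.nwk").write_text(self.truth.gene_tree_newick + "\n")


# ---------------------------------------------------------------------------
# archetype


def _background(length: int, rng: np.random.Generator) -> np.ndarray:
    freqs = pam.equilibrium_frequencies() * _BG_MASK
    freqs = freqs / freqs.sum()
    return rng.choice(pam.N_AA, size=length, p=freqs)


def build_archetype_protein(
    params: ArchetypeParams, rng: np.random.Generator,
) -> tuple[str, dict[str, tuple[int, int]], np.ndarray]:
    """Build the archetype protein.

    Returns (residue string, true segment boundaries, invariant-site mask).
    Motif residues (anchors, conserved His/Phe, cleavage and C-terminal
    motifs, part of the transit-peptide serines or signal-peptide h-region)
    are marked invariant; they are never substituted during evolution.
    """
    p = params
    if p.cua_len < 46 or p.cub_len < 46:
        raise ValueError("copper domains must be >= 46 residues (anchor..3rd His)")
    if p.linker_len < 60 or p.linker_len > 160:
        raise ValueError("linker must be 60-160 residues for CuB anchoring")
    if p.dwl_len < 35 or p.kfdv_len < 70:
        raise ValueError("DWL/KFDV segments too small to host their motifs")
    if p.targeting == "CTP" and p.nterm_len < 40:
        raise ValueError("CTP N-terminus too small to host the AxA motif")
    if p.targeting == "SP" and p.nterm_len < 22:
        raise ValueError("SP N-terminus too small to host the h-region")

    seq = _background(p.total, rng)
    invariant = np.zeros(p.total, dtype=bool)
    idx = {a: i for i, a in enumerate(pam.AA)}

    def plant(pos: int, text: str, mark: bool = True) -> None:
        for k, ch in enumerate(text):
            seq[pos + k] = idx[ch]
            if mark:
                invariant[pos + k] = True

    # segment boundaries
    b = {}
    start = 0
    for name, ln in (("NTERM", p.nterm_len), ("CUA", p.cua_len),
                     ("LINKER", p.linker_len), ("CUB", p.cub_len),
                     ("DWL", p.dwl_len), ("KFDV", p.kfdv_len)):
        b[name] = (start, start + ln)
        start += ln

    # N-terminus
    if p.targeting == "CTP":
        ser_pos = rng.choice(35, size=p.ser_count, replace=False)
        for k, pos in enumerate(sorted(ser_pos)):
            plant(int(pos), "S", mark=(k < 6))  # 6 invariant: Ser floor >= 0.17
        axa = p.nterm_len - 20
        if axa < 35:
            axa = 35
        plant(axa, "A")
        plant(axa + 2, "A")
    else:  # SP: hydrophobic h-region at residues 5..20
        for pos in range(5, 13):
            plant(pos, "L")                       # invariant core of the h-region
        hydro = [idx[a] for a in "LIVFA"]
        for pos in range(13, 21):
            seq[pos] = hydro[rng.integers(0, len(hydro))]

    cua, linker, cub, dwl, kfdv = (b["CUA"][0], b["LINKER"][0], b["CUB"][0],
                                   b["DWL"][0], b["KFDV"][0])
    # CuA: HxxxC anchor (most commonly HCAYC) + two further conserved His
    plant(cua, "HCAYC")
    plant(cua + 22, "H")
    plant(cua + p.cua_len - 1, "H")
    # CuB: HxxxH anchor (hydrophobic 4th position), invariant F, third His
    plant(cub, "HRVMH")
    plant(cub + 7, "F")
    plant(cub + p.cub_len - 1, "H")
    # DWL: namesake motif + YxY processing site (inside the 50-aa segment)
    plant(dwl + 2, "DWL")
    plant(dwl + 30, "YDY")
    # keep the DWL extension window free of spurious YxY (background has Y)
    y = idx["Y"]
    for pos in range(dwl, b["DWL"][1]):
        if seq[pos] == y and not invariant[pos]:
            seq[pos] = idx["T"]
    # KFDV region: Glu-rich motif, KFDV, EFAGSF, candidate third Cu His run
    plant(kfdv + 10, "EEEEEVLVI")
    plant(kfdv + 30, "KFDV")
    plant(kfdv + 60, "EFAGSF")
    plant(kfdv + 66, "HHH")

    return pam.indices_to_str(seq), b, invariant


def default_intron_slots(boundaries: dict[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
    """Fixed menu of candidate intron positions: (codon index, phase) keyed
    by slot id. Ids follow the region naming (N/A/L/D/K + ordinal)."""
    return {
        "N1": (boundaries["NTERM"][0] + 30, 0),
        "A1": (boundaries["CUA"][0] + 37, 0),
        "L1": (boundaries["LINKER"][0] + 29, 0),
        "L2": (boundaries["LINKER"][0] + 69, 2),
        "D1": (boundaries["DWL"][0] + 23, 1),
        "K1": (boundaries["KFDV"][0] + 63, 0),
    }


# ---------------------------------------------------------------------------
# gene tree (birth-death along the species tree)


def simulate_gene_tree(species_root: Node, dup: float, loss: float,
                       rng: np.random.Generator,
                       root_gene_count: int = 1) -> Node | None:
    """Duplication/loss birth–death process along the species tree. Returns
    the gene tree (leaves carry their species name in ``.name``) or None if
    every lineage was lost."""

    def branch(sp_node: Node, remaining: float) -> Node | None:
        rate = dup + loss
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if dt >= remaining:
            if sp_node.is_leaf():
                return Node(name=sp_node.name, length=remaining)
            kids = [branch(c, c.length or 0.0) for c in sp_node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += remaining
                return kids[0]
            n = Node(length=remaining)
            for k in kids:
                n.add(k)
            return n
        if rng.random() < (dup / rate if rate > 0 else 0.0):
            halves = [branch(sp_node, remaining - dt) for _ in range(2)]
            halves = [h for h in halves if h is not None]
            if not halves:
                return None
            if len(halves) == 1:
                halves[0].length += dt
                return halves[0]
            n = Node(length=dt)
            for h in halves:
                n.add(h)
            return n
        return None  # lineage lost

    roots = []
    for _ in range(root_gene_count):
        kids = [branch(c, c.length or 0.0) for c in species_root.children]
        kids = [k for k in kids if k is not None]
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0)
            roots.append(kids[0])
        elif kids:
            n = Node(length=0.0)
            for k in kids:
                n.add(k)
            roots.append(n)
    if not roots:
        return None
    if len(roots) == 1:
        root = roots[0]
        root.length = None
        return root
    root = Node()
    for r in roots:
        root.add(r)
    return root


def _name_gene_leaves(gene_tree: Node) -> None:
    counters: dict[str, int] = {}
    for leaf in gene_tree.leaves():
        sp = leaf.name
        counters[sp] = counters.get(sp, 0) + 1
        leaf.name = f"{sp}_g{counters[sp]:02d}"


# ---------------------------------------------------------------------------
# the full simulation


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Generate genomes + gene models + truth for one synthetic family.

    Deterministic: the same config (seed included) produces byte-identical
    output files via :meth:`SimulatedFamily.write`.
    """
    rng = np.random.default_rng(config.seed)
    try:
        sp_root = from_newick(config.species_tree)
    except Exception as e:
        raise ValueError(f"unreadable species tree: {e}") from e

    arch_seq, boundaries, invariant = build_archetype_protein(config.archetype, rng)
    slots = default_intron_slots(boundaries)
    truth = TruthLog(slots=dict(slots))

    gene_tree = simulate_gene_tree(sp_root, config.duplication_rate,
                                   config.loss_rate, rng,
                                   config.root_gene_count)
    if gene_tree is None:
        return SimulatedFamily(config, {}, [], truth, None)
    _name_gene_leaves(gene_tree)
    from .intron_evolution import _node_ids
    ids = _node_ids(gene_tree)

    # --- intron events ------------------------------------------------
    events: list[tuple[str, str, str, int, int]] = []
    present_at: dict[Node, set[str]] = {}
    slot_order = sorted(slots)
    forced_by_edge: dict[str, list[tuple[str, str]]] = {}
    for kind, slot_id, leaf_set in config.forced_intron_events:
        target = _mrca(gene_tree, set(leaf_set))
        forced_by_edge.setdefault(ids[target], []).append((kind, slot_id))

    root_set = set(config.ancestral_introns)
    for s in sorted(root_set):
        events.append((ids[gene_tree], "GAIN", s, *slots[s]))
    present_at[gene_tree] = root_set

    for node in gene_tree.preorder():
        if node is gene_tree:
            continue
        state = set(present_at[node.parent])
        ln = node.length or 0.0
        p_gain = 1.0 - np.exp(-config.intron_gain_rate * ln)
        p_loss = 1.0 - np.exp(-config.intron_loss_rate * ln)
        for s in slot_order:
            if s in state:
                if rng.random() < p_loss:
                    state.discard(s)
                    events.append((ids[node], "LOSS", s, *slots[s]))
            else:
                if rng.random() < p_gain:
                    state.add(s)
                    events.append((ids[node], "GAIN", s, *slots[s]))
        for kind, slot_id in forced_by_edge.get(ids[node], []):
            if kind == "GAIN" and slot_id not in state:
                state.add(slot_id)
                events.append((ids[node], "GAIN", slot_id, *slots[slot_id]))
            elif kind == "LOSS" and slot_id in state:
                state.discard(slot_id)
                events.append((ids[node], "LOSS", slot_id, *slots[slot_id]))
        present_at[node] = state
    truth.events = events

    # --- sequence evolution -------------------------------------------
    var = ~invariant
    seqs: dict[Node, np.ndarray] = {gene_tree: pam.str_to_indices(arch_seq)}
    for node in gene_tree.preorder():
        if node is gene_tree:
            continue
        steps = int(round((node.length or 0.0) * 100.0 * config.pam_scale))
        parent_seq = seqs[node.parent]
        child = parent_seq.copy()
        if steps > 0:
            child[var] = pam.evolve(parent_seq[var], steps, rng, allowed=_BG_MASK)
        seqs[node] = child

    truth.gene_tree_newick = to_newick(gene_tree)

    # --- assemble genes, decoys and genomes ---------------------------
    leaves = gene_tree.leaves()
    gc_decoy_gene = min((l.name for l in leaves)) if (config.gc_decoy_intron and leaves) else None

    gene_parts: dict[str, list] = {}
    for leaf in leaves:
        gid = leaf.name
        species = gid.rsplit("_g", 1)[0]
        protein = pam.indices_to_str(seqs[leaf])
        cds = _backtranslate(protein, rng)
        slot_ids = tuple(sorted(present_at[leaf], key=lambda s: slots[s]))
        introns = []
        for s in slot_ids:
            codon, phase = slots[s]
            length = int(rng.integers(config.intron_length_range[0],
                                      config.intron_length_range[1] + 1))
            donor = "GC" if (gid == gc_decoy_gene and s == slot_ids[0]) else "GT"
            iseq = donor + _random_nt(length - 4, rng) + "AG"
            introns.append((3 * codon + phase, iseq))
        gene_parts.setdefault(species, []).append((gid, cds, introns))
        truth.genes[gid] = TruthGene(gid, species, "VALID", protein,
                                     dict(boundaries),
                                     config.archetype.targeting, slot_ids)

    _inject_decoy_parts(gene_parts, truth, boundaries, config.decoy_spec, rng)

    genomes: dict[str, str] = {}
    models: list[GeneModel] = []
    for species in sorted(gene_parts):
        chunks: list[str] = []
        pos = 0
        for gid, cds, introns in sorted(gene_parts[species]):
            spacer = _random_nt(config.spacer_min + int(rng.integers(0, 200)), rng)
            chunks.append(spacer)
            pos += len(spacer)
            local_seq, local_exons = _interleave(cds, introns)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                exons = tuple((pos + s, pos + e) for s, e in local_exons)
                chunks.append(local_seq)
            else:
                G = len(local_seq)
                exons = tuple(sorted((pos + G - e, pos + G - s)
                                     for s, e in local_exons))
                chunks.append(_revcomp(local_seq))
            pos += len(local_seq)
            models.append(GeneModel(gene_id=gid, seq_id=species, strand=strand,
                                    exons=exons, source_tag="ppofam_sim"))
        chunks.append(_random_nt(config.spacer_min, rng))
        genomes[species] = "".join(chunks)
    models.sort(key=lambda m: m.gene_id)

    family = SimulatedFamily(config, genomes, models, truth, gene_tree)
    _assert_replay(family, present_at, ids)
    return family


def _assert_replay(family: SimulatedFamily, present_at, ids) -> None:
    """Internal consistency: the event log replays to the emitted introns."""
    from .intron_evolution import replay_events

    tree = family.gene_tree
    for slot in family.truth.slots:
        ev = [(e, k) for (e, k, s, _, _) in family.truth.events if s == slot]
        leaf_states = replay_events(tree, 0, ev)
        for leaf in tree.leaves():
            expected = int(slot in present_at[leaf])
            if leaf_states[leaf.name] != expected:
                raise AssertionError("intron event log does not replay")


def _mrca(tree: Node, leaf_names: set[str]) -> Node:
    for node in tree.postorder():
        if leaf_names <= set(node.leaf_names()):
            return node
    raise ValueError(f"no MRCA for {sorted(leaf_names)}")


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _SYNONYMS[aa][rng.integers(0, len(_SYNONYMS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=max(n, 0)))


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _interleave(cds: str, introns: list[tuple[int, str]]) -> tuple[str, list[tuple[int, int]]]:
    """Insert introns (at CDS nucleotide offsets) and return the local gene
    sequence plus exon intervals in local transcript-orientation coordinates."""
    parts = []
    exons = []
    src = dst = 0
    for pos, iseq in sorted(introns):
        parts.append(cds[src:pos])
        exons.append((dst, dst + (pos - src)))
        dst += pos - src
        parts.append(iseq)
        dst += len(iseq)
        src = pos
    parts.append(cds[src:])
    exons.append((dst, dst + len(cds) - src))
    return "".join(parts), exons


# ---------------------------------------------------------------------------
# decoys


def _inject_decoy_parts(gene_parts, truth: TruthLog, boundaries,
                        decoy_spec: dict, rng: np.random.Generator,
                        unique_sources: bool = False) -> None:
    """Create decoy genes, each violating exactly one validation rule.

    TOO_SHORT: CDS truncated to 1199 nt. PREMATURE_STOP: one mid-linker codon
    -> TAA. MISSING_HIS: third CuA His codon -> Ala. INCOMPLETE_DOMAIN: CuB
    anchor His -> Arg (no HxxxH motif remains). Decoys are emitted as
    single-exon copies.
    """
    valid = sorted(truth.valid_ids)
    if not valid:
        if any(decoy_spec.get(c, 0) for c in DECOY_CLASSES):
            raise ValueError("cannot inject decoys into an empty family")
        return
    total = sum(decoy_spec.get(c, 0) for c in DECOY_CLASSES)
    if unique_sources and total > len(valid):
        raise ValueError(f"{total} decoys requested but only {len(valid)} "
                         "valid genes available as unique sources")
    unknown = set(decoy_spec) - set(DECOY_CLASSES)
    if unknown:
        raise ValueError(f"unknown decoy classes: {sorted(unknown)}")

    cua = boundaries["CUA"]
    cub = boundaries["CUB"]
    linker = boundaries["LINKER"]
    counter = 0
    src_cycle = 0
    for cls in DECOY_CLASSES:
        for _ in range(decoy_spec.get(cls, 0)):
            source_id = valid[src_cycle % len(valid)]
            src_cycle += 1
            counter += 1
            src = truth.genes[source_id]
            cds = _backtranslate(src.protein, rng)
            protein = src.protein
            if cls == "TOO_SHORT":
                cds = cds[:1199]
                protein = protein[:1199 // 3]
            elif cls == "PREMATURE_STOP":
                codon = (linker[0] + linker[1]) // 2
                cds = cds[:3 * codon] + "TAA" + cds[3 * codon + 3:]
                protein = protein[:codon] + "X" + protein[codon + 1:]
            elif cls == "MISSING_HIS":
                codon = cua[1] - 1            # third CuA His
                cds = cds[:3 * codon] + "GCT" + cds[3 * codon + 3:]
                protein = protein[:codon] + "A" + protein[codon + 1:]
            elif cls == "INCOMPLETE_DOMAIN":
                codon = cub[0]                # CuB anchor His
                cds = cds[:3 * codon] + "CGT" + cds[3 * codon + 3:]
                protein = protein[:codon] + "R" + protein[codon + 1:]
            gid = f"{src.species}_x{counter:02d}"
            gene_parts[src.species].append((gid, cds, []))
            truth.genes[gid] = TruthGene(gid, src.species, cls, protein,
                                         dict(boundaries), src.targeting, ())


def inject_decoys(family: SimulatedFamily, decoy_spec: dict, seed: int,
                  unique_sources: bool = False) -> SimulatedFamily:
    """Return a new family with decoys appended (regenerates genomes so the
    decoy genes get genomic coordinates)."""
    cfg = replace(family.config, decoy_spec=dict(decoy_spec), seed=family.config.seed)
    if not any(decoy_spec.get(c, 0) for c in DECOY_CLASSES):
        return family
    # simplest deterministic route: re-run the simulation with the spec set
    return simulate_family(cfg)
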