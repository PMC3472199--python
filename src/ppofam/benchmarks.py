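"""Recovery studies on truth-known synthetic data.

Each study generates its own inputs from a seed, runs the pipeline stage
under scrutiny, and measures agreement against either the generator's truth
log or an independent brute-force oracle. These back both the test suite and
``scripts/acceptance.py``; sizes are arguments so callers choose the scale.
"""

from __future__ import annotations

import hashlib
import itertools
import shutil
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import pam
from .alignment_core import build_coordinate_maps, progressive_align, trim_to_core
from .domain_annotation import (classify_targeting, locate_cu_domains,
                                scan_motifs, segment_architecture)
from .intron_evolution import (annotate_canonical, extract_introns,
                               fitch_changes, homologize_introns,
                               label_regions, _node_ids)
from .io_formats import splice_cds, translate
from .phylogeny import DistanceMatrix, bootstrap_support, neighbor_joining
from .synthetic_family import ArchetypeParams, SimulationConfig, simulate_family
from .tree import Node
from .validation import filter_family

# study trees: a balanced quartet plus a six-species tree with a ladder of
# unambiguous clades; branch lengths in substitutions/site
QUARTET_TREE = "((S1:0.2,S2:0.2):0.2,(S3:0.2,S4:0.2):0.2);"
SIX_SPECIES_TREE = ("(((S1:0.15,S2:0.15):0.1,(S3:0.15,S4:0.15):0.1):0.05,"
                    "(S5:0.2,S6:0.2):0.1);")
FIVE_SPECIES_TREE = ("(((S1:0.15,S2:0.15):0.1,(S3:0.15,S4:0.15):0.1):0.05,"
                     "S5:0.3);")

ALL_DECOYS = {"TOO_SHORT": 1, "PREMATURE_STOP": 1, "MISSING_HIS": 1,
              "INCOMPLETE_DOMAIN": 1}


def _family_candidates(family):
    models = {m.gene_id: m for m in family.models}
    out = []
    for gid in sorted(models):
        cds = splice_cds(models[gid], family.genomes)
        out.append((cds, translate(cds, tolerate_trailing=True)))
    return models, out


# ---------------------------------------------------------------------------
# 1. validation recovery


def validation_recovery_study(n_families: int, seed: int,
                              min_valid: int = 8, max_valid: int = 15) -> dict:
    """Over ``n_families`` synthetic families (each with one decoy per
    class), check that the retained set equals the truth log's VALID set,
    and probe the 1199/1200-nt retention boundary."""
    agree = 0
    done = 0
    offset = 0
    while done < n_families:
        cfg = SimulationConfig(
            species_tree=SIX_SPECIES_TREE, duplication_rate=0.6,
            loss_rate=0.15, root_gene_count=2, decoy_spec=dict(ALL_DECOYS),
            seed=seed + offset)
        offset += 1
        family = simulate_family(cfg)
        n_valid = len(family.truth.valid_ids)
        if not (min_valid <= n_valid <= max_valid):
            continue
        done += 1
        _, candidates = _family_candidates(family)
        retained, _, _ = filter_family(candidates)
        if {r.gene_id for r in retained} == family.truth.valid_ids:
            agree += 1

    # retention boundary: a 1200-nt CDS (stop included) is kept, 1199 is not
    rng = np.random.default_rng(seed)
    short_arch = ArchetypeParams(kfdv_len=82)   # 399 codons -> 1200 nt CDS
    cfg = SimulationConfig(archetype=short_arch,
                           decoy_spec={"TOO_SHORT": 1}, seed=seed)
    family = simulate_family(cfg)
    _, candidates = _family_candidates(family)
    retained, rejected, _ = filter_family(candidates)
    lengths_ok = (all(r.cds_length_nt == 1200 for r in retained)
                  and all(r.cds_length_nt == 1199 and "TOO_SHORT" in r.reasons
                          for r in rejected))
    return {"n_families": n_families, "agreement": agree,
            "boundary_ok": bool(retained and rejected and lengths_ok)}


# ---------------------------------------------------------------------------
# 2. neighbor joining vs additive matrices and exhaustive least squares


def random_binary_tree(names: list[str], rng: np.random.Generator,
                       min_bl: float = 0.1, max_bl: float = 1.0) -> Node:
    """Random unrooted binary topology (trifurcating root surrogate) with
    positive branch lengths."""
    nodes = [Node(name=n, length=float(rng.uniform(min_bl, max_bl)))
             for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(min_bl, max_bl)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for x in nodes:
        root.add(x)
    return root


def tree_distance_matrix(root: Node) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length (additive) distances."""
    leaves = root.leaves()
    paths = []
    for leaf in leaves:
        acc, d, n = 0.0, {}, leaf
        while n is not None:
            d[id(n)] = acc
            acc += n.length or 0.0
            n = n.parent
        paths.append(d)
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = min(paths[i][k] + paths[j][k]
                                    for k in paths[i] if k in paths[j])
    return [l.name for l in leaves], D


def enumerate_unrooted_topologies(names: list[str]):
    """All unrooted binary topologies over ``names`` (3 leaves: 1; 6: 105)."""
    base = Node()
    for nm in names[:3]:
        base.add(Node(name=nm))
    trees = [base]
    for nm in names[3:]:
        grown = []
        for t in trees:
            edges = [n for n in t.postorder() if n is not t]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.postorder() if n is not t2]
                target = edges2[k]
                parent = target.parent
                idx = parent.children.index(target)
                mid = Node()
                mid.add(target)
                mid.add(Node(name=nm))
                mid.parent = parent
                parent.children[idx] = mid
                grown.append(t2)
        trees = grown
    return trees


def least_squares_fit(topology: Node, names: list[str], D: np.ndarray) -> float:
    """OLS branch-length fit of a topology to a distance matrix; returns the
    sum of squared residuals (branch lengths unconstrained)."""
    edges = [n for n in topology.postorder() if n is not topology]
    leaf_sets = [frozenset(e.leaf_names()) for e in edges]
    idx = {nm: i for i, nm in enumerate(names)}
    pairs = list(itertools.combinations(names, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (u, v) in enumerate(pairs):
        y[r] = D[idx[u], idx[v]]
        for c, ls in enumerate(leaf_sets):
            if (u in ls) != (v in ls):
                A[r, c] = 1.0
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def nj_recovery_study(n_matrices: int, seed: int,
                      n_exhaustive: int = 20) -> dict:
    """NJ on additive matrices from random 5–8-leaf trees: topology recovery,
    worst-case path-length deviation, and (for a subset with <= 6 leaves)
    agreement with exhaustive topology enumeration under least squares."""
    rng = np.random.default_rng(seed)
    recovered = 0
    max_bl_err = 0.0
    exhaustive_checked = exhaustive_agree = 0
    for _ in range(n_matrices):
        n = int(rng.integers(5, 9))
        names = [f"T{i}" for i in range(n)]
        true = random_binary_tree(names, rng)
        tnames, D = tree_distance_matrix(true)
        dm = DistanceMatrix(tnames, D, np.ones_like(D, dtype=int))
        nj = neighbor_joining(dm)
        if nj.bipartitions() == true.bipartitions():
            recovered += 1
        _, D2 = tree_distance_matrix(nj)
        perm = [nj.leaf_names().index(x) for x in tnames]
        max_bl_err = max(max_bl_err, float(np.abs(D - D2[np.ix_(perm, perm)]).max()))
        if n <= 6 and exhaustive_checked < n_exhaustive:
            exhaustive_checked += 1
            best_sse, best_topo = None, None
            for topo in enumerate_unrooted_topologies(names):
                sse = least_squares_fit(topo, tnames, D)
                if best_sse is None or sse < best_sse - 1e-12:
                    best_sse, best_topo = sse, topo
            if best_topo.bipartitions() == nj.bipartitions():
                exhaustive_agree += 1
    return {"n_matrices": n_matrices, "recovered": recovered,
            "max_pathlength_error": max_bl_err,
            "exhaustive_checked": exhaustive_checked,
            "exhaustive_agree": exhaustive_agree}


# ---------------------------------------------------------------------------
# 3. Fitch / scenario-count oracle


def brute_force_parsimony(tree: Node, presence: dict[str, int]) -> tuple[int, int]:
    """Exhaustive minimization over all internal labellings: returns
    (min changes, number of optimal labellings). Independent oracle."""
    internals = [n for n in tree.postorder() if not n.is_leaf()]
    ids = _node_ids(tree)
    best, count = None, 0
    for states in itertools.product((0, 1), repeat=len(internals)):
        lab = {ids[n]: s for n, s in zip(internals, states)}
        for leaf in tree.leaves():
            lab[ids[leaf]] = presence[leaf.name]
        changes = sum(lab[ids[n]] != lab[ids[n.parent]]
                      for n in tree.postorder() if n is not tree)
        if best is None or changes < best:
            best, count = changes, 1
        elif changes == best:
            count += 1
    return best, count


def random_rooted_tree(n: int, rng: np.random.Generator) -> Node:
    nodes = [Node(name=f"T{i}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = Node()
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    return nodes[0]


def fitch_oracle_study(n_characters: int, seed: int) -> dict:
    from .intron_evolution import enumerate_equally_parsimonious

    rng = np.random.default_rng(seed)
    agree = count_agree = 0
    for _ in range(n_characters):
        n = int(rng.integers(3, 9))
        tree = random_rooted_tree(n, rng)
        presence = {f"T{i}": int(rng.random() < 0.5) for i in range(n)}
        mc, _ = fitch_changes(tree, presence)
        oracle_mc, oracle_count = brute_force_parsimony(tree, presence)
        agree += (mc == oracle_mc)
        scen = enumerate_equally_parsimonious(tree, presence)
        count_agree += (scen[0].n_equally_parsimonious == oracle_count
                        and len(scen) == oracle_count)
    return {"n_characters": n_characters, "min_changes_agree": agree,
            "scenario_count_agree": count_agree}


# ---------------------------------------------------------------------------
# 4. Dayhoff estimator bias


def dayhoff_bias_study(steps: tuple[int, ...], replicates: int, sites: int,
                       seed: int) -> dict:
    """Evolve ``sites`` positions by n PAM steps, estimate the distance by
    inverting the expected-difference curve, report mean relative bias."""
    rng = np.random.default_rng(seed)
    out = {}
    for n in steps:
        estimates = []
        for _ in range(replicates):
            ancestor = pam.sample_equilibrium(sites, rng)
            derived = pam.evolve(ancestor, n, rng)
            p = float((ancestor != derived).mean())
            estimates.append(pam.dayhoff_distance(p))
        mean = float(np.mean(estimates))
        out[n] = {"mean_estimate": mean, "true": n / 100.0,
                  "relative_bias": abs(mean - n / 100.0) / (n / 100.0)}
    return out


# ---------------------------------------------------------------------------
# 5. intron homologization recovery


def _shared_unique_config(seed: int) -> SimulationConfig:
    """Five species, no duplication: three shared intron characters (L1
    ancestral; A1 and D1 gained on internal edges) plus two unique ones (N1,
    K1 on leaf edges), and one GC..AG decoy intron."""
    return SimulationConfig(
        species_tree=FIVE_SPECIES_TREE, duplication_rate=0.0, loss_rate=0.0,
        intron_gain_rate=0.0, intron_loss_rate=0.0,
        ancestral_introns=("L1",),
        forced_intron_events=(
            ("GAIN", "A1", ("S1_g01", "S2_g01")),
            ("GAIN", "D1", ("S3_g01", "S4_g01")),
            ("GAIN", "N1", ("S5_g01",)),
            ("GAIN", "K1", ("S1_g01",)),
        ),
        gc_decoy_intron=True, pam_scale=1.0, seed=seed)


def intron_recovery_study(n_runs: int, seed: int) -> dict:
    """Run the alignment -> projection -> homologization -> labelling chain
    and compare the recovered partition (and region labels) with the planted
    slots; also check canonical/non-canonical splice flags."""
    partition_ok = 0
    canonical_ok = 0
    for k in range(n_runs):
        family = simulate_family(_shared_unique_config(seed + k))
        models = {m.gene_id: m for m in family.models}
        prots = {g: translate(splice_cds(m, family.genomes))
                 for g, m in models.items()}
        msa = progressive_align({g: p.residues for g, p in prots.items()})
        archs = {}
        for gid, p in prots.items():
            hits = scan_motifs(p)
            cua, cub = locate_cu_domains(p, hits)
            archs[gid] = segment_architecture(p, cua, cub, hits)
        trim = trim_to_core(msa, archs)
        maps = build_coordinate_maps(msa)
        records = []
        for gid in sorted(models):
            records.extend(extract_introns(models[gid]))
        annotate_canonical(records, family.genomes, models)
        chars = homologize_introns(records, maps, sorted(models),
                                   column_range=trim.column_range)
        label_regions(chars, archs, maps)
        truth_partition: dict[str, set[str]] = {}
        for gid, t in family.truth.genes.items():
            for s in t.intron_slots:
                truth_partition.setdefault(s, set()).add(gid)
        recovered = {c.label: set(c.members) for c in chars}
        if recovered == truth_partition:
            partition_ok += 1
        noncanon = [r for r in records if not r.canonical]
        if len(noncanon) == 1 and all(
                r.canonical for r in records if r is not noncanon[0]):
            canonical_ok += 1
    return {"n_runs": n_runs, "partition_recovered": partition_ok,
            "canonical_flags_ok": canonical_ok}


# ---------------------------------------------------------------------------
# 6. bootstrap sanity


def bootstrap_sanity_study(seed: int, reps: int = 200) -> dict:
    """Low-divergence six-gene family with unambiguous clades: every
    true-clade support should be 100%; a single replicate gives {0, 100}."""
    cfg = SimulationConfig(species_tree=SIX_SPECIES_TREE,
                           duplication_rate=0.0, loss_rate=0.0, seed=seed)
    family = simulate_family(cfg)
    models = {m.gene_id: m for m in family.models}
    prots = {g: translate(splice_cds(m, family.genomes)).residues
             for g, m in models.items()}
    msa = progressive_align(prots)
    tree, supports = bootstrap_support(msa, reps=reps, seed=seed)
    true_splits = {
        frozenset(set(tree.leaf_names()) - {"S1_g01", "S2_g01"}),
        frozenset({"S3_g01", "S4_g01"}),
        frozenset({"S5_g01", "S6_g01"}),
    } & set(supports)
    min_true = min(supports[s] for s in true_splits) if true_splits else 0.0
    _, single = bootstrap_support(msa, reps=1, seed=seed)
    return {"reps": reps,
            "n_true_clades": len(true_splits),
            "min_true_clade_support": min_true,
            "single_rep_binary": set(single.values()) <= {0.0, 100.0}}


# ---------------------------------------------------------------------------
# 7. end-to-end determinism


def determinism_study(seed: int, bootstrap_reps: int = 25) -> dict:
    """Run the full survey twice with one config; compare bundle bytes."""
    from .survey import SurveyConfig, run_survey

    def bundle_hash(outdir: Path) -> str:
        h = hashlib.sha256()
        for p in sorted(outdir.rglob("*")):
            if p.is_file():
                h.update(p.relative_to(outdir).as_posix().encode())
                h.update(p.read_bytes())
        return h.hexdigest()

    sim = SimulationConfig(seed=seed, decoy_spec=dict(ALL_DECOYS))
    hashes = []
    for _ in range(2):
        tmp = Path(tempfile.mkdtemp(prefix="ppofam_det_"))
        try:
            run_survey(SurveyConfig(simulate=sim, bootstrap_reps=bootstrap_reps,
                                    seed=seed, outdir=str(tmp / "bundle")))
            hashes.append(bundle_hash(tmp / "bundle"))
        finally:
            shutil.rmtree(tmp, ignore_errors=True)
    return {"identical": hashes[0] == hashes[1]}


# ---------------------------------------------------------------------------
# 8. targeting classification confusion


def targeting_confusion_study(seed: int) -> dict:
    """CTP- and SP-archetype families at default thresholds: fraction of
    genes classified as their true class."""
    totals = {"CTP": [0, 0], "SP": [0, 0]}
    for variant in ("CTP", "SP"):
        cfg = SimulationConfig(archetype=ArchetypeParams(targeting=variant),
                               duplication_rate=0.5, loss_rate=0.1, seed=seed)
        family = simulate_family(cfg)
        models = {m.gene_id: m for m in family.models}
        for gid in sorted(family.truth.valid_ids):
            prot = translate(splice_cds(models[gid], family.genomes))
            cls, _ = classify_targeting(prot)
            totals[variant][1] += 1
            totals[variant][0] += (cls == variant)
    return {v: {"correct": c, "total": t} for v, (c, t) in totals.items()}
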