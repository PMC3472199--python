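"""End-to-end survey pipeline: gene models -> validation -> annotation ->
core alignment -> NJ phylogeny with bootstrap -> intron homologization and
gain/loss reconstruction -> report bundle.

All randomness flows from the single config seed through per-stage child
seeds, so identical configs yield byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment_core import (MultipleAlignment, build_coordinate_maps,
                             load_external_alignment, progressive_align,
                             trim_to_core)
from .domain_annotation import (AnnotationParams, classify_targeting,
                                column_information, locate_cu_domains,
                                parse_targetp, scan_motifs,
                                segment_architecture)
from .intron_evolution import (annotate_canonical, dollo_events,
                               enumerate_equally_parsimonious, extract_introns,
                               fitch_changes, homologize_introns, label_regions)
from .io_formats import (read_fasta, read_gene_models, splice_cds, translate,
                         write_fasta, write_tsv, write_newick)
from .phylogeny import bootstrap_support, dayhoff_distances, root_with_outgroup
from .synthetic_family import SimulationConfig, simulate_family
from .tree import Node
from .validation import MIN_CDS_LENGTH, filter_family

log = logging.getLogger(__name__)


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derivation (keeps seeds below 2**31)."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class SurveyConfig:
    genome_fastas: tuple[str, ...] = ()
    gff3: str | None = None
    simulate: SimulationConfig | None = None
    alignment: str | None = None       # external aligned FASTA (adapter mode)
    no_fallback: bool = False
    targetp_file: str | None = None
    min_cds_length: int = MIN_CDS_LENGTH
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    column_tolerance: int = 0
    deletion_mode: str = "pairwise"
    bootstrap_reps: int = 1000
    outgroup: str | None = None
    seed: int = 0
    outdir: str = "survey_out"

    def __post_init__(self):
        has_paths = bool(self.genome_fastas or self.gff3)
        if has_paths == (self.simulate is not None):
            raise ValueError(
                "exactly one of (genome FASTA(s) + GFF3) or a simulation "
                "config must be provided")
        if has_paths and not (self.genome_fastas and self.gff3):
            raise ValueError("both genome FASTA(s) and a GFF3 are required")


@dataclass
class ReportBundle:
    outdir: Path
    retained_ids: list[str]
    tree: Node | None
    rooted_tree: Node | None
    architectures: dict
    characters: list
    notices: list[str]
    proteins: dict = field(default_factory=dict)


def run_survey(config: SurveyConfig) -> ReportBundle:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []

    # ---- inputs -------------------------------------------------------
    if config.simulate is not None:
        family = simulate_family(config.simulate)
        family.write(out / "simulated_input")
        models = family.models
        genome = dict(family.genomes)
    else:
        genome = {}
        for fa in config.genome_fastas:
            genome.update(read_fasta(fa))
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            merged = Path(td) / "genome.fa"
            write_fasta(genome, merged)
            models = read_gene_models(config.gff3, merged)

    if not models:
        notices.append("empty input: no gene models")
        _write_metadata(out, config, notices)
        return ReportBundle(out, [], None, None, {}, [], notices, {})

    # ---- validation ---------------------------------------------------
    candidates = []
    for m in models:
        cds = splice_cds(m, genome)
        prot = translate(cds, tolerate_trailing=True)
        candidates.append((cds, prot))
    retained, rejected, counts = filter_family(
        candidates, config.min_cds_length, config.annotation)
    reports = sorted(retained + rejected, key=lambda r: r.gene_id)
    write_tsv(out / "validation_report.tsv",
              ["gene_id", "retained", "reasons", "cds_length_nt",
               "n_his_cua", "n_his_cub"],
              [(r.gene_id, int(r.retained), ",".join(sorted(r.reasons)),
                r.cds_length_nt, r.n_his_cua, r.n_his_cub) for r in reports])
    retained_ids = [r.gene_id for r in retained]
    proteins = {c.gene_id: p for c, p in candidates}
    models_by_id = {m.gene_id: m for m in models}

    # ---- domain annotation ---------------------------------------------
    external_targeting = (parse_targetp(config.targetp_file)
                          if config.targetp_file else None)
    architectures = {}
    arch_rows = []
    for gid in retained_ids:
        prot = proteins[gid]
        hits = scan_motifs(prot)
        cua, cub = locate_cu_domains(prot, hits, config.annotation)
        arch = segment_architecture(prot, cua, cub, hits, config.annotation)
        arch.targeting, arch.targeting_score = classify_targeting(
            prot, config.annotation, external_targeting)
        architectures[gid] = arch
        arch_rows.append((
            gid,
            ";".join(f"{k}:{s}-{e}" for k, (s, e) in arch.segments.items()),
            arch.targeting, f"{arch.targeting_score:.4f}",
            ",".join(str(i) for i in arch.cu_his_positions),
            ",".join(f"{h.motif_name}@{h.start}" for h in hits),
        ))
    write_tsv(out / "architecture.tsv",
              ["gene_id", "segments", "targeting", "targeting_score",
               "cu_his_positions", "motifs"],
              arch_rows,
              metadata={"targeting_predictor":
                        "built-in serine/hydropathy heuristic (stand-in for "
                        "ChloroP/TargetP)" if external_targeting is None
                        else "external table"})

    # ---- alignment and core trim ---------------------------------------
    seqs = {gid: proteins[gid].residues for gid in retained_ids}
    if len(seqs) >= 2:
        if config.alignment:
            msa = load_external_alignment(config.alignment, expected=seqs)
        elif config.no_fallback:
            raise ValueError("--no-fallback set but no external alignment given")
        else:
            msa = progressive_align(seqs)
        trim = trim_to_core(msa, architectures)
        write_fasta({g: trim.core.row(g) for g in trim.core.rows},
                    out / "core_alignment.fasta")
        bits = column_information(trim.core.matrix)
        write_tsv(out / "conservation.tsv",
                  ["column", "bits", "consensus"],
                  [(i, "NA" if b is None else f"{b:.4f}", _consensus(trim.core, i))
                   for i, b in enumerate(bits)])
        maps = build_coordinate_maps(msa)
    else:
        msa = trim = maps = None
        notices.append("fewer than 2 retained genes: alignment skipped")

    # ---- phylogeny ------------------------------------------------------
    tree = rooted = None
    if msa is not None and len(retained_ids) >= 3:
        dm = dayhoff_distances(MultipleAlignment(trim.core.rows, trim.core.matrix),
                               config.deletion_mode)
        write_tsv(out / "distances.tsv",
                  ["gene_id"] + dm.taxa,
                  [(t, *(f"{dm.values[i, j]:.6f}" for j in range(len(dm.taxa))))
                   for i, t in enumerate(dm.taxa)])
        tree, supports = bootstrap_support(
            MultipleAlignment(trim.core.rows, trim.core.matrix),
            reps=config.bootstrap_reps,
            seed=child_seed(config.seed, "bootstrap"),
            deletion_mode=config.deletion_mode)
        if config.outgroup and tree.find_leaf(config.outgroup) is not None:
            rooted = root_with_outgroup(tree, config.outgroup)
        elif config.outgroup:
            notices.append(f"outgroup {config.outgroup!r} not among retained genes")
        (out / "tree.nwk").write_text(write_newick(rooted or tree) + "\n")
    else:
        notices.append("fewer than 3 retained genes: phylogeny and "
                       "reconstruction skipped")

    # ---- introns --------------------------------------------------------
    records = []
    for gid in retained_ids:
        records.extend(extract_introns(models_by_id[gid]))
    annotate_canonical(records, genome, models_by_id)
    write_tsv(out / "introns.tsv",
              ["gene_id", "intron_index", "genomic_start", "genomic_end",
               "length_nt", "codon_index", "phase", "canonical"],
              [(r.gene_id, r.intron_index, *r.genomic_interval, r.length_nt,
                r.codon_index, r.phase, int(bool(r.canonical))) for r in records])

    characters = []
    if maps is not None:
        characters = homologize_introns(
            records, maps, retained_ids,
            column_range=trim.column_range if trim else None,
            column_tolerance=config.column_tolerance)
        label_regions(characters, architectures, maps)
        write_tsv(out / "characters.tsv",
                  ["character_id", "label", "column", "phase", "members",
                   "presence"],
                  [(c.character_id, c.label, c.alignment_column, c.phase,
                    ",".join(c.members),
                    "".join(str(c.presence[g]) for g in retained_ids))
                   for c in characters])
        _write_nexus(out / "characters.nex", characters, retained_ids)

    if characters and (rooted or tree) is not None:
        recon_tree = rooted or tree
        ev_rows = []
        for c in characters:
            mc, _ = fitch_changes(recon_tree, c.presence)
            scen = enumerate_equally_parsimonious(recon_tree, c.presence,
                                                  character_id=c.character_id)
            dollo = dollo_events(recon_tree, c.presence, c.character_id)
            ev_rows.append((c.character_id, c.label, "FITCH", mc,
                            scen[0].n_equally_parsimonious,
                            ";".join(f"{e}:{k}" for e, k in scen[0].events)))
            ev_rows.append((c.character_id, c.label, "DOLLO", dollo.min_changes,
                            1, ";".join(f"{e}:{k}" for e, k in dollo.events)))
        write_tsv(out / "events.tsv",
                  ["character_id", "label", "method", "min_changes",
                   "n_scenarios", "events"],
                  ev_rows)

    _write_metadata(out, config, notices)
    bundle = ReportBundle(out, retained_ids, tree, rooted, architectures,
                          characters, notices,
                          {g: proteins[g].residues for g in retained_ids})
    (out / "report.txt").write_text(render_figure2_report(bundle))
    return bundle


def _consensus(msa: MultipleAlignment, col: int) -> str:
    from collections import Counter

    residues = [r[col] for r in msa.matrix if r[col] not in "-X"]
    if not residues:
        return "-"
    counts = Counter(residues)
    return min(sorted(counts), key=lambda k: -counts[k])


def _write_nexus(path, characters, gene_ids) -> None:
    """0/1 character matrix in a NEXUS-style block for external parsimony
    tools."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(gene_ids)} NCHAR={len(characters)};\n")
        fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n  MATRIX\n')
        for g in gene_ids:
            row = "".join(str(c.presence[g]) for c in characters)
            fh.write(f"    {g} {row}\n")
        fh.write("  ;\nEND;\n")


def _write_metadata(out: Path, config: SurveyConfig, notices: list[str]) -> None:
    meta = {
        "ppofam_version": __version__,
        "seed": config.seed,
        "stage_seeds": {"bootstrap": child_seed(config.seed, "bootstrap")},
        "min_cds_length": config.min_cds_length,
        "deletion_mode": config.deletion_mode,
        "bootstrap_reps": config.bootstrap_reps,
        "column_tolerance": config.column_tolerance,
        "outgroup": config.outgroup,
        "targeting_thresholds": {
            "ser_threshold": config.annotation.ser_threshold,
            "hyd_threshold": config.annotation.hyd_threshold,
            "note": "heuristic stand-in for ChloroP/TargetP; thresholds are "
                    "package defaults, not values from an external predictor",
        },
        "alignment_mode": "external" if config.alignment else "built-in fallback",
        "trimming": "after alignment (union of CuA-start..DWL-end columns)",
        "simulated": config.simulate is not None,
        "notices": notices,
    }
    if config.simulate is not None:
        sim = config.simulate
        meta["simulation"] = {
            "species_tree": sim.species_tree,
            "duplication_rate": sim.duplication_rate,
            "loss_rate": sim.loss_rate,
            "pam_scale": sim.pam_scale,
            "intron_gain_rate": sim.intron_gain_rate,
            "intron_loss_rate": sim.intron_loss_rate,
            "intron_length_range": list(sim.intron_length_range),
            "ancestral_introns": list(sim.ancestral_introns),
            "seed": sim.seed,
        }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# figure-style text report


def render_figure2_report(bundle: ReportBundle) -> str:
    """Text analogue of the survey figure: the support-filtered tree plus one
    line per retained gene with targeting class, the first five residues of
    each copper domain (HxxxC / HxxxH), and intron bars by region label.
    Supports of 50% or less are hidden."""
    lines = ["# ppofam survey report"]
    tree = bundle.rooted_tree or bundle.tree
    if tree is not None:
        shown = tree.copy()
        for node in shown.postorder():
            if not node.is_leaf() and node.support is not None:
                if node.support <= 50:
                    node.label = None
                else:
                    node.label = str(int(round(node.support)))
        lines.append("tree (supports > 50% shown): " + write_newick(shown))
    leaf_order = (tree.leaf_names() if tree is not None else bundle.retained_ids)
    by_gene: dict[str, list[str]] = {}
    for c in bundle.characters:
        for g in c.members:
            by_gene.setdefault(g, []).append(c.label)
    for gid in leaf_order:
        arch = bundle.architectures.get(gid)
        if arch is None:
            continue
        cua_s = arch.segments["CUA"][0]
        cub_s = arch.segments["CUB"][0]
        prot = bundle.proteins.get(gid, "")
        anchors = (f"{prot[cua_s:cua_s + 5]} / {prot[cub_s:cub_s + 5]}"
                   if prot else f"CuA@{cua_s} / CuB@{cub_s}")
        bars = " ".join(f"|{l}" for l in by_gene.get(gid, [])) or "(no introns)"
        lines.append(f"{gid}\t[{arch.targeting}]\t{anchors}\t{bars}")
    for notice in bundle.notices:
        lines.append(f"NOTE: {notice}")
    return "\n".join(lines) + "\n"
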