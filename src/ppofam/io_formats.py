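"""Standard-format I/O and strand-aware CDS handling.

Internal coordinates are 0-based half-open throughout; GFF3's 1-based
inclusive intervals are converted at the boundary. Exons of '-'-strand genes
are stored ascending genomically (GFF3 practice) and spliced in reverse for
transcription.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .tree import Node, from_newick, to_newick  # noqa: F401  (re-exported)

log = logging.getLogger(__name__)

VALID_NT = set("ACGTN")


class FrameError(ValueError):
    """CDS length not a multiple of 3."""

    reason_code = "FRAME"


@dataclass(frozen=True)
class GeneModel:
    """One candidate gene: ordered exon intervals on a genome sequence."""

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_tag: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"{self.gene_id}: bad exon interval ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class CodingSequence:
    gene_id: str
    nucleotides: str

    def __post_init__(self):
        bad = set(self.nucleotides) - VALID_NT
        if bad:
            raise ValueError(
                f"{self.gene_id}: unsupported nucleotide codes {sorted(bad)} "
                "(only A/C/G/T/N accepted; sanitize other ambiguity codes first)"
            )

    @property
    def length_nt(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class ProteinSequence:
    gene_id: str
    residues: str
    premature_stop_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if "*" in self.residues:
            raise ValueError(f"{self.gene_id}: residues must not contain '*'")

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: uppercase sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gene_models(gff3_source, genome_fasta_source) -> list[GeneModel]:
    """Read mRNA gene models (exons = CDS features) from GFF3 + genome FASTA.

    Returns one :class:`GeneModel` per mRNA, ordered by gene_id. An mRNA with
    no CDS children is skipped with a warning; a CDS on a sequence absent from
    the FASTA is a hard error naming the contig.
    """
    genome = read_fasta(genome_fasta_source)
    db = gffutils.create_db(
        str(gff3_source), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type("mRNA"):
        cds_feats = sorted(db.children(mrna, featuretype="CDS"),
                           key=lambda f: f.start)
        if not cds_feats:
            log.warning("mRNA %s has no CDS features; skipped", mrna.id)
            continue
        exons = []
        for f in cds_feats:
            if f.seqid not in genome:
                raise ValueError(
                    f"CDS of {mrna.id} references unknown sequence {f.seqid!r}")
            exons.append((f.start - 1, f.end))  # 1-based closed -> 0-based half-open
        models.append(GeneModel(
            gene_id=mrna.id, seq_id=cds_feats[0].seqid,
            strand=mrna.strand, exons=tuple(exons), source_tag=mrna.source,
        ))
    return sorted(models, key=lambda m: m.gene_id)


def read_gene_models_str(gff3_text: str, genome: dict[str, str]) -> list[GeneModel]:
    """Convenience wrapper accepting in-memory GFF3 text and a genome dict."""
    with tempfile.TemporaryDirectory() as td:
        gff = Path(td) / "in.gff3"
        fa = Path(td) / "in.fa"
        gff.write_text(gff3_text)
        write_fasta(genome, fa)
        return read_gene_models(gff, fa)


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start = min(s for s, _ in m.exons) + 1
            g_end = max(e for _, e in m.exons)
            src = m.source_tag or "ppofam"
            fh.write(f"{m.seq_id}\t{src}\tgene\t{g_start}\t{g_end}\t.\t{m.strand}"
                     f"\t.\tID=gene_{m.gene_id}\n")
            fh.write(f"{m.seq_id}\t{src}\tmRNA\t{g_start}\t{g_end}\t.\t{m.strand}"
                     f"\t.\tID={m.gene_id};Parent=gene_{m.gene_id}\n")
            exons = m.exons if m.strand == "+" else tuple(reversed(m.exons))
            cum = 0
            rows = []
            for s, e in exons:  # transcription order for phase bookkeeping
                phase = (3 - cum % 3) % 3
                rows.append((s, e, phase))
                cum += e - s
            for i, (s, e, phase) in enumerate(sorted(rows), 1):
                fh.write(f"{m.seq_id}\t{src}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}"
                         f"\t{phase}\tID={m.gene_id}.cds{i};Parent={m.gene_id}\n")


# ---------------------------------------------------------------------------
# splicing & translation


def splice_cds(model: GeneModel, genome: dict[str, str]) -> CodingSequence:
    """Concatenate exon sequences in transcription order ('-' strand genes
    are reverse-complemented)."""
    try:
        seq = genome[model.seq_id]
    except KeyError:
        raise ValueError(f"{model.gene_id}: unknown sequence {model.seq_id!r}") from None
    parts = []
    for start, end in model.exons:
        if end > len(seq):
            raise ValueError(
                f"{model.gene_id}: exon ({start},{end}) beyond end of "
                f"{model.seq_id} (length {len(seq)})")
        parts.append(seq[start:end])
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return CodingSequence(model.gene_id, cds.upper())


def translate(cds: CodingSequence, *, tolerate_trailing: bool = False) -> ProteinSequence:
    """Translate with the standard genetic code.

    The terminal stop codon (if present) is removed; internal stops are
    rendered as 'X' and their codon indices recorded. A CDS whose length is
    not a multiple of 3 raises :class:`FrameError` unless
    ``tolerate_trailing`` is set, in which case the trailing partial codon is
    dropped (used for already-truncated gene models).
    """
    nts = cds.nucleotides
    if len(nts) % 3 != 0:
        if not tolerate_trailing:
            raise FrameError(
                f"{cds.gene_id}: CDS length {len(nts)} is not a multiple of 3")
        nts = nts[: len(nts) - len(nts) % 3]
    aa = str(Seq(nts).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    stops = tuple(i for i, c in enumerate(aa) if c == "*")
    return ProteinSequence(cds.gene_id, aa.replace("*", "X"), stops)


# ---------------------------------------------------------------------------
# Newick re-exports (parsing/writing live in ppofam.tree)

read_newick = from_newick
write_newick = to_newick


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv(path, header: list[str], rows: list[tuple], metadata: dict | None = None) -> None:
    """Tab-delimited UTF-8 report with a header row; optional ``# key=value``
    metadata lines above the header."""
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}={v}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
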