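"""Candidate-retention filters.

A candidate PPO gene model is retained iff its CDS is at least 1200 nt
(terminal stop included), encodes no premature stop codon, and its protein
carries both copper-binding domains with all three conserved histidines in
each. Everything else is rejected with machine-readable reason codes:

  TOO_SHORT          CDS shorter than 1200 nt
  FRAME              CDS length not a multiple of 3 (full-length models only;
                     a trailing partial codon on an already-too-short model
                     is subsumed by TOO_SHORT)
  PREMATURE_STOP     internal stop codon
  INCOMPLETE_DOMAIN  CuA or CuB anchor motif not located
  MISSING_HIS        a located copper domain has fewer than 3 conserved His
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .domain_annotation import AnnotationParams, DEFAULT_PARAMS, locate_cu_domains
from .io_formats import CodingSequence, ProteinSequence, translate

MIN_CDS_LENGTH = 1200

REASON_CODES = ("TOO_SHORT", "FRAME", "PREMATURE_STOP", "MISSING_HIS",
                "INCOMPLETE_DOMAIN")


@dataclass
class ValidationReport:
    gene_id: str
    retained: bool
    reasons: frozenset[str]
    cds_length_nt: int
    n_his_cua: int
    n_his_cub: int

    def __post_init__(self):
        assert self.retained == (not self.reasons)


def validate_candidate(
    cds: CodingSequence,
    protein: ProteinSequence | None = None,
    min_cds_length: int = MIN_CDS_LENGTH,
    params: AnnotationParams = DEFAULT_PARAMS,
) -> ValidationReport:
    """Apply the retention filters to one candidate.

    ``protein`` may be supplied (must derive from ``cds``); otherwise it is
    translated here. Always returns a report, never raises on bad content.
    """
    reasons: set[str] = set()
    length = cds.length_nt
    if length < min_cds_length:
        reasons.add("TOO_SHORT")
    if length % 3 != 0 and "TOO_SHORT" not in reasons:
        reasons.add("FRAME")
    if protein is None:
        protein = translate(cds, tolerate_trailing=True)
    if protein.premature_stop_positions:
        reasons.add("PREMATURE_STOP")
    cua, cub = locate_cu_domains(protein, params=params)
    n_his_cua, n_his_cub = cua.n_his, cub.n_his
    for dom in (cua, cub):
        if not dom.found_anchor:
            reasons.add("INCOMPLETE_DOMAIN")
        elif dom.n_his < 3:
            reasons.add("MISSING_HIS")
    return ValidationReport(
        gene_id=cds.gene_id,
        retained=not reasons,
        reasons=frozenset(reasons),
        cds_length_nt=length,
        n_his_cua=n_his_cua,
        n_his_cub=n_his_cub,
    )


def filter_family(
    candidates: list[tuple[CodingSequence, ProteinSequence | None]],
    min_cds_length: int = MIN_CDS_LENGTH,
    params: AnnotationParams = DEFAULT_PARAMS,
) -> tuple[list[ValidationReport], list[ValidationReport], Counter]:
    """Partition candidates into retained and rejected.

    Returns (retained, rejected, per-reason counts); the partition is
    exhaustive and disjoint, ordered by gene_id within each part.
    """
    reports = [validate_candidate(c, p, min_cds_length, params)
               for c, p in candidates]
    reports.sort(key=lambda r: r.gene_id)
    retained = [r for r in reports if r.retained]
    rejected = [r for r in reports if not r.retained]
    counts = Counter()
    for r in rejected:
        counts.update(r.reasons)
    return retained, rejected, counts
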