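"""PPO domain architecture annotation.

Locates the two copper-binding domains (CuA anchored by its HxxxC motif, CuB
by its HxxxH motif with an invariant downstream phenylalanine), segments each
protein into the six-region architecture NTERM | CUA | LINKER | CUB | DWL |
KFDV, classifies N-terminal targeting (chloroplast transit peptide vs
secretory signal peptide) with a documented heuristic, and computes
per-column conservation (sequence-logo information content).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import ProteinSequence

log = logging.getLogger(__name__)

SEGMENTS = ("NTERM", "CUA", "LINKER", "CUB", "DWL", "KFDV")

#: residues accepted at the 4th position of the CuB HxxxH motif
HXXXH_HYDROPHOBIC = set("AVLIM")

#: Kyte–Doolittle hydropathy values (signal-peptide h-region heuristic)
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int
    matched_text: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_text)


@dataclass
class CuDomainResult:
    """Outcome of locating one copper-binding domain."""

    found_anchor: bool
    span: tuple[int, int] | None       # anchor start -> third His, half-open
    his_positions: tuple[int, ...]     # conserved His located (<= 3)
    n_his: int                         # conserved His present, in [0, 3]

    @property
    def located(self) -> bool:
        return self.span is not None


@dataclass
class DomainArchitecture:
    gene_id: str
    segments: dict[str, tuple[int, int]]
    cu_his_positions: tuple[int, ...]
    targeting: str = "UNKNOWN"
    targeting_score: float = 0.0
    kfdv_empty: bool = False

    def segment_of(self, residue: int) -> str | None:
        for name, (s, e) in self.segments.items():
            if s <= residue < e:
                return name
        return None


@dataclass
class AnnotationParams:
    """Tunable windows/thresholds for domain location and targeting."""

    his_window: int = 60          # window after an anchor searched for His
    linker_min: int = 60          # CuB anchor distance from CuA end, lower
    linker_max: int = 160         # ... and upper bound
    dwl_length: int = 50
    yxy_search: tuple[int, int] = (40, 70)  # YxY window past CuB end (DWL extension)
    ser_threshold: float = 0.15   # cTP: Ser fraction over residues [0, 35)
    axa_range: tuple[int, int] = (35, 110)  # cTP: AxA cleavage motif location
    hyd_threshold: float = 2.5    # SP: mean Kyte–Doolittle over an 8-window
    hyd_window: int = 8
    hyd_range: tuple[int, int] = (5, 30)


DEFAULT_PARAMS = AnnotationParams()


# ---------------------------------------------------------------------------
# motif scanning


def scan_motifs(protein: ProteinSequence) -> list[MotifHit]:
    """All (possibly overlapping) hits of the PPO motif catalogue, by start.

    HXXXC/HXXXH anchor the CuA/CuB domains; AXA is the transit-peptide
    cleavage motif; YXY marks the C-terminal proteolytic processing site in
    the DWL domain; KFDV and EFAGSF are literal C-terminal motifs; GLU_RICH
    is a 9-residue window with >= 5 glutamates; HIS_RUN is a maximal run of
    >= 2 consecutive histidines (candidate third copper site).
    """
    p = protein.residues
    hits: list[MotifHit] = []
    n = len(p)
    for i in range(n):
        if p[i] == "H" and i + 5 <= n:
            if p[i + 4] == "C":
                hits.append(MotifHit("HXXXC", i, p[i:i + 5]))
            if p[i + 4] == "H" and p[i + 3] in HXXXH_HYDROPHOBIC:
                hits.append(MotifHit("HXXXH", i, p[i:i + 5]))
        if p[i] == "A" and i + 3 <= n and p[i + 2] == "A":
            hits.append(MotifHit("AXA", i, p[i:i + 3]))
        if p[i] == "Y" and i + 3 <= n and p[i + 2] == "Y":
            hits.append(MotifHit("YXY", i, p[i:i + 3]))
        if p.startswith("KFDV", i):
            hits.append(MotifHit("KFDV", i, "KFDV"))
        if p.startswith("EFAGSF", i):
            hits.append(MotifHit("EFAGSF", i, "EFAGSF"))
        if i + 9 <= n and p[i:i + 9].count("E") >= 5:
            hits.append(MotifHit("GLU_RICH", i, p[i:i + 9]))
    # maximal runs of >= 2 His
    i = 0
    while i < n:
        if p[i] == "H":
            j = i
            while j < n and p[j] == "H":
                j += 1
            if j - i >= 2:
                hits.append(MotifHit("HIS_RUN", i, p[i:j]))
            i = j
        else:
            i += 1
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


# ---------------------------------------------------------------------------
# copper-binding domains


def _his_in_window(p: str, start: int, window: int) -> list[int]:
    return [j for j in range(start + 1, min(len(p), start + window))
            if p[j] == "H"]


def locate_cu_domains(
    protein: ProteinSequence,
    hits: list[MotifHit] | None = None,
    params: AnnotationParams = DEFAULT_PARAMS,
) -> tuple[CuDomainResult, CuDomainResult]:
    """Locate CuA and CuB.

    CuA: the first HxxxC anchor whose following ``his_window`` residues
    contain at least two further histidines; its span runs from the anchor to
    the third conserved His (inclusive). CuB: the first HxxxH anchor at
    linker distance ``linker_min``..``linker_max`` past the CuA end whose
    window contains a third His and a phenylalanine downstream of the second
    motif His. When no anchor satisfies the His requirement, the best
    anchor's His count is still reported so validation can distinguish a
    missing domain (no anchor) from missing histidines.
    """
    if hits is None:
        hits = scan_motifs(protein)
    p = protein.residues

    def resolve(anchors: list[int], motif_his: int, need_further: int,
                require_f: bool) -> CuDomainResult:
        if not anchors:
            return CuDomainResult(False, None, (), 0)
        best: tuple[int, int] | None = None  # (-count, anchor)
        for a in anchors:
            further = _his_in_window(p, a + 4 if motif_his == 2 else a, params.his_window)
            if motif_his == 2:
                further = [j for j in further if j > a + 4]
            n_found = min(need_further, len(further))
            ok = len(further) >= need_further
            if ok and require_f:
                f_ok = any(p[j] == "F" for j in range(a + 5, min(len(p), a + params.his_window)))
                ok = ok and f_ok
            if ok:
                sel = further[:need_further]
                his = ((a, sel[0], sel[1]) if motif_his == 1 else (a, a + 4, sel[0]))
                return CuDomainResult(True, (a, his[-1] + 1), his, 3)
            score = (-n_found, a)
            if best is None or score < best:
                best = score
        a = best[1]
        further = _his_in_window(p, a + 4 if motif_his == 2 else a, params.his_window)
        if motif_his == 2:
            further = [j for j in further if j > a + 4]
        n_his = min(3, motif_his + len(further))
        his = tuple([a] + ([a + 4] if motif_his == 2 else []) + further)[:n_his]
        return CuDomainResult(True, None, his, n_his)

    cua_anchors = [h.start for h in hits if h.motif_name == "HXXXC"]
    cua = resolve(cua_anchors, motif_his=1, need_further=2, require_f=False)

    if cua.located:
        lo = cua.span[1] + params.linker_min
        hi = cua.span[1] + params.linker_max
        cub_anchors = [h.start for h in hits
                       if h.motif_name == "HXXXH" and lo <= h.start <= hi]
    else:
        cub_anchors = [h.start for h in hits if h.motif_name == "HXXXH"]
    cub = resolve(cub_anchors, motif_his=2, need_further=1, require_f=True)
    return cua, cub


def segment_architecture(
    protein: ProteinSequence,
    cua: CuDomainResult,
    cub: CuDomainResult,
    hits: list[MotifHit] | None = None,
    params: AnnotationParams = DEFAULT_PARAMS,
) -> DomainArchitecture:
    """Tile the protein into the six-segment architecture.

    Requires both Cu spans. DWL is ``dwl_length`` residues past the CuB end,
    extended rightwards to cover a YxY hit falling in the ``yxy_search``
    window; KFDV is the remainder. A protein ending inside the DWL window is
    flagged (``kfdv_empty``).
    """
    if not (cua.located and cub.located):
        raise ValueError(f"{protein.gene_id}: both Cu domains must be located")
    if hits is None:
        hits = scan_motifs(protein)
    n = len(protein.residues)
    cua_s, cua_e = cua.span
    cub_s, cub_e = cub.span
    dwl_end = cub_e + params.dwl_length
    for h in hits:
        if h.motif_name == "YXY" and \
                cub_e + params.yxy_search[0] <= h.start < cub_e + params.yxy_search[1]:
            dwl_end = max(dwl_end, h.end)
            break
    kfdv_empty = dwl_end >= n
    dwl_end = min(dwl_end, n)
    arch = DomainArchitecture(
        gene_id=protein.gene_id,
        segments={
            "NTERM": (0, cua_s),
            "CUA": (cua_s, cua_e),
            "LINKER": (cua_e, cub_s),
            "CUB": (cub_s, cub_e),
            "DWL": (cub_e, dwl_end),
            "KFDV": (dwl_end, n),
        },
        cu_his_positions=cua.his_positions + cub.his_positions,
        kfdv_empty=kfdv_empty,
    )
    if kfdv_empty:
        log.warning("%s: protein ends inside the DWL window; KFDV segment empty",
                    protein.gene_id)
    return arch


# ---------------------------------------------------------------------------
# targeting classification


def classify_targeting(
    protein: ProteinSequence,
    params: AnnotationParams = DEFAULT_PARAMS,
    external: dict[str, tuple[str, float]] | None = None,
) -> tuple[str, float]:
    """Heuristic stand-in for ChloroP/TargetP N-terminal classification.

    CTP: serine-enriched first 35 residues (stromal-peptide signature) plus
    an AxA cleavage motif within ``axa_range``. SP: an 8-residue window in
    ``hyd_range`` whose mean Kyte–Doolittle hydropathy reaches
    ``hyd_threshold`` (hydrophobic h-region). Otherwise UNKNOWN. An external
    predictor table (see :func:`parse_targetp`) overrides the heuristic.
    """
    if external is not None and protein.gene_id in external:
        return external[protein.gene_id]
    p = protein.residues
    if len(p) < 35:
        log.warning("%s: too short (<35 aa) for targeting classification",
                    protein.gene_id)
        return "UNKNOWN", 0.0
    ser_frac = p[:35].count("S") / 35.0
    lo, hi = params.axa_range
    has_axa = any(p[i] == "A" and p[i + 2] == "A"
                  for i in range(lo, min(hi, len(p) - 2)))
    if ser_frac >= params.ser_threshold and has_axa:
        return "CTP", ser_frac
    w = params.hyd_window
    best = -math.inf
    for s in range(params.hyd_range[0], min(params.hyd_range[1] - w, len(p) - w) + 1):
        window = p[s:s + w]
        best = max(best, sum(KYTE_DOOLITTLE[c] for c in window) / w)
    if best >= params.hyd_threshold:
        return "SP", best
    return "UNKNOWN", 0.0


def parse_targetp(path) -> dict[str, tuple[str, float]]:
    """Adapter for a whitespace-delimited external predictor table
    (columns: name, prediction code, score). Codes: C -> CTP, S -> SP,
    anything else -> UNKNOWN."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                continue
            name, code, score = parts[0], parts[1].upper(), float(parts[2])
            cls = {"C": "CTP", "S": "SP"}.get(code, "UNKNOWN")
            out[name] = (cls, score)
    return out


# ---------------------------------------------------------------------------
# conservation (sequence-logo information content)

LOG2_20 = math.log2(20)


def column_information(rows: list[str], max_gap_fraction: float = 0.5) -> list[float | None]:
    """Per-column information content in bits: log2(20) minus the Shannon
    entropy of the residue frequencies. Gaps (and 'X') are excluded from the
    frequencies; columns with more than ``max_gap_fraction`` gaps, or with no
    residues at all, are reported as ``None`` (missing). No small-sample
    correction is applied.
    """
    if not rows:
        return []
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("aligned rows must have equal length")
    out: list[float | None] = []
    for c in range(width):
        col = [r[c] for r in rows]
        residues = [x for x in col if x not in ("-", "X")]
        if not residues or (len(col) - len(residues)) / len(col) > max_gap_fraction:
            out.append(None)
            continue
        counts = Counter(residues)
        total = len(residues)
        entropy = -sum((k / total) * math.log2(k / total) for k in counts.values())
        out.append(LOG2_20 - entropy)
    return out
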