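"""Core-protein multiple alignment.

Two routes produce the same :class:`MultipleAlignment` surface: an adapter
that validates an externally supplied aligned FASTA (the recommended path,
mirroring the usual MUSCLE/MAFFT workflow), and a built-in fallback
progressive aligner (UPGMA guide tree on k-mer distances, profiles merged by
affine-gap dynamic programming). Trimming to the core (CuA..DWL) and
residue<->column coordinate maps live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from Bio.Align import substitution_matrices

from .domain_annotation import DomainArchitecture

log = logging.getLogger(__name__)

ALPHABET = "ARNDCQEGHILKMFPSTWYVX"
_AA_IDX = {a: i for i, a in enumerate(ALPHABET)}


def _pam250_table() -> np.ndarray:
    """Fixed PAM250-style integer substitution table over ``ALPHABET``."""
    m = substitution_matrices.load("PAM250")
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out


PAM250 = _pam250_table()

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass
class MultipleAlignment:
    rows: list[str]          # ordered gene_ids
    matrix: list[str]        # equal-length gapped residue strings

    def __post_init__(self):
        widths = {len(r) for r in self.matrix}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        if len(self.rows) != len(self.matrix):
            raise ValueError("rows and matrix must correspond")

    @property
    def column_count(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def row(self, gene_id: str) -> str:
        return self.matrix[self.rows.index(gene_id)]

    def degapped(self, gene_id: str) -> str:
        return self.row(gene_id).replace("-", "")


@dataclass
class CoordinateMap:
    """Residue index <-> alignment column for one gene (non-gap bijective)."""

    gene_id: str
    residue_to_column: np.ndarray   # len = residue count
    column_to_residue: np.ndarray   # len = column count; -1 at gaps


def build_coordinate_maps(msa: MultipleAlignment) -> dict[str, CoordinateMap]:
    maps = {}
    for gid, row in zip(msa.rows, msa.matrix):
        r2c, c2r = [], []
        for col, ch in enumerate(row):
            if ch == "-":
                c2r.append(-1)
            else:
                c2r.append(len(r2c))
                r2c.append(col)
        maps[gid] = CoordinateMap(gid, np.array(r2c, dtype=int),
                                  np.array(c2r, dtype=int))
    return maps


# ---------------------------------------------------------------------------
# affine-gap dynamic programming (shared by sequence and profile alignment)

_NEG = -1e30


@njit(cache=False)
def _affine_dp(sim, gap_open, gap_extend):  # pragma: no cover - jitted
    """Global affine-gap alignment over a dense similarity matrix.

    Returns (score, moves) where moves (reversed order) are 0 = diagonal,
    1 = consume row item only (gap in the column sequence), 2 = consume
    column item only. Tie-break: diagonal, then gap in the first (row)
    profile, then gap in the second.
    """
    n, m = sim.shape
    go = gap_open + gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)   # consuming rows (gap in columns seq)
    Y = np.full((n + 1, m + 1), _NEG)   # consuming cols (gap in rows seq)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -go - gap_extend * (i - 1)
        pX[i, 0] = 0 if i == 1 else 2
    for j in range(1, m + 1):
        Y[0, j] = -go - gap_extend * (j - 1)
        pY[0, j] = 0 if j == 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: prefer M > Y > X on ties
            best = M[i - 1, j - 1]; src = 0
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]; src = 1
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]; src = 2
            M[i, j] = best + sim[i - 1, j - 1]; pM[i, j] = src
            # Y (gap in row profile, consume column j): prefer M > Y > X
            best = M[i, j - 1] - go; src = 0
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend; src = 1
            if X[i, j - 1] - go > best:
                best = X[i, j - 1] - go; src = 2
            Y[i, j] = best; pY[i, j] = src
            # X (gap in column profile, consume row i)
            best = M[i - 1, j] - go; src = 0
            if Y[i - 1, j] - go > best:
                best = Y[i - 1, j] - go; src = 1
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend; src = 2
            X[i, j] = best; pX[i, j] = src
    state = 0
    score = M[n, m]
    if Y[n, m] > score:
        score = Y[n, m]; state = 1
    if X[n, m] > score:
        score = X[n, m]; state = 2
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]; moves[k] = 0; i -= 1; j -= 1
        elif state == 1:
            nxt = pY[i, j]; moves[k] = 1; j -= 1
        else:
            nxt = pX[i, j]; moves[k] = 2; i -= 1
        state = nxt
        k += 1
    return score, moves[:k]


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_IDX.get(c, len(ALPHABET) - 1) for c in seq], dtype=int)


def pairwise_global_align(
    a: str, b: str,
    substitution_table: np.ndarray = PAM250,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[str, str, float]:
    """Optimal global alignment with affine gaps (a gap of length k costs
    ``gap_open + gap_extend * k``). Deterministic tie-breaking: prefer the
    diagonal, then a gap in ``a``, then a gap in ``b``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sim = substitution_table[np.ix_(_encode(a), _encode(b))].astype(float)
    score, moves = _affine_dp(sim, float(gap_open), float(gap_extend))
    out_a, out_b = [], []
    i = j = 0
    for mv in moves[::-1]:
        if mv == 0:
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif mv == 1:
            out_a.append("-"); out_b.append(b[j]); j += 1
        else:
            out_a.append(a[i]); out_b.append("-"); i += 1
    return "".join(out_a), "".join(out_b), float(score)


# ---------------------------------------------------------------------------
# progressive fallback aligner


def _profile_freqs(rows: list[str]) -> np.ndarray:
    L = len(rows[0])
    F = np.zeros((L, len(ALPHABET)))
    for r in rows:
        for c, ch in enumerate(r):
            if ch != "-":
                F[c, _AA_IDX.get(ch, len(ALPHABET) - 1)] += 1.0
    return F / len(rows)


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    sub: np.ndarray, go: float, ge: float) -> list[str]:
    Fa = _profile_freqs(rows_a)
    Fb = _profile_freqs(rows_b)
    sim = Fa @ sub @ Fb.T
    _, moves = _affine_dp(sim, go, ge)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves[::-1]:
        if mv == 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            i += 1; j += 1
        elif mv == 1:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j])
            j += 1
        else:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    from collections import Counter
    ca, cb = Counter(a[i:i + k] for i in range(len(a) - k + 1)), \
        Counter(b[i:i + k] for i in range(len(b) - k + 1))
    common = sum(min(ca[x], cb[x]) for x in ca)
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - common / denom if denom > 0 else 1.0


def progressive_align(
    seqs: dict[str, str],
    substitution_table: np.ndarray = PAM250,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Built-in fallback multiple aligner (UPGMA guide tree on k-mer
    distances; profile-profile merges with affine-gap DP). Deterministic."""
    ids = list(seqs.keys())
    if len(ids) == 0:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return MultipleAlignment(ids, [seqs[ids[0]]])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    Z = linkage(squareform(D, checks=False), method="average")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ida, idb = int(a), int(b)
        ids_a, rows_a = clusters.pop(ida)
        ids_b, rows_b = clusters.pop(idb)
        merged = _merge_profiles(rows_a, rows_b, substitution_table,
                                 float(gap_open), float(gap_extend))
        clusters[n + step] = (ids_a + ids_b, merged)
    (final_ids, final_rows), = clusters.values()
    order = {g: i for i, g in enumerate(final_ids)}
    return MultipleAlignment(ids, [final_rows[order[g]] for g in ids])


def load_external_alignment(path, expected: dict[str, str] | None = None) -> MultipleAlignment:
    """Adapter: validate and use a precomputed aligned FASTA verbatim.

    When ``expected`` (gene_id -> ungapped sequence) is given, each row must
    degap to its input sequence exactly.
    """
    from .io_formats import read_fasta

    recs = read_fasta(path)
    msa = MultipleAlignment(list(recs.keys()), list(recs.values()))
    if expected is not None:
        for gid in msa.rows:
            if gid not in expected:
                raise ValueError(f"alignment row {gid!r} not among input sequences")
            if msa.degapped(gid) != expected[gid]:
                raise ValueError(f"alignment row {gid!r} does not degap to its input")
    return msa


# ---------------------------------------------------------------------------
# trimming to the core (CuA .. DWL)


@dataclass
class TrimResult:
    core: MultipleAlignment
    offsets: dict[str, int]        # residues trimmed off the left, per gene
    column_range: tuple[int, int]  # [start, end) in the untrimmed alignment


def trim_to_core(msa: MultipleAlignment,
                 architectures: dict[str, DomainArchitecture]) -> TrimResult:
    """Remove N- and C-terminal columns, keeping the union span from the
    first column hosting any CuA start to the last column hosting any DWL
    end. Rows without a usable architecture (missing, or empty DWL) are
    excluded with a warning."""
    maps = build_coordinate_maps(msa)
    keep_ids = []
    col_start, col_end = None, None
    for gid in msa.rows:
        arch = architectures.get(gid)
        if arch is None or arch.segments["DWL"][0] >= arch.segments["DWL"][1]:
            log.warning("%s: no usable architecture; excluded from core alignment", gid)
            continue
        keep_ids.append(gid)
        r2c = maps[gid].residue_to_column
        cua_start = arch.segments["CUA"][0]
        dwl_last = arch.segments["DWL"][1] - 1
        c0, c1 = int(r2c[cua_start]), int(r2c[dwl_last])
        col_start = c0 if col_start is None else min(col_start, c0)
        col_end = c1 if col_end is None else max(col_end, c1)
    if not keep_ids:
        raise ValueError("no rows with usable architectures to trim")
    col_end += 1
    rows = [msa.row(g)[col_start:col_end] for g in keep_ids]
    offsets = {}
    for gid in keep_ids:
        c2r = maps[gid].column_to_residue[:col_start]
        offsets[gid] = int((c2r >= 0).sum())
    return TrimResult(MultipleAlignment(keep_ids, rows), offsets,
                      (col_start, col_end))
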