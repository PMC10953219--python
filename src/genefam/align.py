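"""Pairwise and progressive alignment plus an e-value proxy.

Family members are full-length homologs, so alignment is global
(Needleman-Wunsch/Gotoh affine gaps, via Bio.Align.PairwiseAligner) and
identity is computed over aligned columns excluding terminal gaps, which
avoids penalising the large length variation typical of a gene family.

The e-value proxy is a Karlin-Altschul-shaped formula
``E = k * m * n * N * exp(-lambda * score)`` with config-exposed
constants; it orders alignments the way a database search would and is
used only to apply a significance cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import SeqRecord, DNA_ALPHABET, PROTEIN_ALPHABET

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    evalue: float | None = None


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any() or not np.allclose(np.diag(m), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m


def _alphabet_of(seq: str) -> str:
    return "dna" if set(seq) <= DNA_ALPHABET else "protein"


def _make_aligner(substitution_matrix=None, gap_open: float = 10.0,
                  gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        _BLOSUM62 if substitution_matrix is None else substitution_matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def alignment_identity(aligned_a: str, aligned_b: str,
                       exclude_terminal_gaps: bool = True) -> float:
    """Fraction of identical columns, excluding dual-gap columns and
    (by default) terminal-gap columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    lo, hi = 0, len(aligned_a)
    if exclude_terminal_gaps:
        both = [i for i in range(len(aligned_a))
                if aligned_a[i] != "-" and aligned_b[i] != "-"]
        if not both:
            return 0.0
        lo, hi = both[0], both[-1] + 1
    ident = comparable = 0
    for a, b in zip(aligned_a[lo:hi], aligned_b[lo:hi]):
        if a == "-" and b == "-":
            continue
        comparable += 1
        if a == b and a != "-":
            ident += 1
    return ident / comparable if comparable else 0.0


def global_align(a: SeqRecord, b: SeqRecord, substitution_matrix=None,
                 gap_open: float = 10.0, gap_extend: float = 1.0) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps; deterministic choice
    among co-optimal alignments."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    if _alphabet_of(a.sequence) != _alphabet_of(b.sequence):
        raise ValueError(f"mixed alphabets: {a.id} vs {b.id}")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(
        seq_a_id=a.id, seq_b_id=b.id, aligned_a=ga, aligned_b=gb,
        score=float(aln.score), identity=alignment_identity(ga, gb))


def evalue_proxy(score: float, len_a: int, len_b: int, n_comparisons: int = 1,
                 ka_lambda: float = 0.267, ka_k: float = 0.041) -> float:
    """E = k * m * n * N * exp(-lambda * score); strictly decreasing in score."""
    if len_a < 1 or len_b < 1:
        raise ValueError("sequence lengths must be >= 1")
    return ka_k * len_a * len_b * n_comparisons * math.exp(-ka_lambda * score)


def distance_matrix(msa: list[SeqRecord], model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an MSA: p-distance or Poisson-corrected.

    p = mismatches / columns where both rows are non-gap;
    Poisson d = -ln(1 - p). A pair with no comparable columns, or with
    p >= 1 under the Poisson model, is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    L = len(msa[0].sequence)
    if any(len(r.sequence) != L for r in msa):
        raise ValueError("MSA rows must have equal length")
    n = len(msa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = msa[i].sequence, msa[j].sequence
            comparable = mismatch = 0
            for a, b in zip(si, sj):
                if a == "-" or b == "-":
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {msa[i].id} and {msa[j].id}")
            p = mismatch / comparable
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson distance undefined (p={p}) for "
                        f"{msa[i].id} vs {msa[j].id}")
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=[r.id for r in msa], matrix=D)


# ------------------------------------------------------------------ MSA
# A deliberately simple progressive aligner (NJ guide tree + profile-
# profile Needleman-Wunsch with linear gaps). Documented as approximate;
# an externally produced MSA can be supplied to any downstream stage
# instead.

_GAP_RES = -4.0


def _col_score(col_a: str, col_b: str, matrix) -> float:
    total = pairs = 0
    for x in col_a:
        for y in col_b:
            pairs += 1
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total += _GAP_RES
            else:
                total += matrix[x][y]
    return total / pairs


def _profile_align(rows_a: list[str], rows_b: list[str], matrix,
                   gap: float = 8.0) -> tuple[list[str], list[str]]:
    cols_a = ["".join(r[i] for r in rows_a) for i in range(len(rows_a[0]))]
    cols_b = ["".join(r[i] for r in rows_b) for i in range(len(rows_b[0]))]
    la, lb = len(cols_a), len(cols_b)
    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = -gap * np.arange(1, la + 1)
    score[0, 1:] = -gap * np.arange(1, lb + 1)
    ptr[1:, 0], ptr[0, 1:] = 1, 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cand = (score[i - 1, j - 1] + _col_score(cols_a[i - 1], cols_b[j - 1], matrix),
                    score[i - 1, j] - gap,
                    score[i, j - 1] - gap)
            k = int(np.argmax(cand))  # ties: diagonal > up > left
            score[i, j], ptr[i, j] = cand[k], k
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    gap_a, gap_b = "-" * len(rows_a), "-" * len(rows_b)
    while i > 0 or j > 0:
        k = ptr[i, j]
        if i > 0 and j > 0 and k == 0:
            out_a.append(cols_a[i - 1]); out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and k != 2:
            out_a.append(cols_a[i - 1]); out_b.append(gap_b)
            i -= 1
        else:
            out_a.append(gap_a); out_b.append(cols_b[j - 1])
            j -= 1
    out_a.reverse(); out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(rows_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(rows_b))]
    return new_a, new_b


def build_msa(records: list[SeqRecord], substitution_matrix=None,
              gap_open: float = 10.0, gap_extend: float = 1.0) -> list[SeqRecord]:
    """Naive progressive MSA guided by an NJ tree on pairwise identities.

    Good enough to feed distance-based phylogeny on closely related
    families; not a ClustalX replacement.
    """
    from .phylo import neighbor_joining  # local import avoids a cycle

    if len(records) == 1:
        return [SeqRecord(records[0].id, records[0].description, records[0].sequence)]
    matrix = _BLOSUM62 if substitution_matrix is None else substitution_matrix
    n = len(records)
    by_id = {r.id: r for r in records}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], matrix, gap_open, gap_extend)
            D[i, j] = D[j, i] = 1.0 - aln.identity
    if n == 2:
        aln = global_align(records[0], records[1], matrix, gap_open, gap_extend)
        return [SeqRecord(records[0].id, records[0].description, aln.aligned_a),
                SeqRecord(records[1].id, records[1].description, aln.aligned_b)]
    guide = neighbor_joining(DistanceMatrix([r.id for r in records], D))

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_id[node.name].sequence]
        ids, rows = merge(node.children[0])
        for child in node.children[1:]:
            ids_c, rows_c = merge(child)
            rows, rows_c = _profile_align(rows, rows_c, matrix)
            ids, rows = ids + ids_c, rows + rows_c
        return ids, rows

    ids, rows = merge(guide.root)
    aligned = {i: s for i, s in zip(ids, rows)}
    return [SeqRecord(r.id, r.description, aligned[r.id]) for r in records]
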