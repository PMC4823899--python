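"""Progressive multiple alignment and identity statistics.

A deterministic MUSCLE-style stand-in: a UPGMA guide tree on 3-mer cosine
distances, then profile-profile merges scored with BLOSUM62
expected column scores under affine gap penalties (open 10, extend 1, the
classic half-bit scale).  Identity statistics exclude any pair-column where
either sequence carries a gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._align_kernels import OP_CONSUME_A, OP_CONSUME_B, gotoh_align
from .io_formats import SequenceSet, _ENCODE_LUT
from .models import AMINO_ACIDS, GAP
from .partition import Partition, as_partition

GAP_OPEN = 10.0
GAP_EXTEND = 1.0


def _blosum62_matrix() -> np.ndarray:
    bl = substitution_matrices.load("BLOSUM62")
    s = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = bl[a, b]
    return s


BLOSUM62 = _blosum62_matrix()


def _encode(seq: str) -> np.ndarray:
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == -2).any():
        raise ValueError("sequence contains letters outside the amino-acid alphabet")
    return arr


# -- identity statistics ----------------------------------------------


def pairwise_identity(s1: str, s2: str) -> float:
    """Fraction of matching residues over columns where neither sequence is
    gapped; zero when no such column exists."""
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal (aligned) length")
    a, b = _encode(s1), _encode(s2)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        return 0.0
    return float((a[ok] == b[ok]).sum() / n)


@dataclass
class IdentitySummary:
    """Pairwise identity matrix with its averages."""

    ids: List[str]
    pairwise: np.ndarray
    average: float
    within_minus_between: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "ids": self.ids,
            "pairwise": self.pairwise.tolist(),
            "average": self.average,
        }
        if self.within_minus_between is not None:
            out["within_minus_between"] = self.within_minus_between
        return out


def _pair_indices(n: int):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def identity_matrix(alignment: SequenceSet) -> np.ndarray:
    seqs = alignment.sequences
    n = len(seqs)
    m = np.eye(n)
    for i, j in _pair_indices(n):
        m[i, j] = m[j, i] = pairwise_identity(seqs[i], seqs[j])
    return m


def average_identity(
    alignment: SequenceSet,
    pairs: str = "all",
    partition: Optional[Partition | Dict] = None,
) -> float:
    """Unweighted mean pairwise identity over the selected pairs.

    ``pairs`` is one of ``"all"``, ``"within"`` (both sequences in the same
    partition group) or ``"between"``.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    if pairs not in ("all", "within", "between"):
        raise ValueError("pairs must be 'all', 'within' or 'between'")
    ids = alignment.ids
    m = identity_matrix(alignment)
    if pairs == "all":
        sel = _pair_indices(len(ids))
    else:
        part = as_partition(partition)
        grp = {i: part.group_of(i) for i in ids}
        same = [(i, j) for i, j in _pair_indices(len(ids)) if grp[ids[i]] == grp[ids[j]]]
        if pairs == "within":
            if not same:
                raise ValueError("no within-group pairs (groups of size < 2?)")
            sel = same
        else:
            sel = [p for p in _pair_indices(len(ids)) if p not in same]
    return float(np.mean([m[i, j] for i, j in sel]))


def identity_summary(
    alignment: SequenceSet, partition: Optional[Partition | Dict] = None
) -> IdentitySummary:
    m = identity_matrix(alignment)
    n = len(alignment)
    avg = float(np.mean([m[i, j] for i, j in _pair_indices(n)]))
    wmb = None
    if partition is not None:
        wmb = average_identity(alignment, "within", partition) - average_identity(
            alignment, "between", partition
        )
    return IdentitySummary(alignment.ids, m, avg, wmb)


def column_identity_scores(alignment: SequenceSet) -> np.ndarray:
    """Per-column mean pairwise identity (gap pair-columns excluded).

    The conservation score used to reorder columns in the
    similarity-conditioned experiment.
    """
    mat = alignment.to_matrix()
    n, L = mat.shape
    match = np.zeros(L)
    comparable = np.zeros(L)
    for i, j in _pair_indices(n):
        ok = (mat[i] >= 0) & (mat[j] >= 0)
        match += ok & (mat[i] == mat[j])
        comparable += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(comparable > 0, match / np.maximum(comparable, 1), 0.0)
    return score


# -- alignment ---------------------------------------------------------


def strip_gaps(seqs: SequenceSet) -> SequenceSet:
    """Remove gap characters from every sequence, preserving order."""
    return SequenceSet([(i, s.replace(GAP, "")) for i, s in seqs])


@dataclass
class PairwiseAlignment:
    aligned1: str
    aligned2: str
    score: float


def _profile_frequencies(mat: np.ndarray) -> np.ndarray:
    """(n_cols, 20) residue frequencies; gaps contribute zero weight."""
    n_seq, n_cols = mat.shape
    freq = np.zeros((n_cols, 20))
    for s in range(20):
        freq[:, s] = (mat == s).sum(axis=0)
    return freq / n_seq


def _merge_profiles(mat_a: np.ndarray, mat_b: np.ndarray):
    fa = _profile_frequencies(mat_a)
    fb = _profile_frequencies(mat_b)
    score = fa @ BLOSUM62 @ fb.T
    ops, best = gotoh_align(score, GAP_OPEN, GAP_EXTEND)
    n_out = len(ops)
    out = np.full((mat_a.shape[0] + mat_b.shape[0], n_out), -1, dtype=np.int8)
    na = mat_a.shape[0]
    cols_a = np.flatnonzero(ops != OP_CONSUME_B)
    cols_b = np.flatnonzero(ops != OP_CONSUME_A)
    out[:na, cols_a] = mat_a
    out[na:, cols_b] = mat_b
    return out, float(best)


def pairwise_align(s1: str, s2: str) -> PairwiseAlignment:
    """Optimal global alignment of two ungapped sequences (Needleman–Wunsch
    with affine gaps, BLOSUM62), deterministic tie-breaking: residue pair
    over gap-in-first over gap-in-second."""
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    a = _encode(s1)[None, :]
    b = _encode(s2)[None, :]
    merged, score = _merge_profiles(a, b)
    row1 = "".join(GAP if v < 0 else AMINO_ACIDS[v] for v in merged[0])
    row2 = "".join(GAP if v < 0 else AMINO_ACIDS[v] for v in merged[1])
    return PairwiseAlignment(row1, row2, score)


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """1 - cosine similarity of k-mer count vectors."""
    vecs = []
    for s in seqs:
        arr = _encode(s).astype(np.int64)
        if len(arr) < k:
            vecs.append(np.zeros(20**k))
            continue
        idx = np.zeros(len(arr) - k + 1, dtype=np.int64)
        for off in range(k):
            idx = idx * 20 + arr[off : len(arr) - k + 1 + off]
        vecs.append(np.bincount(idx, minlength=20**k).astype(float))
    n = len(seqs)
    d = np.zeros((n, n))
    norms = [np.linalg.norm(v) for v in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                cos = 0.0
            else:
                cos = float(vecs[i] @ vecs[j] / (norms[i] * norms[j]))
            d[i, j] = d[j, i] = 1.0 - cos
    return d


def progressive_align(seqs: SequenceSet) -> SequenceSet:
    """Progressive multiple alignment.

    Guide tree: neighbour joining on 3-mer cosine distances; merges follow
    the tree bottom-up with the same profile scoring throughout.  Stripping
    gaps from the result recovers the inputs exactly; the output row order
    is the input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for ident, s in seqs:
        if not s:
            raise ValueError(f"empty sequence {ident!r}")
        if GAP in s:
            raise ValueError(f"sequence {ident!r} is gapped; strip gaps first")
    ids = seqs.ids
    mats = {i: _encode(s)[None, :].astype(np.int8) for i, s in seqs}
    if len(seqs) == 2:
        merged, _ = _merge_profiles(mats[ids[0]], mats[ids[1]])
        order = {ids[0]: 0, ids[1]: 1}
        return SequenceSet.from_matrix(ids, merged[[order[i] for i in ids]])
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    d = _kmer_distance_matrix(seqs.sequences)
    # UPGMA (average-linkage) guide tree, as MUSCLE uses: with clustered
    # data it merges each cluster internally before crossing clusters,
    # which neighbour joining does not guarantee on these star-like,
    # non-additive distances
    linkage = average(squareform(d, checks=False))
    parts = {i: ([ids[i]], mats[ids[i]]) for i in range(len(ids))}
    nxt = len(ids)
    for a, b, _, _ in linkage:
        la, ma = parts.pop(int(a))
        lb, mb = parts.pop(int(b))
        merged, _ = _merge_profiles(ma, mb)
        parts[nxt] = (la + lb, merged)
        nxt += 1
    labels, merged = parts.popitem()[1]
    row_of = {lab: r for r, lab in enumerate(labels)}
    return SequenceSet.from_matrix(ids, merged[[row_of[i] for i in ids]])
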