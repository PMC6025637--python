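"""Progressive multiple alignment and alignment-column utilities.

The family this package targets is indel-poor (members are 93-99% identical
at the protein level), so a classic guide-tree progressive scheme in the
ClustalW mould is sufficient: k-mer distances -> average-linkage guide tree
-> Needleman-Wunsch/Gotoh pairwise and profile-profile merges with affine
gap costs.  Everything is deterministic: ties in the dynamic program are
broken in a fixed order (match, then gap-in-first, then gap-in-second) and
the guide tree uses scipy's deterministic linkage.

Gap handling for downstream statistics follows the complete-deletion
convention: distances are computed on columns with no gap in any row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import AlignmentError

__all__ = [
    "GAP",
    "AlignmentScoring",
    "MultipleAlignment",
    "align_pairwise",
    "align_progressive",
    "strip_gap_columns",
    "percent_identity",
]

GAP = "-"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: first gap residue costs ``gap_open``, each further
    one ``gap_extend`` (both negative)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def score(self, a: str, b: str) -> float:
        return float(_BLOSUM62[a, b])


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows with ids; one row anchors reference numbering."""

    ids: list[str]
    rows: list[str]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("alignment rows have unequal lengths")
        if self.reference_id is None and self.ids:
            self.reference_id = self.ids[0]
        if self.reference_id not in self.ids:
            raise AlignmentError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise AlignmentError(f"id {rid!r} not in alignment")

    def reference_column_map(self) -> dict[int, int]:
        """Map 1-based ungapped reference positions -> 0-based columns."""
        ref = self.row(self.reference_id)
        out, pos = {}, 0
        for col, c in enumerate(ref):
            if c != GAP:
                pos += 1
                out[pos] = col
        return out


def align_pairwise(a: str, b: str, scoring: AlignmentScoring | None = None):
    """Global pairwise alignment (Gotoh affine gaps). Returns (score, rowA, rowB)."""
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    out_a, out_b, score = _align_profiles([a], [b], scoring or AlignmentScoring())
    return score, out_a[0], out_b[0]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 1))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 1))}
    inter = len(ka & kb)
    return 1.0 - inter / max(min(len(ka), len(kb)), 1)


def _profile_columns(rows: list[str]) -> list[dict[str, float]]:
    cols = []
    for i in range(len(rows[0])):
        counts: dict[str, float] = {}
        for r in rows:
            counts[r[i]] = counts.get(r[i], 0.0) + 1.0
        total = len(rows)
        cols.append({c: v / total for c, v in counts.items()})
    return cols


def _profile_score(ca: dict[str, float], cb: dict[str, float], scoring: AlignmentScoring) -> float:
    s = 0.0
    for x, fx in ca.items():
        if x == GAP:
            continue
        for y, fy in cb.items():
            if y == GAP:
                continue
            s += fx * fy * float(_BLOSUM62[x, y])
    return s


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scoring: AlignmentScoring
) -> tuple[list[str], list[str], float]:
    """Gotoh on column profiles; returns gapped copies of both row sets and
    the alignment score."""
    pa, pb = _profile_columns(rows_a), _profile_columns(rows_b)
    n, m = len(pa), len(pb)
    go, ge = scoring.gap_open, scoring.gap_extend
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
        ptr[1, i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
        ptr[2, 0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _profile_score(pa[i - 1], pb[j - 1], scoring)
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))
            M[i, j] = cand[k] + s
            ptr[0, i, j] = k
            cand = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            k = int(np.argmax(cand))
            X[i, j] = cand[k]
            ptr[1, i, j] = k
            cand = (M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
            k = int(np.argmax(cand))
            Y[i, j] = cand[k]
            ptr[2, i, j] = (0, 2, 1)[k]
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    score = float((M[i, j], X[i, j], Y[i, j])[state])
    ga: list[bool] = []  # per output column: does A advance?
    gb: list[bool] = []
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == 0:
            ga.append(True)
            gb.append(True)
            i, j = i - 1, j - 1
        elif state == 1:
            ga.append(True)
            gb.append(False)
            i -= 1
        else:
            ga.append(False)
            gb.append(True)
            j -= 1
        state = int(prev)
    ga.reverse()
    gb.reverse()
    out_a = []
    for r in rows_a:
        it = iter(r)
        out_a.append("".join(next(it) if adv else GAP for adv in ga))
    out_b = []
    for r in rows_b:
        it = iter(r)
        out_b.append("".join(next(it) if adv else GAP for adv in gb))
    return out_a, out_b, score


def align_progressive(
    sequences: dict[str, str] | list[tuple[str, str]],
    scoring: AlignmentScoring | None = None,
    reference_id: str | None = None,
) -> MultipleAlignment:
    """Guide-tree progressive multiple alignment.

    Guide distances are 3-mer set dissimilarities; the guide tree is
    average-linkage; profiles are merged bottom-up with affine-gap Gotoh.
    """
    scoring = scoring or AlignmentScoring()
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise AlignmentError("need at least two sequences to align")
    for rid, seq in items:
        if not seq:
            raise AlignmentError(f"sequence {rid!r} is empty")
    ids = [rid for rid, _ in items]
    seqs = [seq for _, seq in items]
    n = len(items)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _kmer_distance(seqs[i], seqs[j])
    z = linkage(squareform(dmat, checks=False), method="average")
    root = to_tree(z)

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        li, lr = merge(node.left)
        ri, rr = merge(node.right)
        la, lb, _ = _align_profiles(lr, rr, scoring)
        return li + ri, la + lb

    order, rows = merge(root)
    by_index = dict(zip(order, rows))
    return MultipleAlignment(
        ids=ids,
        rows=[by_index[i] for i in range(n)],
        reference_id=reference_id or ids[0],
    )


def strip_gap_columns(msa: MultipleAlignment, also_strip: str = "X") -> MultipleAlignment:
    """Complete deletion: keep only columns with no gap (and, by default, no
    ambiguous 'X') in any row."""
    drop = set(GAP + also_strip)
    keep = [
        i
        for i in range(msa.n_columns)
        if all(r[i] not in drop for r in msa.rows)
    ]
    if not keep:
        raise AlignmentError("complete deletion removed every column")
    return MultipleAlignment(
        ids=list(msa.ids),
        rows=["".join(r[i] for i in keep) for r in msa.rows],
        reference_id=msa.reference_id,
    )


def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identical residues over columns where neither row is gapped."""
    if len(row_a) != len(row_b):
        raise AlignmentError("rows have different lengths")
    compared = matches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x == y:
            matches += 1
    if compared == 0:
        raise AlignmentError("no comparable (mutually ungapped) columns")
    return 100.0 * matches / compared
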