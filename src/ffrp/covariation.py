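"""Mutual information between columns of a protein multiple alignment.

Co-varying positions in the DNA-binding domain of a transcription-factor
family are detected as column pairs with high mutual information

    MI(a, b) = sum_{i,j} p_ij log2( p_ij / (p_i q_j) )

computed from empirical symbol frequencies among rows that are non-gap at
both columns.  MI is reported in bits; no APC or entropy normalization is
applied — raw MI plus per-column occupancy is returned so callers can filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAP = "-"


class AlignmentError(ValueError):
    pass


class UndefinedMIError(AlignmentError):
    """Joint occupancy too small to estimate MI."""


@dataclass
class ProteinAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise AlignmentError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, a: int) -> list[str]:
        """Column a (1-based)."""
        return [r[a - 1] for r in self.rows]

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        from .io_formats import read_fasta, SequenceRecord  # noqa: F401
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)


@dataclass
class MutualInformationMatrix:
    """Symmetric matrix of column-pair MI in bits; diagonal is per-column
    entropy.  Pairs below the occupancy cutoff are NaN."""

    values: np.ndarray
    column_occupancy: np.ndarray


def _joint_counts(col_a: list[str], col_b: list[str], gap_as_symbol: bool):
    pairs = [
        (x, y)
        for x, y in zip(col_a, col_b)
        if gap_as_symbol or (x != GAP and y != GAP)
    ]
    return pairs


def column_mi(
    alignment: ProteinAlignment, a: int, b: int, gap_as_symbol: bool = False
) -> float:
    """MI between columns a and b (1-based) in bits.

    Gaps are excluded pairwise by default: only rows non-gap at both columns
    enter the contingency table.  With gap_as_symbol=True the gap character
    is treated as a 21st symbol instead.
    """
    n_cols = alignment.n_columns
    if not (1 <= a <= n_cols and 1 <= b <= n_cols):
        raise AlignmentError(f"column index out of range: {a}, {b}")
    pairs = _joint_counts(alignment.column(a), alignment.column(b), gap_as_symbol)
    if len(pairs) < 2:
        raise UndefinedMIError(
            f"columns {a},{b}: joint occupancy {len(pairs)} < 2"
        )
    n = len(pairs)
    joint: dict[tuple[str, str], int] = {}
    pa: dict[str, int] = {}
    pb: dict[str, int] = {}
    for x, y in pairs:
        joint[(x, y)] = joint.get((x, y), 0) + 1
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in joint.items():
        p_xy = c / n
        mi += p_xy * np.log2(p_xy / ((pa[x] / n) * (pb[y] / n)))
    return max(mi, 0.0)


def column_entropy(alignment: ProteinAlignment, a: int, gap_as_symbol: bool = False) -> float:
    col = alignment.column(a)
    symbols = [x for x in col if gap_as_symbol or x != GAP]
    if not symbols:
        return 0.0
    n = len(symbols)
    counts: dict[str, int] = {}
    for x in symbols:
        counts[x] = counts.get(x, 0) + 1
    return float(-sum((c / n) * np.log2(c / n) for c in counts.values()))


def mi_matrix(
    alignment: ProteinAlignment,
    min_occupancy: float = 0.0,
    gap_as_symbol: bool = False,
) -> MutualInformationMatrix:
    """All-pairs column MI.  Pairs where either column's non-gap occupancy is
    below min_occupancy are left NaN; the diagonal carries column entropy."""
    if not (0.0 <= min_occupancy <= 1.0):
        raise AlignmentError("min_occupancy must lie in [0, 1]")
    L = alignment.n_columns
    n = alignment.n_sequences
    occ = np.array(
        [sum(1 for x in alignment.column(a) if x != GAP) / n for a in range(1, L + 1)]
    )
    values = np.full((L, L), np.nan)
    for a in range(1, L + 1):
        values[a - 1, a - 1] = column_entropy(alignment, a, gap_as_symbol)
    for a in range(1, L + 1):
        if occ[a - 1] < min_occupancy:
            continue
        for b in range(a + 1, L + 1):
            if occ[b - 1] < min_occupancy:
                continue
            try:
                v = column_mi(alignment, a, b, gap_as_symbol)
            except UndefinedMIError:
                continue
            values[a - 1, b - 1] = values[b - 1, a - 1] = v
    return MutualInformationMatrix(values=values, column_occupancy=occ)


def top_covarying_positions(mi: MutualInformationMatrix, k: int) -> list[tuple[int, int, float]]:
    """The k highest-MI column pairs (a < b, 1-based), descending MI with
    ties broken by (a, b) lexicographic order.  If fewer than k pairs were
    computed, all are returned."""
    if k < 1:
        raise AlignmentError("k must be >= 1")
    L = mi.values.shape[0]
    pairs = [
        (a + 1, b + 1, float(mi.values[a, b]))
        for a in range(L)
        for b in range(a + 1, L)
        if np.isfinite(mi.values[a, b])
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs[:k]
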