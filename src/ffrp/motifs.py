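"""PWM algebra: information content, log-odds scanning with exact p-values,
motif comparison, and multiple-testing adjustment.

The scanner mirrors FIMO's contract: both strands of each sequence are scored
with the motif's log-odds matrix against a background model, and each window's
p-value Pr(score >= s | background) is computed exactly by dynamic programming
over a discretized score lattice.  Motif comparison mirrors TOMTOM's contract
(best gapless column alignment over offsets and orientations, Pearson or
Euclidean column distance) but uses a permutation column-shuffle null rather
than TOMTOM's analytic null, so p-values are rank-faithful, not p-identical,
to TOMTOM.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: complement of base index i is 3 - i under the A,C,G,T ordering
_COMPLEMENT_AXIS = slice(None, None, -1)


class MotifError(ValueError):
    """Invalid motif or background model."""


@dataclass
class Motif:
    """Position weight matrix over (A, C, G, T) with provenance.

    probs has shape (4, W); each column sums to 1.
    provenance is one of {"predicted", "refined", "measured", "discovered"}.
    """

    name: str
    probs: np.ndarray
    provenance: str = "predicted"
    source_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise MotifError(f"motif {self.name!r}: probs must be 4 x W")
        if self.probs.shape[1] < 1:
            raise MotifError(f"motif {self.name!r}: zero width")
        if np.any(self.probs < -1e-12):
            raise MotifError(f"motif {self.name!r}: negative probabilities")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise MotifError(
                f"motif {self.name!r}: column {bad + 1} sums to {sums[bad]:.6f}, not 1"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def reverse_complement(self) -> "Motif":
        return Motif(
            name=self.name + "_rc",
            probs=self.probs[_COMPLEMENT_AXIS, ::-1].copy(),
            provenance=self.provenance,
            source_params=dict(self.source_params),
        )

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    def with_pseudocount(self, pseudocount: float) -> "Motif":
        p = self.probs + pseudocount
        return dataclasses.replace(self, probs=p / p.sum(axis=0, keepdims=True))


@dataclass
class BackgroundModel:
    """Order-0 or order-1 Markov background over A,C,G,T."""

    order: int = 0
    p0: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p0.shape != (4,) or abs(self.p0.sum() - 1.0) > 1e-6 or np.any(self.p0 < 0):
            raise MotifError("background p0 must be a distribution over 4 bases")
        if self.order not in (0, 1):
            raise MotifError("background order must be 0 or 1")
        if self.order == 1:
            if self.transition is None:
                raise MotifError("order-1 background requires a transition matrix")
            self.transition = np.asarray(self.transition, dtype=float)
            if self.transition.shape != (4, 4) or np.any(
                np.abs(self.transition.sum(axis=1) - 1.0) > 1e-6
            ):
                raise MotifError("transition rows must be stochastic")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def from_sequences(cls, sequences, order: int = 0) -> "BackgroundModel":
        """Empirical background from iterable of A/C/G/T/N strings."""
        counts0 = np.ones(4)  # +1 smoothing
        counts1 = np.ones((4, 4))
        for seq in sequences:
            idx = encode(seq)
            valid = idx >= 0
            np.add.at(counts0, idx[valid], 1)
            if order == 1 and len(idx) > 1:
                a, b = idx[:-1], idx[1:]
                ok = (a >= 0) & (b >= 0)
                np.add.at(counts1, (a[ok], b[ok]), 1)
        p0 = counts0 / counts0.sum()
        if order == 0:
            return cls(order=0, p0=p0)
        return cls(order=1, p0=p0, transition=counts1 / counts1.sum(axis=1, keepdims=True))


@dataclass
class MotifHit:
    """One scanner match.  start is 1-based on the forward strand; for
    minus-strand hits matched_sequence is the reverse complement of the
    genomic window (motif orientation)."""

    sequence_id: str
    start: int
    strand: str
    matched_sequence: str
    log_odds_score: float
    p_value: float


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T to 0..3; anything else (incl. N) to -1."""
    table = np.full(256, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def information_content(motif: Motif, background: BackgroundModel | None = None):
    """Per-column and total information content in bits.

    IC_col = sum_b p log2(p/q) with the convention 0*log(0) = 0.
    """
    if background is None:
        background = BackgroundModel.uniform()
    q = background.p0[:, None]
    p = motif.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    per_column = terms.sum(axis=0)
    return per_column, float(per_column.sum())


class ScoreDistribution:
    """Exact null distribution of the integer-lattice log-odds score of a
    motif under an order-0 or order-1 background, built by column-wise DP.

    Scores are discretized to bins of width ``delta`` (default 1e-4 bits);
    the same lattice is used to score windows, so window p-values are exact
    at that resolution.  Motif cells with zero probability score -inf and
    their null mass can never reach a finite threshold; that mass is dropped
    from the lattice (tracked as ``impossible_mass``).
    """

    def __init__(self, motif: Motif, background: BackgroundModel, delta: float = 1e-4):
        self.delta = float(delta)
        self.width = motif.width
        q0 = background.p0
        with np.errstate(divide="ignore"):
            lodds = np.log2(motif.probs / q0[:, None])
        self.finite = np.isfinite(lodds)
        self.int_scores = np.zeros_like(lodds, dtype=np.int64)
        self.int_scores[self.finite] = np.rint(lodds[self.finite] / self.delta).astype(
            np.int64
        )
        self.lodds = lodds

        col_min = np.where(self.finite, self.int_scores, np.iinfo(np.int64).max).min(axis=0)
        col_max = np.where(self.finite, self.int_scores, np.iinfo(np.int64).min).max(axis=0)
        if np.any(~self.finite.any(axis=0)):
            raise MotifError("motif has a column with no finite log-odds score")
        self.min_score = int(col_min.sum())
        self.max_score = int(col_max.sum())
        size = self.max_score - self.min_score + 1

        if background.order == 0:
            pmf = np.zeros(1)
            pmf[0] = 1.0
            offset = 0  # pmf[i] = Pr(score == offset + i + min achievable so far)
            lo = 0
            for j in range(self.width):
                new = np.zeros(len(pmf) + int(col_max[j] - col_min[j]))
                for b in range(4):
                    if not self.finite[b, j]:
                        continue
                    sh = int(self.int_scores[b, j] - col_min[j])
                    new[sh : sh + len(pmf)] += q0[b] * pmf
                pmf = new
                lo += int(col_min[j])
            full = np.zeros(size)
            full[lo - self.min_score : lo - self.min_score + len(pmf)] = pmf
        else:
            # DP state = last emitted base; column 1 from p0, rest from the chain
            T = background.transition
            cur = [np.zeros(1) for _ in range(4)]
            lo = 0
            for j in range(self.width):
                span = int(col_max[j] - col_min[j])
                new = [np.zeros(len(cur[0]) + span) for _ in range(4)]
                for b in range(4):
                    if not self.finite[b, j]:
                        continue
                    sh = int(self.int_scores[b, j] - col_min[j])
                    if j == 0:
                        new[b][sh] = background.p0[b]
                    else:
                        for prev_b in range(4):
                            new[b][sh : sh + len(cur[prev_b])] += T[prev_b, b] * cur[prev_b]
                cur = new
                lo += int(col_min[j])
            pmf = np.sum(cur, axis=0)
            full = np.zeros(size)
            full[lo - self.min_score : lo - self.min_score + len(pmf)] = pmf

        self.pmf = full
        self.impossible_mass = float(1.0 - full.sum())
        # survival: tail[i] = Pr(score >= min_score + i)
        self.tail = np.cumsum(full[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        """Pr(score >= int_score) on the lattice.  Any achievable window
        score is >= min_score, so the index is clamped from below."""
        if int_score > self.max_score:
            return 0.0
        return float(self.tail[max(0, int_score - self.min_score)])

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is <= p_threshold."""
        idx = np.searchsorted(-self.tail, -p_threshold, side="left")
        return self.min_score + int(idx)


def _scan_one_orientation(seq_idx, motif_dist: ScoreDistribution, p_threshold):
    """Return (starts0, int_scores, real_scores, pvalues) of passing windows."""
    W = motif_dist.width
    L = len(seq_idx)
    if L < W:
        return np.array([], dtype=int), None, None, None
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, W)
    valid = (windows >= 0).all(axis=1)
    # zero-probability motif cells make a window score -inf: exclude
    cols = np.arange(W)
    int_table = np.where(motif_dist.finite, motif_dist.int_scores, np.int64(-(2**40)))
    int_scores = int_table[np.clip(windows, 0, 3), cols].sum(axis=1)
    finite_ok = int_scores > -(2**39)
    keep = valid & finite_ok
    if not np.any(keep):
        return np.array([], dtype=int), None, None, None
    idx = np.nonzero(keep)[0]
    iscores = int_scores[idx]
    pvals = motif_dist.tail[
        np.clip(iscores - motif_dist.min_score, 0, len(motif_dist.tail) - 1)
    ]
    pass_mask = pvals <= p_threshold
    idx = idx[pass_mask]
    iscores = iscores[pass_mask]
    pvals = pvals[pass_mask]
    real = motif_dist.lodds[np.clip(windows[idx], 0, 3), cols].sum(axis=1)
    return idx, iscores, real, pvals


def scan(
    sequences,
    motif: Motif,
    background: BackgroundModel | None = None,
    p_threshold: float = 1e-4,
    delta: float = 1e-4,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan sequences for motif occurrences with exact p-values.

    sequences: iterable of objects with .id and .sequence, or (id, seq) pairs.
    Windows containing N (or a zero-probability motif cell) are skipped.
    Hits with p <= p_threshold are returned sorted by (sequence_id, start,
    strand).
    """
    if background is None:
        background = BackgroundModel.uniform()
    if not (0 < p_threshold < 1):
        raise MotifError("p_threshold must be in (0, 1)")
    fwd = ScoreDistribution(motif, background, delta)
    rc = ScoreDistribution(motif.reverse_complement(), background, delta) if both_strands else None

    hits: list[MotifHit] = []
    n_short = 0
    for rec in sequences:
        if hasattr(rec, "id"):
            sid, seq = rec.id, rec.sequence
        else:
            sid, seq = rec
        if len(seq) < motif.width:
            n_short += 1
            continue
        idx = encode(seq)
        starts, _, reals, ps = _scan_one_orientation(idx, fwd, p_threshold)
        for s0, r, p in zip(starts, reals if reals is not None else [], ps if ps is not None else []):
            hits.append(
                MotifHit(sid, int(s0) + 1, "+", seq[s0 : s0 + motif.width].upper(), float(r), float(p))
            )
        if both_strands:
            starts, _, reals, ps = _scan_one_orientation(idx, rc, p_threshold)
            for s0, r, p in zip(
                starts, reals if reals is not None else [], ps if ps is not None else []
            ):
                hits.append(
                    MotifHit(
                        sid,
                        int(s0) + 1,
                        "-",
                        revcomp(seq[s0 : s0 + motif.width].upper()),
                        float(r),
                        float(p),
                    )
                )
    if n_short:
        logger.info("scan: %d sequences shorter than motif width skipped", n_short)
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# motif comparison


@dataclass
class MotifComparison:
    query: str
    target: str
    best_offset: int
    orientation: str
    pearson_distance: float
    euclidean_distance: float
    p_value: float | None = None
    adjusted_p: float | None = None
    overlap: int = 0


def _column_distance_matrix(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Pairwise distances between columns of two 4 x W matrices.

    Pearson: 1 - r between the two 4-vectors; Euclidean: L2 norm.
    Returns shape (Wa, Wb).
    """
    A = a.T  # (Wa, 4)
    B = b.T
    if method == "euclidean":
        diff = A[:, None, :] - B[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if method == "pearson":
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(Ac, axis=1)
        nb = np.linalg.norm(Bc, axis=1)
        num = Ac @ Bc.T
        denom = np.outer(na, nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        return 1.0 - r
    raise MotifError(f"unknown distance method {method!r}")


def _alignments(wq: int, wt: int, min_overlap: int):
    """Yield (offset, q_cols, t_cols): offset = position of query col 1
    relative to target col 1 (0 means aligned starts)."""
    for offset in range(-(wq - min_overlap), wt - min_overlap + 1):
        q_lo = max(0, -offset)
        t_lo = max(0, offset)
        n = min(wq - q_lo, wt - t_lo)
        if n >= min_overlap:
            yield offset, np.arange(q_lo, q_lo + n), np.arange(t_lo, t_lo + n)


def _best_alignment(qp: np.ndarray, tp: np.ndarray, method: str, min_overlap: int):
    """Minimal mean column distance over offsets and target orientations."""
    best = None
    for orient, tmat in (("+", tp), ("-", tp[_COMPLEMENT_AXIS, ::-1])):
        D = _column_distance_matrix(qp, tmat, method)
        for offset, qc, tc in _alignments(qp.shape[1], tp.shape[1], min_overlap):
            d = float(D[qc, tc].mean())
            key = (d, offset, orient)
            if best is None or key < best:
                best = key
    if best is None:
        raise MotifError("no alignment satisfies min_overlap")
    return best  # (distance, offset, orientation)


def compare_motifs(
    query: Motif,
    target: Motif,
    method: str = "pearson",
    min_overlap: int = 4,
    n_permutations: int = 0,
    universe: list[Motif] | None = None,
    seed: int = 0,
) -> MotifComparison:
    """Best gapless alignment of two PWMs over offsets and orientations.

    With n_permutations > 0, an empirical p-value is computed against a null
    of random query motifs assembled from columns pooled over ``universe``
    (default: the two motifs being compared): p = (1 + #{d_null <= d_obs}) /
    (n_permutations + 1).
    """
    if min_overlap < 1 or min(query.width, target.width) < min_overlap:
        raise MotifError("min_overlap larger than a motif width")
    d_obs, offset, orient = _best_alignment(query.probs, target.probs, method, min_overlap)
    d_pe = _best_alignment(query.probs, target.probs, "pearson", min_overlap)[0]
    d_eu = _best_alignment(query.probs, target.probs, "euclidean", min_overlap)[0]
    overlap = min(query.width, target.width)
    cmp = MotifComparison(
        query=query.name,
        target=target.name,
        best_offset=offset,
        orientation=orient,
        pearson_distance=d_pe,
        euclidean_distance=d_eu,
        overlap=overlap,
    )
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pool_motifs = universe if universe is not None else [query, target]
        pool = np.concatenate([m.probs for m in pool_motifs], axis=1)  # (4, P)
        P = pool.shape[1]
        wq = query.width
        draws = rng.integers(0, P, size=(n_permutations, wq))
        # distances between every pool column and target columns, both orients
        best_null = np.full(n_permutations, np.inf)
        for tmat in (target.probs, target.probs[_COMPLEMENT_AXIS, ::-1]):
            D = _column_distance_matrix(pool, tmat, method)  # (P, Wt)
            for _, qc, tc in _alignments(wq, target.width, min_overlap):
                d = D[draws[:, qc], tc].mean(axis=1)
                np.minimum(best_null, d, out=best_null)
        cmp.p_value = float((1 + np.sum(best_null <= d_obs)) / (n_permutations + 1))
    return cmp


def reciprocal_mean_pvalue(
    a: Motif, b: Motif, method: str = "pearson", min_overlap: int = 4,
    n_permutations: int = 10000, universe: list[Motif] | None = None, seed: int = 0,
) -> float:
    """Mean of p(a->b) and p(b->a), restoring symmetry of the permutation p."""
    p_ab = compare_motifs(a, b, method, min_overlap, n_permutations, universe, seed).p_value
    p_ba = compare_motifs(b, a, method, min_overlap, n_permutations, universe, seed + 1).p_value
    return 0.5 * (p_ab + p_ba)


def adjust_pvalues(p_list, method: str = "fdr_bh"):
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise MotifError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def motif_distance_matrix(
    motifs: list[Motif], method: str = "euclidean", min_overlap: int = 4
) -> np.ndarray:
    """Symmetric matrix of pairwise best-alignment distances; diagonal 0."""
    if len(motifs) < 2:
        raise MotifError("need at least two motifs")
    n = len(motifs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _best_alignment(motifs[i].probs, motifs[j].probs, method, min_overlap)[0]
            D[i, j] = D[j, i] = d
    return D
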