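"""Regulon inference: ChIP target rules, PWM-based regulons, iterative PWM
refinement against bound promoters, and hypergeometric overlap statistics.

The refinement procedure adapts a seed PWM to the binding-site sequences
actually occurring in the promoters of putatively regulated genes: at each
iteration the target promoters are scanned with increasing stringency
(p-value threshold decreasing linearly from 5e-4 to 1e-4), the hits are
turned into an empirical frequency matrix M, and the working matrix is
updated as the columnwise convex combination

    M_next = (1 - w) * M_current + w * M_empirical

with w increasing linearly from 0.25 to 0.75 over the iterations.  The mix
is always against the current matrix (not the original seed), and an
iteration with zero hits leaves the matrix unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .comparative import PromoterSet
from .io_formats import ChIPPeakTable, GeneAnnotation
from .motifs import BASES, BackgroundModel, Motif, MotifHit, scan

logger = logging.getLogger(__name__)


class RegulonError(ValueError):
    pass


@dataclass
class TargetSet:
    """Genes whose promoter carries a ChIP peak with p < p_max within
    window_bp upstream of the reference point (TSS, falling back to the
    strand-aware CDS start)."""

    tf_id: str
    gene_ids: set[str]
    evidence: dict[str, list[tuple[int, int]]]  # gene -> [(peak position, distance)]
    p_max: float = 0.10
    window_bp: int = 100


@dataclass
class RegulonPrediction:
    tf_id: str
    motif: Motif
    hits_by_gene: dict[str, list[MotifHit]]
    gene_ids: set[str]
    scan_params: dict = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    k: int  # overlap
    K: int  # |set_a|
    n: int  # |set_b|
    N: int  # universe size
    p_value: float


@dataclass
class RefinementIteration:
    iteration: int
    w: float
    p_threshold: float
    n_hits: int
    empirical: np.ndarray | None
    mixed: np.ndarray


@dataclass
class RefinementTrace:
    seed_motif: Motif
    iterations: list[RefinementIteration]
    final_motif: Motif
    failed: bool = False


def chip_targets(
    peaks: ChIPPeakTable,
    annotations: list[GeneAnnotation],
    tf_id: str = "tf",
    p_max: float = 0.10,
    window_bp: int = 100,
) -> TargetSet:
    """Apply the ChIP target rule: a gene is a binding target iff some peak
    with p-value < p_max lies within window_bp upstream of its reference
    point (distance 0..window_bp inclusive, strand-aware; downstream peaks
    do not count).  One peak may serve several genes (divergent promoters).
    """
    if window_bp < 0:
        raise RegulonError("window_bp must be >= 0")
    sig = peaks.df[peaks.df.p_value < p_max]
    gene_ids: set[str] = set()
    evidence: dict[str, list[tuple[int, int]]] = {}
    for g in annotations:
        ref = g.reference_point
        rows = sig[sig.chrom == g.chrom]
        if g.strand == "+":
            dist = ref - rows.position
        else:
            dist = rows.position - ref
        ok = rows[(dist >= 0) & (dist <= window_bp)]
        if len(ok):
            gene_ids.add(g.gene_id)
            d = dist[ok.index]
            evidence[g.gene_id] = list(
                zip(ok.position.astype(int).tolist(), d.astype(int).tolist())
            )
    return TargetSet(
        tf_id=tf_id, gene_ids=gene_ids, evidence=evidence, p_max=p_max, window_bp=window_bp
    )


def pwm_regulon(
    motif: Motif,
    promoter_set: PromoterSet,
    background: BackgroundModel | None = None,
    p_threshold: float = 1e-4,
    tf_id: str = "tf",
) -> RegulonPrediction:
    """Scan every promoter with the motif; genes with at least one hit at
    p <= p_threshold form the predicted regulon."""
    usable = [e for e in promoter_set.entries if len(e.sequence) >= motif.width]
    if len(usable) < len(promoter_set.entries):
        logger.warning(
            "pwm_regulon: %d promoters shorter than motif width skipped",
            len(promoter_set.entries) - len(usable),
        )
    hits = scan(
        [(e.gene_id, e.sequence) for e in usable],
        motif,
        background=background,
        p_threshold=p_threshold,
    )
    by_gene: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_gene.setdefault(h.sequence_id, []).append(h)
    return RegulonPrediction(
        tf_id=tf_id,
        motif=motif,
        hits_by_gene=by_gene,
        gene_ids=set(by_gene),
        scan_params={"p_threshold": p_threshold, "motif": motif.name},
    )


def hypergeometric_enrichment(set_a, set_b, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= k) for the overlap of two gene sets
    within a universe."""
    universe = set(universe)
    if not universe:
        raise RegulonError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return EnrichmentResult(k=k, K=len(a), n=len(b), N=len(universe), p_value=min(p, 1.0))


def build_count_matrix(hits: list[MotifHit], width: int, as_frequencies: bool = True) -> np.ndarray:
    """Per-column base counts over hit sequences.  Scanner hits already carry
    the matched sequence in motif orientation (minus-strand matches are
    reverse-complemented at scan time), so counting is direct."""
    if not hits:
        raise RegulonError("no hits to build a count matrix from")
    counts = np.zeros((4, width))
    for h in hits:
        if len(h.matched_sequence) != width:
            raise RegulonError(
                f"hit {h.sequence_id}:{h.start} has width {len(h.matched_sequence)}, "
                f"expected {width}"
            )
        for j, ch in enumerate(h.matched_sequence):
            counts[BASES.index(ch), j] += 1.0
    if as_frequencies:
        return counts / counts.sum(axis=0, keepdims=True)
    return counts


def refine_motif(
    seed_motif: Motif,
    promoter_set: PromoterSet,
    target_filter: set[str] | None = None,
    n_iter: int = 5,
    w_range: tuple[float, float] = (0.25, 0.75),
    p_range: tuple[float, float] = (5e-4, 1e-4),
    background: BackgroundModel | None = None,
    log_spaced_thresholds: bool = False,
) -> RefinementTrace:
    """Iteratively adapt a seed PWM to binding-site sequences in target
    promoters (e.g. ChIP-bound and/or co-expressed genes).

    Per iteration i in 1..n_iter: w_i and the scan threshold alpha_i are
    linearly interpolated across their ranges; target promoters are scanned
    at alpha_i; the empirical frequency matrix of the hits is mixed into the
    current matrix with weight w_i.  Zero-hit iterations skip the update
    (logged); if every iteration has zero hits the seed is returned with the
    failure flag set.
    """
    if n_iter < 2:
        raise RegulonError("n_iter must be >= 2")
    entries = promoter_set.entries
    if target_filter is not None:
        entries = [e for e in entries if e.gene_id in target_filter]
    sub = PromoterSet(entries=entries, window_spec=promoter_set.window_spec)
    ws = np.linspace(w_range[0], w_range[1], n_iter)
    if log_spaced_thresholds:
        alphas = np.exp(np.linspace(np.log(p_range[0]), np.log(p_range[1]), n_iter))
    else:
        alphas = np.linspace(p_range[0], p_range[1], n_iter)
    W = seed_motif.width
    current = seed_motif.probs.copy()
    iterations: list[RefinementIteration] = []
    any_hits = False
    for i in range(n_iter):
        motif_i = Motif(name=f"{seed_motif.name}_iter{i + 1}", probs=current)
        hits = scan(
            [(e.gene_id, e.sequence) for e in sub.entries if len(e.sequence) >= W],
            motif_i,
            background=background,
            p_threshold=float(alphas[i]),
        )
        if hits:
            any_hits = True
            M = build_count_matrix(hits, W)
            current = (1.0 - ws[i]) * current + ws[i] * M
            current = current / current.sum(axis=0, keepdims=True)
        else:
            M = None
            logger.info("refine iteration %d: zero hits; matrix unchanged", i + 1)
        iterations.append(
            RefinementIteration(
                iteration=i + 1,
                w=float(ws[i]),
                p_threshold=float(alphas[i]),
                n_hits=len(hits),
                empirical=M,
                mixed=current.copy(),
            )
        )
    final = Motif(
        name=seed_motif.name + "_refined",
        probs=current,
        provenance="refined",
        source_params={
            "seed_motif": seed_motif.name,
            "n_iter": n_iter,
            "w_range": list(w_range),
            "p_range": list(p_range),
        },
    )
    return RefinementTrace(
        seed_motif=seed_motif, iterations=iterations, final_motif=final, failed=not any_hits
    )


def regulon_network(
    tf_list: list[str],
    regulons: dict[str, RegulonPrediction],
    target_sets: dict[str, TargetSet],
) -> pd.DataFrame:
    """TF -> gene edge table labelled by support: pwm_only (motif hit only),
    chip_only (ChIP target only), or pwm+chip (both)."""
    rows = []
    for tf in tf_list:
        pwm_genes = regulons[tf].gene_ids if tf in regulons else set()
        chip_genes = target_sets[tf].gene_ids if tf in target_sets else set()
        for gene in sorted(pwm_genes | chip_genes):
            if gene in pwm_genes and gene in chip_genes:
                support = "pwm+chip"
            elif gene in pwm_genes:
                support = "pwm_only"
            else:
                support = "chip_only"
            rows.append({"tf": tf, "gene": gene, "support": support})
    return pd.DataFrame(rows, columns=["tf", "gene", "support"])


def network_summary(edges: pd.DataFrame) -> pd.DataFrame:
    if edges.empty:
        return pd.DataFrame(columns=["tf", "pwm_only", "chip_only", "pwm+chip", "total"])
    counts = edges.pivot_table(
        index="tf", columns="support", values="gene", aggfunc="count", fill_value=0
    )
    for col in ("pwm_only", "chip_only", "pwm+chip"):
        if col not in counts:
            counts[col] = 0
    counts["total"] = counts[["pwm_only", "chip_only", "pwm+chip"]].sum(axis=1)
    return counts.reset_index()[["tf", "pwm_only", "chip_only", "pwm+chip", "total"]]
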