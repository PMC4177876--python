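"""Reciprocal-best-hit orthology and strand-aware promoter extraction.

Orthologs between two proteomes are reciprocal best hits passing three
filters, each applied in both directions: query length >= 50 aa, contiguous
alignment coverage >= 70% of the full-length query, and sequence identity
>= 50%.  "Contiguous coverage" is the span of a single local alignment on
the query divided by the full query length (summed HSPs do not count).

Two scoring engines are supported: an internal affine-gap local aligner
(BLOSUM62; for test-scale proteomes) and import of external tabular hit
files (BLAST outfmt-6-like TSV) for real proteomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneAnnotation, SequenceRecord
from .motifs import revcomp

logger = logging.getLogger(__name__)


class ComparativeError(ValueError):
    pass


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    percent_identity: float  # 0..100
    alignment_length: int  # aligned columns (aa)
    query_coverage: float  # contiguous aligned span / full query length
    bit_score: float
    query_length: int = 0
    tied_best: bool = False  # another subject reached the same best score


@dataclass
class RBHFilters:
    min_len: int = 50  # aa, full-length query
    min_coverage: float = 0.70
    min_identity: float = 0.50  # fraction


@dataclass
class OrthologTable:
    pairs: list[tuple[str, str, str, str]]  # (species_a, gene_a, species_b, gene_b)
    filter_params: RBHFilters = field(default_factory=RBHFilters)

    def partners_of(self, gene: str) -> list[tuple[str, str]]:
        out = []
        for sa, ga, sb, gb in self.pairs:
            if ga == gene:
                out.append((sb, gb))
            elif gb == gene:
                out.append((sa, ga))
        return out


@dataclass
class WindowSpec:
    """Promoter window relative to a reference point, in gene orientation.

    upstream_bp bases 5' of the reference and downstream_bp bases starting
    at it; e.g. (-250, +50) is WindowSpec(250, 50).  reference is
    "CDS_start" or "TSS" (TSS falls back to CDS start when absent).
    """

    upstream_bp: int
    downstream_bp: int = 0
    reference: str = "CDS_start"

    def __post_init__(self) -> None:
        if self.upstream_bp < 0:
            raise ComparativeError("upstream_bp must be >= 0")
        if self.reference not in ("CDS_start", "TSS"):
            raise ComparativeError("reference must be CDS_start or TSS")


@dataclass
class PromoterEntry:
    gene_id: str
    species: str
    chrom: str
    start: int  # genomic 1-based inclusive
    end: int
    strand: str
    sequence: str  # strand-corrected: position -1 abuts the reference point
    truncated: bool = False


@dataclass
class PromoterSet:
    entries: list[PromoterEntry]
    window_spec: WindowSpec

    def by_gene(self) -> dict[str, PromoterEntry]:
        return {e.gene_id: e for e in self.entries}

    def sequences(self) -> list[SequenceRecord]:
        return [SequenceRecord(e.gene_id, e.sequence) for e in self.entries]


# ---------------------------------------------------------------------------
# pairwise hits


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def _align_pair(query: SequenceRecord, subject: SequenceRecord) -> AlignmentHit | None:
    aligner = _get_aligner()
    alns = aligner.align(query.sequence, subject.sequence)
    try:
        aln = alns[0]
    except IndexError:
        return None
    score = float(alns.score)
    if score <= 0:
        return None
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / length if length else 0.0
    q_blocks = aln.aligned[0]
    span = int(q_blocks[-1][1] - q_blocks[0][0]) if len(q_blocks) else 0
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        percent_identity=identity,
        alignment_length=int(length),
        query_coverage=span / len(query.sequence),
        bit_score=score,
        query_length=len(query.sequence),
    )


def pairwise_hits(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    mode: str = "internal",
) -> list[AlignmentHit]:
    """Best hit in proteome_b for every query in proteome_a, by bit score
    (ties broken by subject id, lexicographic).  Internal mode uses the
    affine-gap local aligner; for external hit tables use
    import_tabular_hits()."""
    if mode != "internal":
        raise ComparativeError("use import_tabular_hits() for external hit tables")
    if not proteome_a or not proteome_b:
        raise ComparativeError("empty proteome")
    hits = []
    for q in proteome_a:
        best: AlignmentHit | None = None
        for s in proteome_b:
            h = _align_pair(q, s)
            if h is None:
                continue
            if best is not None and h.bit_score == best.bit_score:
                best.tied_best = True
                if h.subject_id < best.subject_id:
                    h.tied_best = True
                    best = h
            elif best is None or h.bit_score > best.bit_score:
                best = h
        if best is not None:
            hits.append(best)
    return hits


def import_tabular_hits(
    path,
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
) -> list[AlignmentHit]:
    """Read a BLAST outfmt-6-like 12-column TSV (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore) and reduce to
    best hit per query.  Query lengths/coverage come from proteome_a."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    if df.isna().any().any():
        raise ComparativeError(f"{path}: malformed tabular row")
    qlen = {r.id: len(r.sequence) for r in proteome_a}
    hits: dict[str, AlignmentHit] = {}
    for row in df.itertuples(index=False):
        if row.qseqid not in qlen:
            raise ComparativeError(f"{path}: unknown query id {row.qseqid!r}")
        h = AlignmentHit(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            percent_identity=float(row.pident),
            alignment_length=int(row.length),
            query_coverage=(int(row.qend) - int(row.qstart) + 1) / qlen[row.qseqid],
            bit_score=float(row.bitscore),
            query_length=qlen[row.qseqid],
        )
        cur = hits.get(h.query_id)
        if (
            cur is None
            or h.bit_score > cur.bit_score
            or (h.bit_score == cur.bit_score and h.subject_id < cur.subject_id)
        ):
            hits[h.query_id] = h
    return list(hits.values())


def _passes(h: AlignmentHit, f: RBHFilters) -> bool:
    return (
        h.query_length >= f.min_len
        and h.query_coverage >= f.min_coverage
        and h.percent_identity >= 100.0 * f.min_identity
    )


def reciprocal_best_hits(
    hits_ab: list[AlignmentHit],
    hits_ba: list[AlignmentHit],
    filters: RBHFilters | None = None,
    species_a: str = "a",
    species_b: str = "b",
    all_hits_ab: list[AlignmentHit] | None = None,
) -> OrthologTable:
    """Orthologs as mutual best hits passing the length/coverage/identity
    filters in both directions.  A tie at the best bit score (ambiguous
    orthology) rejects the pair.  hits_ab / hits_ba are best-hit lists as
    produced by pairwise_hits(); pass the full hit lists via all_hits_ab to
    enable tie detection on imported tables carrying multiple HSPs."""
    if filters is None:
        filters = RBHFilters()
    best_ab = {h.query_id: h for h in hits_ab}
    best_ba = {h.query_id: h for h in hits_ba}
    ambiguous: set[str] = set()
    if all_hits_ab:
        by_query: dict[str, list[AlignmentHit]] = {}
        for h in all_hits_ab:
            by_query.setdefault(h.query_id, []).append(h)
        for q, hs in by_query.items():
            top = max(h.bit_score for h in hs)
            if sum(1 for h in hs if h.bit_score == top) > 1:
                ambiguous.add(q)
                logger.info("RBH: query %s has tied best hits; rejected", q)
    pairs = []
    for qa, hab in sorted(best_ab.items()):
        if qa in ambiguous or hab.tied_best:
            continue
        hba = best_ba.get(hab.subject_id)
        if hba is None or hba.subject_id != qa or hba.tied_best:
            continue
        if _passes(hab, filters) and _passes(hba, filters):
            pairs.append((species_a, qa, species_b, hab.subject_id))
    return OrthologTable(pairs=pairs, filter_params=filters)


# ---------------------------------------------------------------------------
# promoter extraction


def extract_promoters(
    genome: list[SequenceRecord],
    annotations: list[GeneAnnotation],
    window_spec: WindowSpec,
    species: str = "",
) -> PromoterSet:
    """Strand-aware promoter windows.

    For a plus-strand gene with reference point s and window (-u, +d) the
    genomic interval is [s-u, s+d-1]; for a minus-strand gene with reference
    point e it is [e-d+1, e+u], reverse complemented, so that position -1 of
    the returned sequence always abuts the reference point.  Windows
    truncated at a contig edge are flagged.
    """
    chroms = {rec.id: rec.sequence for rec in genome}
    u, d = window_spec.upstream_bp, window_spec.downstream_bp
    entries = []
    for g in annotations:
        if g.chrom not in chroms:
            raise ComparativeError(f"gene {g.gene_id!r}: chrom {g.chrom!r} missing")
        seq = chroms[g.chrom]
        if window_spec.reference == "TSS" and g.tss is not None:
            ref = g.tss
        else:
            ref = g.cds_start if g.strand == "+" else g.cds_end
        if g.strand == "+":
            start, end = ref - u, ref + d - 1
        else:
            start, end = ref - d + 1, ref + u
        t_start, t_end = max(1, start), min(len(seq), end)
        truncated = (t_start != start) or (t_end != end)
        sub = seq[t_start - 1 : t_end]
        if g.strand == "-":
            sub = revcomp(sub)
        entries.append(
            PromoterEntry(
                gene_id=g.gene_id,
                species=species,
                chrom=g.chrom,
                start=t_start,
                end=t_end,
                strand=g.strand,
                sequence=sub,
                truncated=truncated,
            )
        )
    return PromoterSet(entries=entries, window_spec=window_spec)


def orthologous_promoter_sets(
    ortholog_tables: list[OrthologTable],
    promoter_sets: dict[str, PromoterSet],
    anchor_species: str,
    anchor_gene: str,
) -> list[SequenceRecord]:
    """Collect the anchor gene's promoter plus its ortholog promoters across
    species as one multi-FASTA-ready record list (inputs suitable for
    external de novo motif discovery).  Returns [] (with a log entry) when
    fewer than 2 members exist."""
    members: list[tuple[str, str]] = [(anchor_species, anchor_gene)]
    for table in ortholog_tables:
        for sa, ga, sb, gb in table.pairs:
            if (sa, ga) == (anchor_species, anchor_gene):
                members.append((sb, gb))
            elif (sb, gb) == (anchor_species, anchor_gene):
                members.append((sa, ga))
    records = []
    for sp, gene in members:
        ps = promoter_sets.get(sp)
        if ps is None:
            continue
        entry = ps.by_gene().get(gene)
        if entry is not None:
            records.append(SequenceRecord(f"{sp}|{gene}", entry.sequence))
    if len(records) < 2:
        logger.info(
            "anchor %s|%s has %d promoter(s); skipped", anchor_species, anchor_gene, len(records)
        )
        return []
    return records


def ortholog_table_to_frame(table: OrthologTable) -> pd.DataFrame:
    return pd.DataFrame(
        table.pairs, columns=["species_a", "gene_a", "species_b", "gene_b"]
    )
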