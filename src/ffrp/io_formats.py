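"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* All internal coordinates are 1-based inclusive (GFF-native).  Conversion to
  0-based half-open happens only at the BED boundary; reading a BED written
  here restores the originals.
* FASTA via Bio.SeqIO with a strict validation layer on top; GFF3 via
  gffutils (in-memory DB); MEME minimal motif text via Bio.motifs plus our
  own consistency checks; TSV tables via pandas.
* Writers emit a header comment line carrying tool version and parameters.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import BASES, BackgroundModel, Motif, MotifHit

TOOL_TAG = "ffrp 0.1.0"

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """Strand-aware gene coordinates, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.cds_end < self.cds_start:
            raise FormatError(
                f"gene {self.gene_id!r}: end {self.cds_end} < start {self.cds_start}"
            )

    @property
    def reference_point(self) -> int:
        """TSS if known, else the strand-aware CDS start coordinate."""
        if self.tss is not None:
            return self.tss
        return self.cds_start if self.strand == "+" else self.cds_end


@dataclass
class ChIPPeakTable:
    """ChIP-chip peaks: columns chrom, position, intensity, p_value, condition."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "position", "intensity", "p_value", "condition"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"peak table missing columns: {missing}")
        if not pd.api.types.is_numeric_dtype(self.df["position"]):
            raise FormatError("peak positions must be numeric")
        bad = self.df[(self.df.p_value < 0) | (self.df.p_value > 1)]
        if len(bad):
            raise FormatError(
                f"peak p_value outside [0,1] at rows {list(bad.index[:5])}"
            )
        self.df = (
            self.df.sort_values(["chrom", "position"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MotifFile:
    motifs: list[Motif]
    background: BackgroundModel = field(default_factory=BackgroundModel.uniform)
    format_version: str = "4"


# ---------------------------------------------------------------------------
# FASTA


def _validate_record(rec: SequenceRecord, alphabet: str, path) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    if not rec.id:
        raise FormatError(f"{path}: record with empty id")
    if not rec.sequence:
        raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
    for off, ch in enumerate(rec.sequence):
        if ch not in allowed:
            raise FormatError(
                f"{path}: record {rec.id!r}: illegal character {ch!r} "
                f"at offset {off} for {alphabet} alphabet"
            )


def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file; sequences are uppercased and validated against the
    declared alphabet.  Raises FormatError naming the record and offset on an
    illegal character, and on duplicate or empty ids."""
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sr = SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
        _validate_record(sr, alphabet, path)
        if sr.id in seen:
            raise FormatError(f"{path}: duplicate record id {sr.id!r}")
        seen.add(sr.id)
        records.append(sr)
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(path, records: list[SequenceRecord], width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (gene features, or CDS where no gene
    feature exists).  Coordinates are kept 1-based inclusive, exactly as in
    the file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneAnnotation] = []
    feature_types = ["gene"] if any(True for _ in db.features_of_type("gene")) else ["CDS"]
    for feat in db.features_of_type(feature_types, order_by=("seqid", "start")):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"{path}: feature at {feat.seqid}:{feat.start} lacks ID")
        if feat.strand not in "+-":
            raise FormatError(f"{path}: feature {ids[0]!r} has unknown strand")
        tss_attr = feat.attributes.get("tss")
        genes.append(
            GeneAnnotation(
                gene_id=ids[0],
                chrom=feat.seqid,
                strand=feat.strand,
                cds_start=feat.start,
                cds_end=feat.end,
                tss=int(tss_attr[0]) if tss_attr else None,
            )
        )
    return genes


def write_gff(path, genes: list[GeneAnnotation], source: str = "ffrp") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#! {TOOL_TAG} gene annotations\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.tss is not None:
                attrs += f";tss={g.tss}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# peak tables


def read_peak_table(path) -> ChIPPeakTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    try:
        df["position"] = pd.to_numeric(df["position"])
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: non-numeric or missing position column") from exc
    return ChIPPeakTable(df)


def write_peak_table(path, table: ChIPPeakTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_TAG} peak table\n")
        table.df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme_motifs(path, motif_file: MotifFile) -> None:
    """Write motifs in MEME minimal text format (version 4)."""
    bg = motif_file.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg.p0[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n"
        )
        for m in motif_file.motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 1000000 E= 0\n"
            )
            for col in m.probs.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def _validate_meme_matrices(text: str, path) -> None:
    """Check raw letter-probability rows before any downstream parser can
    renormalize them: each row must hold 4 probabilities summing to 1 within
    1e-3 and the row count must match the declared width."""
    lines = text.splitlines()
    i = 0
    motif_name = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_name = line.split()[1] if len(line.split()) > 1 else "?"
        if line.startswith("letter-probability matrix"):
            tokens = line.split()
            try:
                w = int(tokens[tokens.index("w=") + 1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: matrix header lacks width: {line}") from exc
            rows = 0
            j = i + 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) != 4:
                    break
                try:
                    vals = [float(x) for x in parts]
                except ValueError:
                    break
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}: motif {motif_name!r} column {rows + 1} sums "
                        f"to {sum(vals):.4f}"
                    )
                rows += 1
                j += 1
            if rows != w:
                raise FormatError(
                    f"{path}: motif {motif_name!r} declares width {w} but has "
                    f"{rows} probability rows"
                )
            i = j
            continue
        i += 1


def read_meme_motifs(path, provenance: str = "discovered") -> MotifFile:
    """Parse MEME minimal text format via Bio.motifs, then validate: every
    probability column must sum to 1 within 1e-3 and row counts must match
    the declared width."""
    with open(path) as fh:
        text = fh.read()
    _validate_meme_matrices(text, path)
    try:
        record = bio_motifs.parse(io.StringIO(text), "minimal")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse MEME minimal format: {exc}") from exc
    bg_counts = getattr(record, "background", None)
    if bg_counts:
        p0 = np.array([bg_counts[b] for b in BASES], dtype=float)
        p0 = p0 / p0.sum()
        background = BackgroundModel(order=0, p0=p0)
    else:
        background = BackgroundModel.uniform()
    out = []
    for m in record:
        w = m.length
        probs = np.array([[m.pwm[b][j] for j in range(w)] for b in BASES])
        sums = probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"{path}: motif {m.name!r} column {bad + 1} sums to {sums[bad]:.4f}"
            )
        probs = probs / sums
        out.append(Motif(name=m.name, probs=probs, provenance=provenance))
    version = getattr(record, "version", "4") or "4"
    return MotifFile(motifs=out, background=background, format_version=str(version))


# ---------------------------------------------------------------------------
# BED6 export of motif hits (0-based half-open at this boundary only)


def write_bed(path, hits: list[MotifHit], width: int, chrom_of=None) -> None:
    """Export hits as BED6.  ``chrom_of`` maps sequence_id -> chrom; default
    uses sequence_id itself.  Score column = round(100 * -log10 p)."""
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_TAG} motif hits (BED6)\n")
        for h in hits:
            chrom = chrom_of(h.sequence_id) if chrom_of else h.sequence_id
            start0 = h.start - 1
            end0 = start0 + width
            score = int(round(min(1000, -100 * np.log10(max(h.p_value, 1e-300)))))
            fh.write(
                f"{chrom}\t{start0}\t{end0}\t{h.matched_sequence}\t{score}\t{h.strand}\n"
            )


def read_bed(path) -> list[tuple]:
    """Read BED6 back as (chrom, start_1based, end_1based_inclusive, name,
    score, strand) — the inverse of write_bed's coordinate conversion."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]) + 1, int(f[2]), f[3], int(f[4]), f[5]))
    return rows


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(path, values: pd.DataFrame, conditions: pd.Series) -> None:
    """Expression TSV dialect: row 1 = array ids, row 2 = condition labels,
    then one row per gene (first column gene id)."""
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_TAG} expression matrix\n")
        fh.write("gene\t" + "\t".join(values.columns) + "\n")
        fh.write("condition\t" + "\t".join(conditions[c] for c in values.columns) + "\n")
        for gene, row in values.iterrows():
            fh.write(gene + "\t" + "\t".join(f"{x:.10g}" for x in row.values) + "\n")


def read_expression(path):
    """Inverse of write_expression; returns (values DataFrame, conditions
    Series indexed by array id)."""
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    cond_row = lines[1].rstrip("\n").split("\t")
    if cond_row[0] != "condition":
        raise FormatError(f"{path}: second row must carry condition labels")
    arrays = header[1:]
    conditions = pd.Series(cond_row[1:], index=arrays)
    data = {}
    for ln in lines[2:]:
        f = ln.rstrip("\n").split("\t")
        data[f[0]] = [float(x) for x in f[1:]]
    values = pd.DataFrame.from_dict(data, orient="index", columns=arrays)
    return values, conditions


# ---------------------------------------------------------------------------
# generic TSV / JSON helpers


def write_tsv(path, df: pd.DataFrame, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TOOL_TAG} {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
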