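"""Fully synthetic worlds with the statistical structure the pipeline
assumes, so every downstream stage is testable without external data.

A world emulates, at desk scale, the data landscape of a halophilic archaeon
with a family of paralogous transcription factors: a genome whose promoters
carry binding sites sampled from per-TF ground-truth PWMs in designated
regulons; ChIP-chip style peak tables concentrated near the planted sites
with configurable sensitivity and false-positive rate; an expression
compendium in which co-operonic and regulon/TF gene pairs share latent
factors (population correlation = the requested rho, decoupled in a
designated stress condition); and a set of divergent ortholog proteomes and
genomes across synthetic species to exercise reciprocal-best-hit filters.

Everything is reproducible: identical seeds give byte-identical outputs,
and every planted site is recoverable by exact string search at its
recorded coordinate and strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import ExpressionMatrix
from .io_formats import (
    ChIPPeakTable,
    GeneAnnotation,
    SequenceRecord,
    write_expression,
    write_fasta,
    write_gff,
    write_meme_motifs,
    write_peak_table,
    MotifFile,
)
from .motifs import BASES, Motif, revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SyntheticDataError(ValueError):
    pass


@dataclass
class PlantedSite:
    tf_id: str
    gene_id: str
    position: int  # 1-based genomic start, forward strand
    strand: str
    sequence: str  # motif orientation


@dataclass
class SpeciesData:
    name: str
    proteome: list[SequenceRecord]
    genome: list[SequenceRecord]
    genes: list[GeneAnnotation]
    fragmented: set[str] = field(default_factory=set)


@dataclass
class SyntheticWorld:
    genome: list[SequenceRecord]
    genes: list[GeneAnnotation]
    promoter_len: int
    rng_seed: int
    truth_pwms: dict[str, Motif] = field(default_factory=dict)
    regulons: dict[str, set[str]] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    peaks: dict[str, ChIPPeakTable] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None
    operon_pairs: list[tuple[str, str]] = field(default_factory=list)
    tf_genes: dict[str, str] = field(default_factory=dict)
    ortho_species: list[SpeciesData] = field(default_factory=list)
    _occupied: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneAnnotation:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def promoter_interval(self, gene: GeneAnnotation) -> tuple[int, int]:
        """Genomic (start, end), 1-based inclusive, of the strand-aware
        promoter window of length promoter_len upstream of the reference
        point."""
        ref = gene.reference_point
        if gene.strand == "+":
            return ref - self.promoter_len, ref - 1
        return ref + 1, ref + self.promoter_len


def _random_dna(n: int, gc: float, rng) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(BASES[i] for i in idx)


def generate_genome(
    n_genes: int,
    promoter_len: int = 250,
    gc_content: float = 0.5,
    seed: int = 0,
    gene_len: int = 90,
    chrom: str = "chr1",
) -> tuple[list[SequenceRecord], list[GeneAnnotation]]:
    """Random genome laid out as one block per gene (promoter + CDS), with
    genes alternating strand so every gene has a dedicated intergenic
    promoter region of length promoter_len upstream of its CDS start."""
    if n_genes < 2:
        raise SyntheticDataError("n_genes must be >= 2")
    if not (0 < gc_content < 1):
        raise SyntheticDataError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    block = promoter_len + gene_len
    seq = _random_dna(n_genes * block, gc_content, rng)
    genes = []
    for i in range(n_genes):
        b0 = i * block + 1  # 1-based block start
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            cds_start = b0 + promoter_len
            cds_end = b0 + block - 1
            tss = cds_start
        else:
            cds_start = b0
            cds_end = b0 + gene_len - 1
            tss = cds_end
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                strand=strand,
                cds_start=cds_start,
                cds_end=cds_end,
                tss=tss,
            )
        )
    return [SequenceRecord(chrom, seq)], genes


def make_truth_pwm(
    width: int, seed: int = 0, concentration: float = 0.85, name: str = "truth"
) -> Motif:
    """Random informative PWM: each column puts ~concentration mass on a
    random consensus base, Dirichlet-jittered."""
    rng = np.random.default_rng(seed)
    probs = np.empty((4, width))
    for j in range(width):
        base = rng.integers(0, 4)
        alpha = np.full(4, (1 - concentration) / 3 * 40)
        alpha[base] = concentration * 40
        probs[:, j] = rng.dirichlet(alpha)
    return Motif(name=name, probs=probs, provenance="measured")


def sample_site(pwm: Motif, rng) -> str:
    return "".join(
        BASES[rng.choice(4, p=pwm.probs[:, j] / pwm.probs[:, j].sum())]
        for j in range(pwm.width)
    )


def plant_motif_sites(
    world: SyntheticWorld,
    tf_id: str,
    truth_pwm: Motif,
    regulon_fraction: float = 0.2,
    sites_per_promoter: int = 1,
    seed: int = 0,
) -> SyntheticWorld:
    """Designate a regulon (a random fraction of genes) and write one or more
    sites sampled column-independently from truth_pwm into each regulon
    gene's promoter, at uniform-random non-overlapping offsets and on a
    uniform-random strand.  The exact sequence, coordinate and strand of
    every planted site is recorded."""
    W = truth_pwm.width
    if W > world.promoter_len:
        raise SyntheticDataError("site longer than promoter window")
    rng = np.random.default_rng(seed)
    world.truth_pwms[tf_id] = truth_pwm
    n_regulon = int(round(regulon_fraction * len(world.genes)))
    if n_regulon == 0:
        world.regulons[tf_id] = set()
        return world
    chosen = rng.choice(len(world.genes), size=n_regulon, replace=False)
    regulon = {world.genes[i].gene_id for i in sorted(chosen)}
    world.regulons[tf_id] = regulon
    chrom_seq = list(world.genome[0].sequence)
    for i in sorted(chosen):
        gene = world.genes[i]
        p_start, p_end = world.promoter_interval(gene)
        occupied = world._occupied.setdefault(gene.gene_id, [])
        for _ in range(sites_per_promoter):
            placed = False
            for _try in range(200):
                off = int(rng.integers(0, world.promoter_len - W + 1))
                s0 = p_start + off  # 1-based genomic start
                if all(s0 + W - 1 < a or s0 > b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise SyntheticDataError(
                    f"cannot place non-overlapping site in promoter of {gene.gene_id}"
                )
            occupied.append((s0, s0 + W - 1))
            site = sample_site(truth_pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else revcomp(site)
            chrom_seq[s0 - 1 : s0 - 1 + W] = inserted
            world.planted_sites.append(
                PlantedSite(tf_id, gene.gene_id, s0, strand, site)
            )
    world.genome[0] = SequenceRecord(world.genome[0].id, "".join(chrom_seq))
    return world


def simulate_chip_peaks(
    world: SyntheticWorld,
    tf_id: str,
    sensitivity: float = 0.8,
    fp_rate: float = 0.1,
    pos_sd: float = 10.0,
    seed: int = 0,
    condition: str = "exponential",
) -> ChIPPeakTable:
    """ChIP-chip style peaks: each planted site yields a peak with
    probability sensitivity at a Normal(0, pos_sd)-jittered position with
    p ~ U(0, 0.05); fp_rate * n_genes false peaks land in random non-regulon
    promoters with p ~ U(0, 0.10) (deliberately passing the downstream
    target rule, to stress refinement)."""
    if not (0 <= sensitivity <= 1):
        raise SyntheticDataError("sensitivity must lie in [0, 1]")
    if fp_rate < 0:
        raise SyntheticDataError("fp_rate must be >= 0")
    rng = np.random.default_rng(seed)
    chrom = world.genome[0].id
    rows = []
    for site in world.planted_sites:
        if site.tf_id != tf_id:
            continue
        if rng.random() < sensitivity:
            pos = site.position + int(round(rng.normal(0, pos_sd))) if pos_sd > 0 else site.position
            rows.append(
                {
                    "chrom": chrom,
                    "position": pos,
                    "intensity": float(np.exp(rng.normal(1.0, 0.3))),
                    "p_value": float(rng.uniform(0, 0.05)),
                    "condition": condition,
                }
            )
    regulon = world.regulons.get(tf_id, set())
    non_regulon = [g for g in world.genes if g.gene_id not in regulon]
    n_fp = int(round(fp_rate * len(world.genes)))
    for _ in range(n_fp):
        gene = non_regulon[int(rng.integers(0, len(non_regulon)))]
        p_start, p_end = world.promoter_interval(gene)
        rows.append(
            {
                "chrom": chrom,
                "position": int(rng.integers(p_start, p_end + 1)),
                "intensity": float(np.exp(rng.normal(0.5, 0.3))),
                "p_value": float(rng.uniform(0, 0.10)),
                "condition": condition,
            }
        )
    table = ChIPPeakTable(
        pd.DataFrame(rows, columns=["chrom", "position", "intensity", "p_value", "condition"])
    )
    world.peaks[tf_id] = table
    return table


def simulate_expression(
    world: SyntheticWorld,
    n_arrays: int = 200,
    n_conditions: int = 5,
    operon_rho: float = 0.7,
    regulon_rho: float = 0.6,
    noise_sd: float = 0.0,
    seed: int = 0,
    stress_condition: str = "stress",
) -> ExpressionMatrix:
    """Latent-factor expression compendium.

    Co-operonic pairs share a per-array factor with loading sqrt(operon_rho)
    so their population Pearson correlation equals operon_rho; each TF and
    its regulon genes (those not already in operons) share a per-TF factor
    with loading sqrt(regulon_rho), which is decoupled (rho -> 0) in the
    designated stress condition.  noise_sd adds independent measurement
    noise on top (shrinking correlations toward rho / (1 + noise_sd^2))."""
    if n_arrays < 2 * n_conditions:
        raise SyntheticDataError("n_arrays must be >= 2 * n_conditions")
    for rho in (operon_rho, regulon_rho):
        if not (0 <= rho < 1):
            raise SyntheticDataError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = world.gene_ids
    n_genes = len(gene_ids)
    cond_labels = [f"cond_{k + 1}" for k in range(n_conditions - 1)] + [stress_condition]
    assignment = np.repeat(np.arange(n_conditions), int(np.ceil(n_arrays / n_conditions)))[
        :n_arrays
    ]
    arrays = [f"array_{a:04d}" for a in range(n_arrays)]
    conditions = pd.Series([cond_labels[c] for c in assignment], index=arrays)
    stress_mask = conditions.values == stress_condition

    X = rng.normal(0, 1, size=(n_genes, n_arrays))
    gi = {g: k for k, g in enumerate(gene_ids)}
    in_operon: set[str] = set()
    for a, b in world.operon_pairs:
        f = rng.normal(0, 1, n_arrays)
        for g in (a, b):
            X[gi[g]] = np.sqrt(operon_rho) * f + np.sqrt(1 - operon_rho) * X[gi[g]]
        in_operon.update((a, b))
    for tf_id, regulon in world.regulons.items():
        members = [g for g in sorted(regulon) if g not in in_operon]
        tf_gene = world.tf_genes.get(tf_id)
        if tf_gene and tf_gene not in in_operon and tf_gene not in members:
            members.append(tf_gene)
        f = rng.normal(0, 1, n_arrays)
        loading = np.where(stress_mask, 0.0, np.sqrt(regulon_rho))
        resid = np.where(stress_mask, 1.0, np.sqrt(1 - regulon_rho))
        for g in members:
            X[gi[g]] = loading * f + resid * X[gi[g]]
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, size=X.shape)
    values = pd.DataFrame(X, index=gene_ids, columns=arrays)
    expr = ExpressionMatrix(values=values, conditions=conditions)
    world.expression = expr
    return expr


# ---------------------------------------------------------------------------
# ortholog proteomes


def random_proteome(
    n_proteins: int, length: int = 200, seed: int = 0, prefix: str = "p"
) -> list[SequenceRecord]:
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_proteins):
        seq = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, length))
        out.append(SequenceRecord(f"{prefix}{i:03d}", seq))
    return out


def mutate_proteome(
    proteome: list[SequenceRecord],
    identity_target: float = 0.8,
    fragment_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], set[str]]:
    """Diverge a proteome by point substitution to the requested identity,
    and truncate a fraction of proteins hard enough (< 50 aa and < 70% of
    original length) to fail downstream reciprocal-best-hit filters.
    Returns (new proteome, ids of fragmented proteins)."""
    if not (0 < identity_target <= 1):
        raise SyntheticDataError("identity_target must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    fragmented: set[str] = set()
    for rec in proteome:
        seq = list(rec.sequence)
        n_sub = int(round((1 - identity_target) * len(seq)))
        if n_sub > 0:
            pos = rng.choice(len(seq), size=n_sub, replace=False)
            for p in pos:
                alt = AMINO_ACIDS.replace(seq[p], "")
                seq[p] = alt[rng.integers(0, len(alt))]
        new_seq = "".join(seq)
        if fragment_rate > 0 and rng.random() < fragment_rate:
            cut = max(10, min(49, int(0.6 * len(new_seq))))
            new_seq = new_seq[:cut]
            fragmented.add(rec.id)
        out.append(SequenceRecord(rec.id, new_seq, rec.description))
    return out, fragmented


def generate_ortho_species(
    n_species: int = 18,
    n_proteins: int = 20,
    protein_length: int = 200,
    promoter_len: int = 150,
    identity_target: float = 0.8,
    fragment_rate: float = 0.1,
    conserved_site: str | None = None,
    conserved_genes: list[str] | None = None,
    seed: int = 0,
) -> list[SpeciesData]:
    """Divergent synthetic species, each with a proteome (point-mutated from
    a shared ancestral proteome), a genome and annotations.  Optionally a
    conserved cis-regulatory site is planted at a fixed offset in the
    promoters of designated genes in every species."""
    rng = np.random.default_rng(seed)
    base = random_proteome(n_proteins, protein_length, seed=seed + 1, prefix="g")
    species = []
    for k in range(n_species):
        frag = fragment_rate if k > 0 else 0.0  # species 0 is the reference
        ident = identity_target if k > 0 else 1.0
        proteome, fragmented = mutate_proteome(
            base, identity_target=ident, fragment_rate=frag, seed=seed + 100 + k
        )
        genome, genes = generate_genome(
            n_genes=n_proteins,
            promoter_len=promoter_len,
            gc_content=0.5,
            seed=seed + 200 + k,
            chrom=f"sp{k:02d}_chr",
        )
        # gene ids must match proteome ids for ortholog-promoter joins
        genes = [
            GeneAnnotation(
                gene_id=proteome[i].id,
                chrom=g.chrom,
                strand=g.strand,
                cds_start=g.cds_start,
                cds_end=g.cds_end,
                tss=g.tss,
            )
            for i, g in enumerate(genes)
        ]
        if conserved_site:
            targets = conserved_genes or [base[0].id]
            seq = list(genome[0].sequence)
            for i, g in enumerate(genes):
                if g.gene_id in targets:
                    ref = g.reference_point
                    if g.strand == "+":
                        s0 = ref - promoter_len + 20
                        seq[s0 - 1 : s0 - 1 + len(conserved_site)] = conserved_site
                    else:
                        s0 = ref + promoter_len - 20 - len(conserved_site) + 1
                        seq[s0 - 1 : s0 - 1 + len(conserved_site)] = revcomp(
                            conserved_site
                        )
            genome = [SequenceRecord(genome[0].id, "".join(seq))]
        species.append(
            SpeciesData(
                name=f"sp{k:02d}",
                proteome=proteome,
                genome=genome,
                genes=genes,
                fragmented=fragmented,
            )
        )
    return species


# ---------------------------------------------------------------------------
# whole worlds


def generate_world(
    n_genes: int = 2000,
    promoter_len: int = 250,
    gc_content: float = 0.5,
    n_tfs: int = 8,
    motif_width: int = 15,
    truth_concentration: float = 0.85,
    regulon_fraction: float = 0.02,
    sites_per_promoter: int = 1,
    chip_sensitivity: float = 0.8,
    chip_fp_rate: float = 0.1,
    chip_pos_sd: float = 10.0,
    n_arrays: int = 200,
    n_conditions: int = 5,
    operon_rho: float = 0.7,
    regulon_rho: float = 0.6,
    operon_fraction: float = 0.25,
    n_species: int = 18,
    n_ortho_proteins: int = 20,
    ortho_identity: float = 0.8,
    ortho_fragment_rate: float = 0.1,
    with_expression: bool = True,
    with_species: bool = True,
    seed: int = 0,
) -> SyntheticWorld:
    """Build a complete synthetic world with all per-TF structures."""
    genome, genes = generate_genome(n_genes, promoter_len, gc_content, seed=seed)
    world = SyntheticWorld(
        genome=genome, genes=genes, promoter_len=promoter_len, rng_seed=seed
    )
    # designate 2-gene operons among the first operon_fraction of genes
    n_operons = int(operon_fraction * n_genes / 2)
    world.operon_pairs = [
        (genes[2 * k].gene_id, genes[2 * k + 1].gene_id) for k in range(n_operons)
    ]
    rng = np.random.default_rng(seed + 7)
    non_operonic = [g.gene_id for g in genes[2 * n_operons :]]
    for t in range(n_tfs):
        tf_id = f"tf{t}"
        pwm = make_truth_pwm(
            motif_width,
            seed=seed + 1000 + t,
            concentration=truth_concentration,
            name=f"{tf_id}_truth",
        )
        plant_motif_sites(
            world,
            tf_id,
            pwm,
            regulon_fraction=regulon_fraction,
            sites_per_promoter=sites_per_promoter,
            seed=seed + 2000 + t,
        )
        world.tf_genes[tf_id] = non_operonic[int(rng.integers(0, len(non_operonic)))]
        simulate_chip_peaks(
            world,
            tf_id,
            sensitivity=chip_sensitivity,
            fp_rate=chip_fp_rate,
            pos_sd=chip_pos_sd,
            seed=seed + 3000 + t,
        )
    if with_expression:
        simulate_expression(
            world,
            n_arrays=n_arrays,
            n_conditions=n_conditions,
            operon_rho=operon_rho,
            regulon_rho=regulon_rho,
            seed=seed + 4000,
        )
    if with_species:
        world.ortho_species = generate_ortho_species(
            n_species=n_species,
            n_proteins=n_ortho_proteins,
            promoter_len=promoter_len,
            identity_target=ortho_identity,
            fragment_rate=ortho_fragment_rate,
            seed=seed + 5000,
        )
    return world


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Write the world as a self-contained directory of standard formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fasta", world.genome)
    write_gff(out / "genes.gff3", world.genes)
    (out / "truth").mkdir(exist_ok=True)
    for tf_id, pwm in world.truth_pwms.items():
        write_meme_motifs(out / "truth" / f"{tf_id}.meme", MotifFile(motifs=[pwm]))
    for tf_id, table in world.peaks.items():
        write_peak_table(out / f"peaks_{tf_id}.tsv", table)
    if world.expression is not None:
        write_expression(
            out / "expression.tsv", world.expression.values, world.expression.conditions
        )
    for sp in world.ortho_species:
        d = out / f"species_{sp.name}"
        d.mkdir(exist_ok=True)
        write_fasta(d / "proteome.fasta", sp.proteome)
        write_fasta(d / "genome.fasta", sp.genome)
        write_gff(d / "genes.gff3", sp.genes)
    manifest = {
        "rng_seed": world.rng_seed,
        "n_genes": len(world.genes),
        "promoter_len": world.promoter_len,
        "tfs": sorted(world.truth_pwms),
        "regulon_sizes": {t: len(r) for t, r in sorted(world.regulons.items())},
        "n_planted_sites": len(world.planted_sites),
        "n_species": len(world.ortho_species),
        "operon_pairs": world.operon_pairs,
        "planted_sites": [
            [s.tf_id, s.gene_id, s.position, s.strand, s.sequence]
            for s in world.planted_sites
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
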