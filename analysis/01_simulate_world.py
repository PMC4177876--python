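#!/usr/bin/env python
"""Generate the synthetic study world and write it to results/world/.

The world stands in for the data landscape of a halophilic archaeon with a
small family of paralogous transcription factors: a genome with per-TF
regulons whose promoters carry planted binding sites, ChIP-chip style peak
tables (80% sensitivity, 10% false-positive rate), an expression compendium
with operon-like correlation structure (rho = 0.7, decoupled under stress),
and 18 divergent sister species for ortholog analysis.
"""

from pathlib import Path

from ffrp.synthetic_data import generate_world, write_world

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "world"


def main() -> None:
    world = generate_world(
        n_genes=200,
        promoter_len=150,
        n_tfs=2,
        motif_width=12,
        truth_concentration=0.9,
        regulon_fraction=0.2,
        n_arrays=120,
        n_conditions=4,
        n_species=18,
        n_ortho_proteins=12,
        seed=SEED,
    )
    write_world(world, OUT)
    print(f"world written to {OUT}")
    print(f"  genes: {len(world.genes)}, planted sites: {len(world.planted_sites)}")
    for tf, reg in sorted(world.regulons.items()):
        print(f"  {tf}: regulon {len(reg)} genes, {len(world.peaks[tf])} ChIP peaks")
    print(f"  species: {len(world.ortho_species)}, arrays: {world.expression.n_arrays}")


if __name__ == "__main__":
    main()
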