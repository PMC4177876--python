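"""ChIP target rule, PWM regulons, hypergeometric enrichment, and iterative
motif refinement."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from ffrp.comparative import PromoterSet, PromoterEntry, WindowSpec, extract_promoters
from ffrp.io_formats import ChIPPeakTable, GeneAnnotation
from ffrp.motifs import BASES, Motif, MotifHit
from ffrp.regulon import (
    RegulonError,
    build_count_matrix,
    chip_targets,
    hypergeometric_enrichment,
    pwm_regulon,
    refine_motif,
    regulon_network,
    network_summary,
)
from ffrp.synthetic_data import (
    SyntheticWorld,
    generate_genome,
    make_truth_pwm,
    plant_motif_sites,
    sample_site,
    simulate_chip_peaks,
)


def peaks_df(rows):
    return ChIPPeakTable(
        pd.DataFrame(
            rows, columns=["chrom", "position", "intensity", "p_value", "condition"]
        )
    )


class TestChipTargets:
    GENE = GeneAnnotation("g1", "c", "+", 1000, 1200, tss=1000)

    def test_significant_nearby_peak_included(self):
        t = chip_targets(peaks_df([("c", 960, 1.0, 0.05, "e")]), [self.GENE])
        assert t.gene_ids == {"g1"}
        assert t.evidence["g1"] == [(960, 40)]

    def test_insignificant_peak_excluded(self):
        t = chip_targets(peaks_df([("c", 960, 1.0, 0.15, "e")]), [self.GENE])
        assert t.gene_ids == set()

    @pytest.mark.parametrize(
        "p,dist,expected",
        [
            (0.099, 40, True),
            (0.101, 40, False),
            (0.05, 100, True),
            (0.05, 101, False),
        ],
        ids=["p_just_below", "p_just_above", "dist_at_window", "dist_past_window"],
    )
    def test_rule_boundary(self, p, dist, expected):
        t = chip_targets(peaks_df([("c", 1000 - dist, 1.0, p, "e")]), [self.GENE])
        assert (t.gene_ids == {"g1"}) is expected

    def test_downstream_peak_never_counts(self):
        t = chip_targets(peaks_df([("c", 1040, 1.0, 0.01, "e")]), [self.GENE])
        assert t.gene_ids == set()

    def test_minus_strand_rule_is_mirrored(self):
        gene = GeneAnnotation("gm", "c", "-", 500, 700, tss=700)
        inside = chip_targets(peaks_df([("c", 780, 1.0, 0.05, "e")]), [gene])
        outside = chip_targets(peaks_df([("c", 620, 1.0, 0.05, "e")]), [gene])
        assert inside.gene_ids == {"gm"} and outside.gene_ids == set()

    def test_divergent_promoter_peak_serves_both_genes(self):
        plus = GeneAnnotation("gp", "c", "+", 1000, 1100, tss=1000)
        minus = GeneAnnotation("gm", "c", "-", 800, 900, tss=900)
        t = chip_targets(peaks_df([("c", 950, 1.0, 0.02, "e")]), [plus, minus])
        assert t.gene_ids == {"gp", "gm"}

    def test_perfect_chip_recovers_planted_regulon_exactly(self):
        genome, genes = generate_genome(60, 80, 0.5, seed=1)
        world = SyntheticWorld(genome=genome, genes=genes, promoter_len=80, rng_seed=1)
        plant_motif_sites(world, "tf0", make_truth_pwm(8, 2), regulon_fraction=0.3, seed=3)
        peaks = simulate_chip_peaks(
            world, "tf0", sensitivity=1.0, fp_rate=0.0, pos_sd=0.0, seed=4
        )
        t = chip_targets(peaks, genes, p_max=0.10, window_bp=80)
        assert t.gene_ids == world.regulons["tf0"]


class TestPwmRegulon:
    def test_truth_pwm_recovers_planted_regulon(self):
        genome, genes = generate_genome(100, 100, 0.5, seed=5)
        world = SyntheticWorld(genome=genome, genes=genes, promoter_len=100, rng_seed=5)
        # width 12 at consensus mass 0.9: per-site recovery power ~0.95 at
        # alpha = 1e-4 (same design point as the pipeline demo)
        pwm = make_truth_pwm(12, seed=6, concentration=0.9)
        plant_motif_sites(world, "tf0", pwm, regulon_fraction=0.3, seed=7)
        promoters = extract_promoters(world.genome, world.genes, WindowSpec(100, 0, "TSS"))
        pred = pwm_regulon(pwm, promoters, p_threshold=1e-4)
        planted = world.regulons["tf0"]
        assert len(pred.gene_ids & planted) >= 0.9 * len(planted)

    def test_motif_wider_than_promoters_yields_empty_regulon(self):
        entries = [PromoterEntry("g", "", "c", 1, 6, "+", "ACGTAC")]
        ps = PromoterSet(entries, WindowSpec(6, 0))
        pred = pwm_regulon(make_truth_pwm(10, 1), ps)
        assert pred.gene_ids == set()

    def test_background_rate_on_shuffled_promoters(self):
        """On motif-free background the regulon size stays within binomial
        noise of N * (1 - (1 - alpha)^(2 (L - W + 1)))."""
        rng = np.random.default_rng(8)
        L, W, N, alpha = 200, 8, 300, 1e-3
        entries = [
            PromoterEntry(f"g{i}", "", "c", 1, L, "+", "".join(rng.choice(list("ACGT"), L)))
            for i in range(N)
        ]
        ps = PromoterSet(entries, WindowSpec(L, 0))
        pred = pwm_regulon(make_truth_pwm(W, 9), ps, p_threshold=alpha)
        expect = N * (1 - (1 - alpha) ** (2 * (L - W + 1)))
        sd = np.sqrt(expect)
        assert abs(len(pred.gene_ids) - expect) < 4 * sd + 5


class TestHypergeometricEnrichment:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        a = set(universe[:10])
        res = hypergeometric_enrichment(a, a, universe)
        assert res.k == 10
        assert res.p_value == pytest.approx(1.0 / comb(20, 10), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(universe[:5], universe[10:15], universe)
        assert res.k == 0 and res.p_value == pytest.approx(1.0)

    def test_matches_monte_carlo_resampling(self):
        rng = np.random.default_rng(10)
        universe = [f"g{i}" for i in range(60)]
        a = set(rng.choice(universe, 20, replace=False))
        b = set(rng.choice(universe, 15, replace=False))
        res = hypergeometric_enrichment(a, b, universe)
        n_draws = 100_000
        k_obs = res.k
        draws = np.array(
            [len(a & set(rng.choice(universe, 15, replace=False))) for _ in range(n_draws)]
        )
        mc = np.mean(draws >= k_obs)
        se = np.sqrt(mc * (1 - mc) / n_draws) if 0 < mc < 1 else 1 / n_draws
        assert abs(res.p_value - mc) <= 3 * se + 3 / n_draws

    def test_invariant_under_gene_relabelling(self):
        universe = [f"g{i}" for i in range(30)]
        a, b = set(universe[:12]), set(universe[8:20])
        p1 = hypergeometric_enrichment(a, b, universe).p_value
        relabel = {g: f"x_{g}" for g in universe}
        p2 = hypergeometric_enrichment(
            {relabel[g] for g in a}, {relabel[g] for g in b}, relabel.values()
        ).p_value
        assert p1 == p2

    def test_empty_universe_rejected(self):
        with pytest.raises(RegulonError):
            hypergeometric_enrichment(set(), set(), set())


class TestCountMatrix:
    def test_identical_hits_give_point_mass(self):
        hits = [MotifHit("a", 1, "+", "GTTAC", 1.0, 1e-5)] * 2
        M = build_count_matrix(hits, 5)
        for j, ch in enumerate("GTTAC"):
            assert M[BASES.index(ch), j] == 1.0

    def test_sampled_hits_recover_generating_pwm(self):
        rng = np.random.default_rng(11)
        pwm = make_truth_pwm(6, seed=12)
        hits = [
            MotifHit("g", 1, "+", sample_site(pwm, rng), 0.0, 1e-5) for _ in range(1000)
        ]
        M = build_count_matrix(hits, 6)
        assert np.abs(M - pwm.probs).max() < 0.05

    def test_zero_hits_signalled(self):
        with pytest.raises(RegulonError):
            build_count_matrix([], 5)


def corrupt_pwm(pwm: Motif, rng, strength=5.0) -> Motif:
    probs = np.stack(
        [rng.dirichlet(strength * pwm.probs[:, j] + 0.5) for j in range(pwm.width)],
        axis=1,
    )
    return Motif(pwm.name + "_noisy", probs)


def kl_per_column(p: np.ndarray, q: np.ndarray) -> float:
    """Mean per-column KL(p || q); p may contain zeros (0 log 0 = 0)."""
    eps = 1e-12
    terms = np.where(p > 0, p * np.log(p / (q + eps)), 0.0)
    return float(np.mean(terms.sum(axis=0)))


class TestRefineMotif:
    def _world(self, seed):
        genome, genes = generate_genome(200, 100, 0.5, seed=seed)
        world = SyntheticWorld(genome=genome, genes=genes, promoter_len=100, rng_seed=seed)
        truth = make_truth_pwm(8, seed=seed + 1, concentration=0.9)
        plant_motif_sites(world, "tf", truth, regulon_fraction=0.2, seed=seed + 2)
        promoters = extract_promoters(world.genome, world.genes, WindowSpec(100, 0, "TSS"))
        return world, truth, promoters

    def test_zero_weight_returns_seed(self):
        world, truth, promoters = self._world(20)
        trace = refine_motif(truth, promoters, n_iter=3, w_range=(0.0, 0.0))
        assert np.allclose(trace.final_motif.probs, truth.probs)

    def test_full_weight_single_step_equals_empirical_matrix(self):
        world, truth, promoters = self._world(21)
        trace = refine_motif(truth, promoters, n_iter=2, w_range=(1.0, 1.0))
        it = trace.iterations[-1]
        assert it.n_hits > 0
        assert np.allclose(trace.iterations[-1].mixed, it.empirical)

    def test_columns_stay_normalized_and_convex(self):
        world, truth, promoters = self._world(22)
        rng = np.random.default_rng(22)
        seed_motif = corrupt_pwm(truth, rng)
        trace = refine_motif(seed_motif, promoters, n_iter=5)
        prev = seed_motif.probs
        for it in trace.iterations:
            assert np.allclose(it.mixed.sum(axis=0), 1.0, atol=1e-9)
            if it.empirical is not None:
                lo = np.minimum(prev, it.empirical) - 1e-12
                hi = np.maximum(prev, it.empirical) + 1e-12
                assert np.all(it.mixed >= lo) and np.all(it.mixed <= hi)
            prev = it.mixed

    def test_zero_hit_iterations_skip_update(self):
        entries = [PromoterEntry("g", "", "c", 1, 30, "+", "A" * 30)]
        ps = PromoterSet(entries, WindowSpec(30, 0))
        gc_motif = Motif("gc", np.array([[0.01, 0.49, 0.49, 0.01]] * 8).T / 1.0)
        trace = refine_motif(gc_motif, ps, n_iter=3)
        assert trace.failed
        assert np.allclose(trace.final_motif.probs, gc_motif.probs)

    def test_refinement_moves_corrupted_seed_toward_truth(self):
        """Dirichlet-corrupted seeds must end closer (columnwise KL) to the
        generating PWM after refinement in >= 18 of 20 seeded replicates."""
        wins = 0
        for seed in range(20):
            world, truth, promoters = self._world(100 + seed)
            rng = np.random.default_rng(seed)
            seed_motif = corrupt_pwm(truth, rng)
            trace = refine_motif(
                seed_motif, promoters, target_filter=world.regulons["tf"], n_iter=5
            )
            kl_seed = kl_per_column(seed_motif.probs, truth.probs)
            kl_final = kl_per_column(trace.final_motif.probs, truth.probs)
            wins += kl_final < kl_seed
        assert wins >= 18


class TestRegulonNetwork:
    def _pred(self, genes):
        return type(
            "P", (), {"gene_ids": set(genes)}
        )()

    def test_edge_labels(self):
        from ffrp.regulon import TargetSet

        pred = self._pred({"g1", "g2"})
        ts = TargetSet("tf", {"g2", "g3"}, {})
        edges = regulon_network(["tf"], {"tf": pred}, {"tf": ts})
        labels = dict(zip(edges.gene, edges.support))
        assert labels == {"g1": "pwm_only", "g2": "pwm+chip", "g3": "chip_only"}

    def test_empty_chip_gives_all_pwm_only(self):
        from ffrp.regulon import TargetSet

        pred = self._pred({"g1", "g2"})
        edges = regulon_network(["tf"], {"tf": pred}, {"tf": TargetSet("tf", set(), {})})
        assert set(edges.support) == {"pwm_only"}
        summary = network_summary(edges)
        assert summary.loc[0, "pwm_only"] == 2 and summary.loc[0, "total"] == 2
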