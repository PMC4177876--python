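"""Threading, annealing and ensemble-to-PWM conversion, checked against
exhaustive enumeration on small duplexes."""

import itertools

import numpy as np
import pytest

from ffrp.motifs import BASES, information_content
from ffrp.structure import (
    AnnealingSchedule,
    EnergyModel,
    TemplateInapplicableError,
    anneal,
    compile_energy,
    ensemble_to_pwm,
    identity_threading,
    load_default_template,
    make_fully_contacted_template,
    predict_specificity,
    thread_sequence,
)


def mismatch_energy(template, consensus: str) -> EnergyModel:
    """Planted energy: +1 per base differing from the consensus."""
    residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
    pair = {}
    for aa, target in zip(residues, consensus):
        for b in BASES:
            pair[(aa, b)] = 0.0 if b == target else 1.0
    return EnergyModel(pair_table=pair)


def brute_force_landscape(template, threaded, energy):
    """Independent oracle: energy of every 4^W sequence by direct contact
    summation (optimal hydration per base)."""
    W = template.duplex_length
    out = {}
    for combo in itertools.product(BASES, repeat=W):
        seq = "".join(combo)
        e = 0.0
        for c in template.contacts:
            aa = threaded.threaded_sequence[c.protein_position]
            e += c.weight * energy.epsilon(aa, seq[c.base_pair_index - 1])
        for j, b in enumerate(seq):
            e += min(energy.eta(b, "dry"), energy.eta(b, "hydrated"))
        out[seq] = e
    return out


class TestThreading:
    def test_template_self_threading_is_identity(self):
        template, _ = load_default_template()
        model = identity_threading(template)
        assert model.contact_identity == 1.0
        assert model.unresolved_positions == set()
        for p in template.protein_positions:
            assert model.threaded_sequence[p] == template.template_protein_sequence[p - 1]

    def test_substitutions_at_contact_positions_carried_through(self):
        template, _ = load_default_template()
        seq = list(template.template_protein_sequence)
        subs = dict(zip(sorted(template.contact_positions)[:3], "WWW"))
        for p, aa in subs.items():
            seq[p - 1] = aa
        model = thread_sequence("".join(seq), template)
        for p in template.protein_positions:
            expected = subs.get(p, template.template_protein_sequence[p - 1])
            assert model.threaded_sequence[p] == expected

    def test_unrelated_sequence_refused(self):
        template, _ = load_default_template()
        with pytest.raises(TemplateInapplicableError):
            thread_sequence("MWWPLCGHIFKMLVWPHC", template)


class TestAnnealer:
    def test_consensus_recovered_for_mismatch_energy_across_seeds(self):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        energy = mismatch_energy(template, "GTTAC")
        for seed in range(20):
            ens = anneal(threaded, energy, AnnealingSchedule(rng_seed=seed))
            assert ens.entries[0].dna_sequence == "GTTAC"
            assert ens.entries[0].energy == 0.0

    def test_flat_energy_fills_ensemble_with_unique_visits(self):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        ens = anneal(threaded, EnergyModel(), AnnealingSchedule(rng_seed=1))
        assert len(ens.entries) == 100
        assert len({e.dna_sequence for e in ens.entries}) == 100
        assert all(e.energy == 0.0 for e in ens.entries)

    def test_two_degenerate_minima_both_found(self):
        template = make_fully_contacted_template(4)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        # palindromic preference: A and T equally favourable at every position
        pair = {}
        for aa in residues:
            for b in BASES:
                pair[(aa, b)] = 0.0 if b in "AT" else 1.0
        ens = anneal(threaded, EnergyModel(pair_table=pair), AnnealingSchedule(rng_seed=2))
        zero_energy = {e.dna_sequence for e in ens.entries if e.energy == 0.0}
        assert zero_energy == {"".join(c) for c in itertools.product("AT", repeat=4)}

    def test_ensemble_energies_monotone_and_deterministic(self, rng):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        pair = {(aa, b): float(rng.normal()) for aa in residues for b in BASES}
        energy = EnergyModel(pair_table=pair)
        e1 = anneal(threaded, energy, AnnealingSchedule(rng_seed=9))
        e2 = anneal(threaded, energy, AnnealingSchedule(rng_seed=9))
        energies = [e.energy for e in e1.entries]
        assert energies == sorted(energies)
        assert [e.dna_sequence for e in e1.entries] == [e.dna_sequence for e in e2.entries]

    def test_matches_exhaustive_enumeration_with_hydration(self, rng):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        pair = {(aa, b): float(rng.normal()) for aa in residues for b in BASES}
        hyd = {(b, s): float(rng.normal(0, 0.2)) for b in BASES for s in ("dry", "hydrated")}
        energy = EnergyModel(pair_table=pair, hydration_table=hyd)
        oracle = brute_force_landscape(template, threaded, energy)
        best = min(oracle, key=lambda s: (oracle[s], s))
        ens = anneal(threaded, energy, AnnealingSchedule(rng_seed=4))
        assert ens.entries[0].dna_sequence == best
        assert ens.entries[0].energy == pytest.approx(oracle[best], abs=1e-9)

    def test_high_temperature_visits_follow_boltzmann(self):
        """At fixed high T, chain visit frequencies on a W=4 landscape
        correlate with exp(-E/T) (Spearman > 0.9)."""
        from scipy.stats import spearmanr

        template = make_fully_contacted_template(4)
        threaded = identity_threading(template)
        rng = np.random.default_rng(0)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        pair = {(aa, b): float(rng.normal(0, 1.0)) for aa in residues for b in BASES}
        energy = EnergyModel(pair_table=pair)
        T = 2.0
        sched = AnnealingSchedule(
            t_initial=T, cooling_factor=0.999999, sweeps_per_temperature=20000,
            n_temperatures=1, n_restarts=1, rng_seed=5,
        )
        ens = anneal(threaded, energy, sched, record_visits=True)
        C, _ = compile_energy(threaded, energy)
        seqs = list(ens.visits)
        counts = np.array([ens.visits[s] for s in seqs])
        E = np.array(
            [sum(C[j, BASES.index(ch)] for j, ch in enumerate(s)) for s in seqs]
        )
        rho = spearmanr(counts, np.exp(-E / T)).statistic
        assert rho > 0.9


class TestEnsembleToPwm:
    def test_single_sequence_pseudocount_closed_form(self):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        energy = mismatch_energy(template, "GTTAC")
        ens = anneal(threaded, energy, AnnealingSchedule(rng_seed=0))
        pwm = ensemble_to_pwm(ens, n_low=1, pseudocount=1.0)
        for j, ch in enumerate("GTTAC"):
            for b, base in enumerate(BASES):
                expected = (1.0 + (1 if base == ch else 0)) / 5.0
                assert pwm.probs[b, j] == pytest.approx(expected)

    def test_bottom_100_matches_enumeration(self, rng):
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        pair = {(aa, b): float(rng.normal()) for aa in residues for b in BASES}
        energy = EnergyModel(pair_table=pair)
        ens = anneal(threaded, energy, AnnealingSchedule(rng_seed=6))
        pwm = ensemble_to_pwm(ens, n_low=100, pseudocount=0.0)
        oracle = brute_force_landscape(template, threaded, energy)
        best100 = sorted(oracle, key=lambda s: (oracle[s], s))[:100]
        counts = np.zeros((4, 5))
        for s in best100:
            for j, ch in enumerate(s):
                counts[BASES.index(ch), j] += 1
        assert np.abs(pwm.probs - counts / 100).max() < 1e-12

    def test_boundary_ties_all_included(self):
        template = make_fully_contacted_template(4)
        threaded = identity_threading(template)
        ens = anneal(threaded, EnergyModel(), AnnealingSchedule(rng_seed=1))
        # flat landscape: every sequence ties; all 4^4 visited must be kept
        pwm = ensemble_to_pwm(ens, n_low=10, pseudocount=0.0)
        assert pwm.source_params["n_used"] == len(ens.entries)


class TestPredictSpecificity:
    def test_planted_at_rich_preference_recovered(self):
        """An energy table favouring nAAn...TTn yields a consensus with the
        AA...TT core."""
        template = make_fully_contacted_template(8)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]
        prefs = ["N", "A", "A", "N", "N", "T", "T", "N"]
        pair = {}
        for aa, pref in zip(residues, prefs):
            for b in BASES:
                if pref == "N":
                    pair[(aa, b)] = 0.0
                else:
                    pair[(aa, b)] = 0.0 if b == pref else 2.0
        motif = predict_specificity(
            template.template_protein_sequence,
            template,
            EnergyModel(pair_table=pair),
            AnnealingSchedule(rng_seed=3),
        )
        assert motif.consensus()[1:3] == "AA" and motif.consensus()[5:7] == "TT"

    def test_same_seed_reproduces_pwm(self):
        template, energy = load_default_template()
        sched = AnnealingSchedule(
            rng_seed=8, n_temperatures=20, sweeps_per_temperature=10, n_restarts=1
        )
        m1 = predict_specificity(template.template_protein_sequence, template, energy, sched)
        m2 = predict_specificity(template.template_protein_sequence, template, energy, sched)
        assert np.array_equal(m1.probs, m2.probs)

    def test_non_contact_positions_do_not_change_pwm(self):
        template, energy = load_default_template()
        seq = list(template.template_protein_sequence)
        contact = template.contact_positions
        changed = 0
        for p in range(1, len(seq) + 1):
            if p not in contact and changed < 5 and p not in template.protein_positions:
                seq[p - 1] = "A" if seq[p - 1] != "A" else "G"
                changed += 1
        sched = AnnealingSchedule(
            rng_seed=8, n_temperatures=20, sweeps_per_temperature=10, n_restarts=1
        )
        m1 = predict_specificity(template.template_protein_sequence, template, energy, sched)
        m2 = predict_specificity("".join(seq), template, energy, sched)
        assert np.array_equal(m1.probs, m2.probs)

    def test_larger_epsilon_gap_increases_column_information(self):
        """Specificity transfer: widening one contact's energy gap strictly
        increases that column's information content."""
        template = make_fully_contacted_template(5)
        threaded = identity_threading(template)
        residues = [template.template_protein_sequence[p - 1] for p in template.protein_positions]

        def pwm_for(gap):
            pair = {}
            for k, aa in enumerate(residues):
                g = gap if k == 2 else 0.5
                for b in BASES:
                    pair[(aa, b)] = 0.0 if b == "A" else g
            ens = anneal(
                threaded, EnergyModel(pair_table=pair), AnnealingSchedule(rng_seed=1)
            )
            return ensemble_to_pwm(ens, n_low=100, pseudocount=0.5)

        ics = [information_content(pwm_for(g))[0][2] for g in (0.5, 1.5, 3.0)]
        assert ics[0] < ics[1] < ics[2]
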