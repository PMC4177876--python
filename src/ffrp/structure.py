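"""Structure-templated prediction of transcription-factor DNA-binding
specificity.

The procedure mirrors the protein-DNA design protocol: a query transcription
factor's DNA-binding domain is threaded onto the backbone positions of a
solved homolog-DNA co-crystal template; the identities of the base pairs in
the template duplex (and a per-base hydration state) are then sampled by
Metropolis Monte-Carlo simulated annealing against a pluggable residue-base
contact energy; the position weight matrix is the per-column base frequency
among the 100 lowest-energy unique DNA sequences visited.

The all-atom force field of the original protocol is deliberately replaced
by a simplified pairwise contact energy: E(sigma, s, h) =
sum_contacts weight * eps(residue, base) + sum_bp eta(base, hydration).
Side-chain conformational sampling is absorbed into the eps table; hydration
states are retained as an explicit binary per-base degree of freedom.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from math import exp

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import BASES, Motif

HYDRATION_STATES = ("dry", "hydrated")


class TemplateError(ValueError):
    pass


class TemplateInapplicableError(TemplateError):
    """Query too dissimilar to the template at contact positions."""


@dataclass
class Contact:
    protein_position: int
    base_pair_index: int
    weight: float = 1.0


@dataclass
class StructureTemplate:
    """Contact map between template residue positions and duplex base pairs.

    protein_positions are 1-based indices into template_protein_sequence;
    base_pair_index runs 1..duplex_length.
    """

    template_id: str
    template_protein_sequence: str
    protein_positions: list[int]
    duplex_length: int
    contacts: list[Contact]

    def __post_init__(self) -> None:
        pos_set = set(self.protein_positions)
        for c in self.contacts:
            if not (1 <= c.base_pair_index <= self.duplex_length):
                raise TemplateError(
                    f"contact base pair {c.base_pair_index} outside duplex"
                )
            if c.protein_position not in pos_set:
                raise TemplateError(
                    f"contact protein position {c.protein_position} not listed"
                )
            if not np.isfinite(c.weight) or c.weight < 0:
                raise TemplateError("contact weights must be finite and >= 0")
        for p in self.protein_positions:
            if not (1 <= p <= len(self.template_protein_sequence)):
                raise TemplateError(f"protein position {p} outside template sequence")

    @property
    def contact_positions(self) -> set[int]:
        return {c.protein_position for c in self.contacts}


@dataclass
class EnergyModel:
    """Pairwise residue-base contact scores plus per-base hydration scores.

    pair_table maps (amino_acid, base) -> epsilon; hydration_table maps
    (base, state) -> eta with state in {"dry", "hydrated"}.  Missing entries
    score 0.
    """

    pair_table: dict = field(default_factory=dict)
    hydration_table: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in list(self.pair_table.values()) + list(self.hydration_table.values()):
            if not np.isfinite(v):
                raise TemplateError("energy table entries must be finite")

    def epsilon(self, aa: str, base: str) -> float:
        return self.pair_table.get((aa, base), 0.0)

    def eta(self, base: str, state: str) -> float:
        return self.hydration_table.get((base, state), 0.0)


@dataclass
class ThreadedModel:
    tf_id: str
    template: StructureTemplate
    threaded_sequence: dict  # template position -> residue
    alignment_to_template: dict  # template position -> query position (1-based)
    unresolved_positions: set
    contact_identity: float


@dataclass
class AnnealingSchedule:
    t_initial: float = 2.0
    cooling_factor: float = 0.95
    sweeps_per_temperature: int = 50
    n_temperatures: int = 60
    n_restarts: int = 5
    rng_seed: int = 0
    substitution_fraction: float = 0.8  # 4:1 base substitution : hydration flip

    def validate(self, width: int) -> None:
        if self.t_initial <= 0:
            raise TemplateError("t_initial must be > 0")
        if not (0 < self.cooling_factor < 1):
            raise TemplateError("cooling_factor must lie in (0, 1)")
        total = (
            self.n_restarts * self.n_temperatures * self.sweeps_per_temperature * width
        )
        if total < 100 * width:
            raise TemplateError("schedule evaluates fewer than 100 proposals per bp")


@dataclass
class EnsembleEntry:
    dna_sequence: str
    hydration: tuple
    energy: float


@dataclass
class SequenceEnsemble:
    """Unique DNA sequences visited during annealing, ascending energy (ties
    broken by sequence), each with the hydration vector of its lowest-energy
    visit."""

    entries: list[EnsembleEntry]
    visits: dict | None = None  # sequence -> Metropolis chain visit count

    def __post_init__(self) -> None:
        if not self.entries:
            raise TemplateError("empty ensemble")
        seqs = [e.dna_sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise TemplateError("ensemble contains duplicate sequences")
        energies = [e.energy for e in self.entries]
        if any(b < a - 1e-12 for a, b in zip(energies, energies[1:])):
            raise TemplateError("ensemble not sorted by energy")


# ---------------------------------------------------------------------------
# threading


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


def thread_sequence(
    tf_protein: str,
    template: StructureTemplate,
    tf_id: str = "query",
    min_contact_identity: float = 0.15,
) -> ThreadedModel:
    """Map a query protein onto the template's backbone positions by local
    pairwise alignment (BLOSUM62, affine gaps).

    Template positions falling in alignment gaps keep the template residue
    and are flagged unresolved.  If the identity over contact-bearing
    positions is below ``min_contact_identity`` the template is deemed
    inapplicable and a TemplateInapplicableError is raised.
    """
    tf_protein = tf_protein.upper().replace("*", "")
    aligner = _get_aligner()
    try:
        aln = aligner.align(template.template_protein_sequence, tf_protein)[0]
    except (IndexError, ValueError) as exc:
        raise TemplateInapplicableError(f"{tf_id}: no alignment to template") from exc
    t_blocks, q_blocks = aln.aligned
    pos_map: dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for k in range(te - ts):
            pos_map[ts + k + 1] = qs + k + 1  # 1-based
    threaded: dict[int, str] = {}
    unresolved: set[int] = set()
    for p in template.protein_positions:
        if p in pos_map:
            threaded[p] = tf_protein[pos_map[p] - 1]
        else:
            threaded[p] = template.template_protein_sequence[p - 1]
            unresolved.add(p)
    cpos = sorted(template.contact_positions)
    n_ident = sum(
        1
        for p in cpos
        if p in pos_map and threaded[p] == template.template_protein_sequence[p - 1]
    )
    identity = n_ident / len(cpos) if cpos else 1.0
    if identity < min_contact_identity:
        raise TemplateInapplicableError(
            f"{tf_id}: identity over contact positions {identity:.2f} < "
            f"{min_contact_identity:.2f}; template inapplicable"
        )
    return ThreadedModel(
        tf_id=tf_id,
        template=template,
        threaded_sequence=threaded,
        alignment_to_template={p: pos_map.get(p) for p in template.protein_positions},
        unresolved_positions=unresolved,
        contact_identity=identity,
    )


def identity_threading(template: StructureTemplate, tf_id: str = "template") -> ThreadedModel:
    """Thread the template protein onto itself (zero unresolved positions)."""
    return thread_sequence(template.template_protein_sequence, template, tf_id)


# ---------------------------------------------------------------------------
# energy compilation and annealing


def compile_energy(model: ThreadedModel, energy: EnergyModel):
    """Collapse the contact sum into per-(bp, base) arrays.

    Returns C (W x 4) with C[j, b] = sum over contacts to bp j+1 of
    weight * eps(threaded residue, base b), and H (4 x 2) hydration scores.
    """
    W = model.template.duplex_length
    C = np.zeros((W, 4))
    for c in model.template.contacts:
        aa = model.threaded_sequence[c.protein_position]
        for b, base in enumerate(BASES):
            C[c.base_pair_index - 1, b] += c.weight * energy.epsilon(aa, base)
    H = np.zeros((4, 2))
    for b, base in enumerate(BASES):
        for s, state in enumerate(HYDRATION_STATES):
            H[b, s] = energy.eta(base, state)
    return C, H


def total_energy(C: np.ndarray, H: np.ndarray, seq: np.ndarray, hyd: np.ndarray) -> float:
    return float(C[np.arange(len(seq)), seq].sum() + H[seq, hyd].sum())


def anneal(
    threaded_model: ThreadedModel,
    energy_model: EnergyModel,
    schedule: AnnealingSchedule | None = None,
    ensemble_size: int = 100,
    record_visits: bool = False,
) -> SequenceEnsemble:
    """Sample DNA sequence space by Metropolis simulated annealing.

    Proposals are a single base-pair substitution (uniform among the three
    alternatives) with probability 0.8, or a hydration flip at one base with
    probability 0.2.  The temperature ladder is geometric.  Every evaluated
    state (accepted or not) is recorded in a unique-sequence ledger keyed by
    DNA sequence, keeping the lowest energy seen per sequence.  Deterministic
    given schedule.rng_seed.
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    W = threaded_model.template.duplex_length
    if W < 4:
        raise TemplateError("duplex length must be >= 4")
    schedule.validate(W)
    C, H = compile_energy(threaded_model, energy_model)
    rng = np.random.default_rng(schedule.rng_seed)
    ledger: dict[bytes, tuple[float, bytes]] = {}
    visits: dict[bytes, int] | None = {} if record_visits else None

    def record(seq_bytes: bytes, energy: float, hyd_bytes: bytes) -> None:
        prev = ledger.get(seq_bytes)
        if prev is None or energy < prev[0]:
            ledger[seq_bytes] = (energy, hyd_bytes)

    n_props = schedule.sweeps_per_temperature * W
    for _ in range(schedule.n_restarts):
        seq = rng.integers(0, 4, W).astype(np.int8)
        hyd = rng.integers(0, 2, W).astype(np.int8)
        E = total_energy(C, H, seq.astype(int), hyd.astype(int))
        record(seq.tobytes(), E, hyd.tobytes())
        t = schedule.t_initial
        for _k in range(schedule.n_temperatures):
            kinds = rng.random(n_props) < schedule.substitution_fraction
            positions = rng.integers(0, W, n_props)
            alts = rng.integers(1, 4, n_props)
            us = rng.random(n_props)
            for i in range(n_props):
                pos = positions[i]
                if kinds[i]:
                    old = seq[pos]
                    new = (old + alts[i]) % 4
                    dE = C[pos, new] - C[pos, old] + H[new, hyd[pos]] - H[old, hyd[pos]]
                    seq[pos] = new
                    record(seq.tobytes(), E + dE, hyd.tobytes())
                    if dE <= 0 or us[i] < exp(-dE / t):
                        E += dE
                    else:
                        seq[pos] = old
                else:
                    old_h = hyd[pos]
                    new_h = 1 - old_h
                    dE = H[seq[pos], new_h] - H[seq[pos], old_h]
                    hyd[pos] = new_h
                    record(seq.tobytes(), E + dE, hyd.tobytes())
                    if dE <= 0 or us[i] < exp(-dE / t):
                        E += dE
                    else:
                        hyd[pos] = old_h
                if visits is not None:
                    sb = seq.tobytes()
                    visits[sb] = visits.get(sb, 0) + 1
            t *= schedule.cooling_factor

    entries = [
        EnsembleEntry(
            dna_sequence="".join(BASES[b] for b in np.frombuffer(sb, dtype=np.int8)),
            hydration=tuple(
                HYDRATION_STATES[s] for s in np.frombuffer(hb, dtype=np.int8)
            ),
            energy=e,
        )
        for sb, (e, hb) in ledger.items()
    ]
    entries.sort(key=lambda en: (en.energy, en.dna_sequence))
    target = min(ensemble_size, 4**W)
    if len(entries) < target:
        warnings.warn(
            f"annealing visited only {len(entries)} unique sequences "
            f"(< requested {target}); returning what exists",
            stacklevel=2,
        )
    visit_by_seq = None
    if visits is not None:
        visit_by_seq = {
            "".join(BASES[b] for b in np.frombuffer(sb, dtype=np.int8)): c
            for sb, c in visits.items()
        }
    return SequenceEnsemble(entries=entries[:target], visits=visit_by_seq)


def exhaustive_ensemble(
    threaded_model: ThreadedModel, energy_model: EnergyModel, top: int | None = None
) -> SequenceEnsemble:
    """Enumerate all 4^W sequences (W <= 10) with per-base optimal hydration;
    the small-W ground-truth counterpart of anneal()."""
    W = threaded_model.template.duplex_length
    if W > 10:
        raise TemplateError("exhaustive enumeration limited to W <= 10")
    C, H = compile_energy(threaded_model, energy_model)
    best_h = np.argmin(H, axis=1)  # optimal hydration per base identity
    per_base = C + H[np.arange(4)[None, :].repeat(W, 0), best_h[None, :].repeat(W, 0)]
    entries = []
    for combo in itertools.product(range(4), repeat=W):
        s = np.array(combo)
        e = float(per_base[np.arange(W), s].sum())
        entries.append(
            EnsembleEntry(
                dna_sequence="".join(BASES[b] for b in combo),
                hydration=tuple(HYDRATION_STATES[best_h[b]] for b in combo),
                energy=e,
            )
        )
    entries.sort(key=lambda en: (en.energy, en.dna_sequence))
    if top is not None:
        entries = entries[:top]
    return SequenceEnsemble(entries=entries)


def ensemble_to_pwm(
    ensemble: SequenceEnsemble,
    n_low: int = 100,
    pseudocount: float = 0.5,
    name: str = "predicted",
) -> Motif:
    """PWM from per-column base frequencies among the n_low lowest-energy
    unique sequences.  Sequences tied in energy with the n_low-th entry are
    all included before renormalization."""
    if n_low < 1:
        raise TemplateError("n_low must be >= 1")
    entries = ensemble.entries
    if len(entries) > n_low:
        cutoff = entries[n_low - 1].energy
        n_keep = n_low
        while n_keep < len(entries) and entries[n_keep].energy <= cutoff + 1e-12:
            n_keep += 1
        entries = entries[:n_keep]
    W = len(entries[0].dna_sequence)
    counts = np.full((4, W), float(pseudocount))
    for e in entries:
        for j, ch in enumerate(e.dna_sequence):
            counts[BASES.index(ch), j] += 1.0
    probs = counts / counts.sum(axis=0, keepdims=True)
    return Motif(
        name=name,
        probs=probs,
        provenance="predicted",
        source_params={"n_low": n_low, "n_used": len(entries), "pseudocount": pseudocount},
    )


def predict_specificity(
    tf_protein: str,
    template: StructureTemplate,
    energy_model: EnergyModel,
    schedule: AnnealingSchedule | None = None,
    tf_id: str = "query",
    n_low: int = 100,
    pseudocount: float = 0.5,
) -> Motif:
    """End-to-end: thread -> anneal -> ensemble -> PWM, with provenance."""
    if schedule is None:
        schedule = AnnealingSchedule()
    model = thread_sequence(tf_protein, template, tf_id=tf_id)
    ensemble = anneal(model, energy_model, schedule, ensemble_size=max(100, n_low))
    motif = ensemble_to_pwm(ensemble, n_low=n_low, pseudocount=pseudocount, name=tf_id)
    motif.source_params.update(
        {
            "template": template.template_id,
            "rng_seed": schedule.rng_seed,
            "t_initial": schedule.t_initial,
            "cooling_factor": schedule.cooling_factor,
            "sweeps_per_temperature": schedule.sweeps_per_temperature,
            "n_temperatures": schedule.n_temperatures,
            "n_restarts": schedule.n_restarts,
            "contact_identity": model.contact_identity,
        }
    )
    return motif


# ---------------------------------------------------------------------------
# bundled template and helpers


def load_default_template():
    """Load the bundled simplified template and energy model.

    The bundle is a synthetic stand-in constructed for this package: a
    contact map and residue-base propensity table shaped after the FL11
    dimer-DNA co-crystal geometry (an Lrp/AsnC-family protein bound to an
    A/T-rich duplex), not data extracted from any structure file.
    """
    text = (
        resources.files("ffrp")
        .joinpath("data", "fl11_like_template_synthetic.json")
        .read_text()
    )
    return template_from_dict(json.loads(text))


def template_from_dict(obj: dict) -> tuple[StructureTemplate, EnergyModel]:
    template = StructureTemplate(
        template_id=obj["template_id"],
        template_protein_sequence=obj["template_protein_sequence"],
        protein_positions=list(obj["protein_positions"]),
        duplex_length=int(obj["duplex_length"]),
        contacts=[Contact(*c) for c in obj["contacts"]],
    )
    pair = {(aa, base): float(v) for aa, row in obj["pair_table"].items() for base, v in row.items()}
    hyd = {
        (base, state): float(v)
        for base, row in obj["hydration_table"].items()
        for state, v in row.items()
    }
    return template, EnergyModel(pair_table=pair, hydration_table=hyd)


def make_fully_contacted_template(width: int, template_id: str = "synthetic_full"):
    """Synthetic template in which base pair j is contacted by exactly one
    residue position carrying a distinct amino acid (test/demo helper)."""
    residues = "RKNQSTEDYHWFMLIVACGP"[:width]
    if width > 20:
        raise TemplateError("fully contacted template limited to width <= 20")
    seq = "G" * 5 + residues + "G" * 5
    positions = [6 + j for j in range(width)]
    contacts = [Contact(6 + j, j + 1, 1.0) for j in range(width)]
    return StructureTemplate(
        template_id=template_id,
        template_protein_sequence=seq,
        protein_positions=positions,
        duplex_length=width,
        contacts=contacts,
    )


def energy_model_from_pwm(
    pwm: Motif, template: StructureTemplate, threaded: ThreadedModel, cap: float = 10.0
) -> EnergyModel:
    """Energy table whose Boltzmann weights at T=1 reproduce a target PWM
    column-wise: eps(residue at the contact position, base) =
    -ln pwm[base, bp] (capped).  Requires each contacted bp to see residues
    whose identities are unique across positions, else preferences collide."""
    pair: dict = {}
    for c in template.contacts:
        aa = threaded.threaded_sequence[c.protein_position]
        n_contacts = sum(
            1 for cc in template.contacts if cc.base_pair_index == c.base_pair_index
        )
        for b, base in enumerate(BASES):
            p = max(pwm.probs[b, c.base_pair_index - 1], np.exp(-cap))
            key = (aa, base)
            val = -np.log(p) / (n_contacts * c.weight if c.weight else 1.0)
            if key in pair and abs(pair[key] - val) > 1e-9:
                raise TemplateError(
                    f"residue {aa} contacts multiple base pairs with conflicting "
                    "preferences; use a template with distinct contact residues"
                )
            pair[key] = val
    return EnergyModel(pair_table=pair, hydration_table={})
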