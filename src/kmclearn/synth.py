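"""Synthetic-data generators: ground truths for every stage of the pipeline.

Three kinds of fixture are produced, each bit-reproducible under a fixed
seed:

* noisy boolean bond signals whose flicker the hysteresis filter must reject
  (:func:`generate_bond_signal`);
* atom-resolved bond-graph trajectories generated by simulating a known
  reaction network with explicit atom bookkeeping
  (:func:`generate_reacting_system`), so that extraction and rate estimation
  can be checked against an exact ground truth;
* per-interval Poisson reaction-count streams with known rates
  (:func:`generate_count_stream`).

The default toy chemistry is the methane fragment set
{CH4, CH3, H, H2, C2H6} with six reversible elementary reactions
(dissociation/recombination of CH4, H2 and C2H6), whose species labels match
the field's element/bond-count dialect.  Bond-graph emission is event-driven
and exact — no coordinates are involved — but a toy lattice-coordinate mode
is provided for exercising the distance-based bond detector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeneratorError, ParameterError
from .estimate import reactant_combinations, _multiplicity_matrix
from .extract import BondTrajectory
from .network import (
    ConcentrationTrajectory,
    Reaction,
    ReactionCountSeries,
    ReactionNetwork,
    Species,
)

__all__ = [
    "MoleculeTemplate",
    "GroundTruth",
    "toy_methane_network",
    "random_cluster_network",
    "generate_bond_signal",
    "generate_reacting_system",
    "generate_count_stream",
    "inject_spurious_reactions",
]


@dataclass(frozen=True)
class MoleculeTemplate:
    """Atom-level template of one species: per-atom elements and internal bonds."""

    elements: tuple  # e.g. ("C", "H", "H", "H", "H")
    bonds: tuple  # index pairs, e.g. ((0,1),(0,2),(0,3),(0,4))

    def species(self) -> Species:
        elem = Counter(self.elements)
        bond = Counter(
            tuple(sorted((self.elements[i], self.elements[j]))) for i, j in self.bonds
        )
        return Species.from_counts(elem, bond)


@dataclass
class GroundTruth:
    """What the generator actually did: the true model and its event history."""

    network: ReactionNetwork
    events: list  # (time, reaction_index)
    seed: int
    params: dict = field(default_factory=dict)


def toy_methane_network():
    """The default study system: methane fragments with six reversible reactions.

    Returns ``(network, templates)`` where ``templates`` maps species label to
    its :class:`MoleculeTemplate`.  Rates (count-units / time): CH4 ⇌ CH3 + H
    (0.2 / 0.05), H2 ⇌ H + H (0.4 / 0.05), C2H6 ⇌ CH3 + CH3 (0.3 / 0.05).
    """
    t_h = MoleculeTemplate(("H",), ())
    t_h2 = MoleculeTemplate(("H", "H"), ((0, 1),))
    t_ch3 = MoleculeTemplate(("C", "H", "H", "H"), ((0, 1), (0, 2), (0, 3)))
    t_ch4 = MoleculeTemplate(("C", "H", "H", "H", "H"), ((0, 1), (0, 2), (0, 3), (0, 4)))
    t_c2h6 = MoleculeTemplate(
        ("C", "C", "H", "H", "H", "H", "H", "H"),
        ((0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6), (1, 7)),
    )
    templates = {t.species().label: t for t in (t_h, t_h2, t_ch3, t_ch4, t_c2h6)}
    sp = {name: t.species() for name, t in templates.items()}
    h = sp["H1"]
    h2 = sp["H2 1(H–H)"]
    ch3 = sp["C1 H3 3(H–C)"]
    ch4 = sp["C1 H4 4(H–C)"]
    c2h6 = sp["C2 H6 1(C–C) 6(H–C)"]
    reactions = [
        Reaction((ch3, h), (ch4,), rate_k=0.05),     # recombination
        Reaction((ch4,), (ch3, h), rate_k=0.2),      # CH4 dissociation
        Reaction((h, h), (h2,), rate_k=0.05),        # H + H -> H2
        Reaction((ch3, ch3), (c2h6,), rate_k=0.05),  # CH3 + CH3 -> C2H6
        Reaction((h2,), (h, h), rate_k=0.4),         # H2 dissociation
        Reaction((c2h6,), (ch3, ch3), rate_k=0.3),   # C2H6 dissociation
    ]
    species = sorted(sp.values(), key=lambda s: s.label)
    network = ReactionNetwork(species=species, reactions=reactions, dt=0.01)
    return network, templates


def random_cluster_network(
    rng: np.random.Generator,
    max_size: int = 4,
    n_reactions: int | None = None,
    rate_range=(0.1, 2.0),
) -> ReactionNetwork:
    """Random atom-balanced aggregation–fragmentation network of A_n clusters.

    Species are linear clusters A1..A_max (n atoms of element A, n−1 A–A
    bonds); candidate reactions are all fusions A_i + A_j → A_{i+j} and
    fissions A_n → A_i + A_{n−i}.  A random subset of ``n_reactions`` of them
    receives log-uniform rates.  Balanced by construction.
    """
    if max_size < 2:
        raise ParameterError("max_size must be >= 2")
    species = [
        Species.from_counts({"A": n}, {("A", "A"): n - 1} if n > 1 else {})
        for n in range(1, max_size + 1)
    ]
    candidates = []
    for i in range(1, max_size + 1):
        for j in range(i, max_size + 1):
            if i + j <= max_size:
                candidates.append((
                    (species[i - 1], species[j - 1]), (species[i + j - 1],)
                ))
                candidates.append((
                    (species[i + j - 1],), (species[i - 1], species[j - 1])
                ))
    if n_reactions is None:
        n_reactions = len(candidates)
    if n_reactions > len(candidates):
        raise ParameterError(f"at most {len(candidates)} reactions available")
    idx = rng.choice(len(candidates), size=n_reactions, replace=False)
    lo, hi = rate_range
    reactions = []
    for i in sorted(idx):
        reac, prod = candidates[i]
        k = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        reactions.append(Reaction(reac, prod, rate_k=k))
    return ReactionNetwork(species=species, reactions=reactions, dt=0.1)


def generate_bond_signal(
    n_frames: int,
    true_transitions,
    flicker_rate: float,
    flicker_max_len: int,
    seed: int,
):
    """A clean step signal plus vibrational flicker shorter than the filter window.

    ``true_transitions`` is a list of (frame, new_state); the clean series is
    the corresponding step function (initial state = state before the first
    transition, False if none).  Flickers are runs of length < flicker_max_len
    XOR-ed onto the clean signal at Poisson-placed positions, kept at least
    ``flicker_max_len`` frames away from every transition, from each other and
    from the ends, so that the hysteresis filter at τ = flicker_max_len
    recovers the clean signal exactly.  Returns ``(raw, clean)``.
    """
    if flicker_max_len < 1:
        raise ParameterError("flicker_max_len must be >= 1")
    transitions = sorted((int(f), bool(s)) for f, s in true_transitions)
    frames = [f for f, _ in transitions]
    if any(b - a < flicker_max_len for a, b in zip(frames, frames[1:])):
        raise GeneratorError("transitions closer than flicker_max_len")
    if frames and (frames[0] < flicker_max_len or n_frames - frames[-1] < flicker_max_len):
        raise GeneratorError("transitions too close to the trajectory ends")
    clean = np.zeros(n_frames, dtype=bool)
    state = False
    pos = 0
    for f, s in transitions:
        clean[pos:f] = state
        state = s
        pos = f
    clean[pos:] = state

    rng = np.random.default_rng(seed)
    raw = clean.copy()
    if flicker_rate > 0 and flicker_max_len > 1:
        n_flickers = rng.poisson(flicker_rate * n_frames)
        starts = np.sort(rng.integers(0, n_frames, size=n_flickers))
        lengths = rng.integers(1, flicker_max_len, size=n_flickers)
        guard = flicker_max_len
        blocked_until = guard  # keep clear of frame 0 (initial-state anchor)
        boundaries = frames + [n_frames]
        for s0, ln in zip(starts, lengths):
            end = s0 + int(ln)
            if s0 < blocked_until or end > n_frames - guard:
                continue
            # keep clear of every transition by the guard margin
            if any(f - guard < end and s0 < f + guard for f in frames):
                continue
            raw[s0:end] = ~raw[s0:end]
            blocked_until = end + guard
    return raw, clean


class _AtomSystem:
    """Explicit atom-to-molecule bookkeeping during a template-level simulation."""

    def __init__(self, network, templates, x0, rng):
        self.network = network
        self.templates = templates
        self.rng = rng
        self.molecules: dict = {}  # id -> (species_index, atoms tuple, bonds frozenset)
        self.by_species: list = [set() for _ in range(network.m)]
        self.bond_set: set = set()
        self.next_mol = 0
        self.elements: list = []
        for sidx, count in enumerate(x0):
            label = network.species[sidx].label
            if count and label not in templates:
                raise ConfigurationError(f"no atom template for species {label}")
            for _ in range(int(count)):
                t = templates[label]
                base = len(self.elements)
                self.elements.extend(t.elements)
                atoms = tuple(range(base, base + len(t.elements)))
                bonds = frozenset((atoms[i], atoms[j]) for i, j in t.bonds)
                self._add(sidx, atoms, bonds)

    def _add(self, sidx, atoms, bonds):
        mid = self.next_mol
        self.next_mol += 1
        self.molecules[mid] = (sidx, atoms, bonds)
        self.by_species[sidx].add(mid)
        self.bond_set |= bonds
        return mid

    def _remove(self, mid):
        sidx, atoms, bonds = self.molecules.pop(mid)
        self.by_species[sidx].discard(mid)
        self.bond_set -= bonds
        return atoms

    def fire(self, j):
        """Apply reaction j to uniformly chosen reactant molecule instances."""
        rx = self.network.reactions[j]
        index = self.network.species_index()
        pool: list = []
        for sp, nu in rx.reactant_multiplicities().items():
            sidx = index[sp.label]
            avail = sorted(self.by_species[sidx])
            if len(avail) < nu:
                raise GeneratorError("insufficient reactant molecules (propensity bug)")
            chosen = self.rng.choice(len(avail), size=nu, replace=False)
            for c in sorted(chosen, reverse=True):
                pool.extend(self._remove(avail[c]))
        by_el: dict = {}
        for a in pool:
            by_el.setdefault(self.elements[a], []).append(a)
        for sp in rx.products:
            label = sp.label
            t = self.templates.get(label)
            if t is None:
                raise ConfigurationError(f"no atom template for species {label}")
            try:
                atoms = tuple(by_el[el].pop() for el in t.elements)
            except (KeyError, IndexError) as exc:
                raise ConfigurationError(
                    f"template/stoichiometry mismatch firing {rx.key}"
                ) from exc
            bonds = frozenset(
                (min(atoms[i], atoms[j]), max(atoms[i], atoms[j])) for i, j in t.bonds
            )
            self._add(index[label], atoms, bonds)
        if any(by_el.values()):
            raise ConfigurationError(f"template/stoichiometry mismatch firing {rx.key}")

    def counts(self):
        return np.array([len(s) for s in self.by_species], dtype=np.int64)

    def frame(self):
        return frozenset(self.bond_set)


def generate_reacting_system(
    network: ReactionNetwork,
    templates: dict,
    x0,
    t_end: float,
    frame_dt: float,
    seed: int,
):
    """Simulate the network with explicit atoms; emit per-frame bond graphs.

    Runs the exact stochastic simulation of ``network`` from ``x0`` while
    maintaining atom-to-molecule assignments: each firing consumes concrete
    reactant molecules (chosen uniformly among instances) and rewires their
    atoms into the product templates.  Bond graphs are recorded every
    ``frame_dt``.  Returns ``(bond_trajectory, ground_truth)``.
    """
    if frame_dt <= 0 or t_end <= 0:
        raise ParameterError("t_end and frame_dt must be positive")
    rng = np.random.default_rng(seed)
    sys = _AtomSystem(network, templates, np.asarray(x0, dtype=np.int64), rng)
    NU = _multiplicity_matrix(network)
    k = network.rates()
    n_frames = int(np.floor(t_end / frame_dt)) + 1
    frames: list = []
    events: list = []
    t = 0.0
    next_frame = 0
    while next_frame < n_frames:
        x = sys.counts()
        h = reactant_combinations(network, x[None, :])[0]
        a = h * k
        a0 = a.sum()
        t_next = t + (-np.log(rng.random()) / a0) if a0 > 0 else np.inf
        # emit all frames strictly before the next event
        while next_frame < n_frames and next_frame * frame_dt < min(t_next, np.inf):
            if next_frame * frame_dt > t_end + 1e-12:
                break
            if t_next >= next_frame * frame_dt:
                frames.append(sys.frame())
                next_frame += 1
            else:  # pragma: no cover
                break
        if next_frame >= n_frames or t_next > t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        sys.fire(j)
        events.append((t_next, j))
        t = t_next
    while next_frame < n_frames:  # frozen tail
        frames.append(sys.frame())
        next_frame += 1
    bond_traj = BondTrajectory(
        n_atoms=len(sys.elements),
        elements=tuple(sys.elements),
        frames=frames,
        frame_dt=frame_dt,
    )
    truth = GroundTruth(
        network=network,
        events=events,
        seed=seed,
        params={"x0": list(map(int, x0)), "t_end": t_end, "frame_dt": frame_dt},
    )
    return bond_traj, truth


def generate_count_stream(
    network: ReactionNetwork,
    trajectory: ConcentrationTrajectory,
    seed: int,
    dt: float | None = None,
) -> ReactionCountSeries:
    """Draw n_j(t) ~ Poisson(k_j · h_j(X(t)) · Δt), independent across j and t."""
    dt = network.dt if dt is None else dt
    rng = np.random.default_rng(seed)
    H = reactant_combinations(network, trajectory.X[:-1])
    mu = H * network.rates()[None, :] * dt
    counts = rng.poisson(mu)
    return ReactionCountSeries(counts=counts, reactions=network.reaction_keys())


def inject_spurious_reactions(
    network: ReactionNetwork,
    d: int,
    rate_inflation: float,
    seed: int,
):
    """Append d atom-balanced spurious reactions with inflated rate estimates.

    Spurious reactions are random recombinations of existing species (orders
    ≤ 2 on each side, element-balanced, distinct from every existing reaction
    and from identity rearrangements) that never actually fired; their rates
    are set to ``rate_inflation`` × the median existing rate, emulating
    overestimated rates of rarely observed reactions.  Returns
    ``(augmented_network, genuine_mask)``.
    """
    if d < 0:
        raise ParameterError("d must be >= 0")
    rng = np.random.default_rng(seed)
    out = ReactionNetwork(
        species=list(network.species),
        reactions=[
            Reaction(rx.reactants, rx.products, rate_k=rx.rate_k,
                     observed_count_total=rx.observed_count_total)
            for rx in network.reactions
        ],
        dt=network.dt,
    )
    mask = np.ones(network.r + d, dtype=bool)
    mask[network.r:] = False
    if d == 0:
        return out, mask

    existing = set(network.reaction_keys())
    species = list(network.species)

    def elem_vec(multiset):
        c: Counter = Counter()
        for s in multiset:
            c.update(s.elements)
        return tuple(sorted(c.items()))

    sides = []
    for i in range(len(species)):
        sides.append((species[i],))
        for j in range(i, len(species)):
            sides.append((species[i], species[j]))
    candidates = []
    for lhs in sides:
        for rhs in sides:
            if elem_vec(lhs) != elem_vec(rhs):
                continue
            if tuple(sorted(s.label for s in lhs)) == tuple(sorted(s.label for s in rhs)):
                continue
            rx = Reaction(lhs, rhs, rate_k=0.0)
            if rx.key in existing or rx.key in {c.key for c in candidates}:
                continue
            candidates.append(rx)
    if len(candidates) < d:
        raise GeneratorError(
            f"only {len(candidates)} balanced spurious reactions constructible, need {d}"
        )
    base = float(np.median([rx.rate_k for rx in network.reactions if rx.rate_k > 0]))
    chosen = rng.choice(len(candidates), size=d, replace=False)
    for c in sorted(chosen):
        rx = candidates[c]
        rx.rate_k = rate_inflation * base
        out.reactions.append(rx)
    return out, mask
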