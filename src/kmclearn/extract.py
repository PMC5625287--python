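"""Turn bond-graph (or coordinate) trajectories into species, concentrations and reaction events.

The stages are:

1. :func:`bond_states_from_coordinates` — raw per-frame bond graphs from a
   distance criterion (one cutoff per element pair, minimum-image when a
   periodic box is given).
2. :func:`hysteresis_filter` / :func:`filter_bond_trajectory` — the bond
   duration criterion τ: a bonding-state change is accepted only after it has
   persisted for τ consecutive frames, and is then stamped retroactively at
   the first frame of the persistent run (the physical event time).  This is
   a two-state hysteresis automaton that suppresses vibrational flicker.
3. :func:`molecules_per_frame` — connected components of the smoothed bond
   graph, mapped to species by element and bond-type counts.
4. :func:`detect_reaction_events` — molecules that change between consecutive
   frames are linked through shared atoms; each connected component of that
   bipartite link graph is one elementary reaction event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigurationError, FormatError, InconsistencyError, ParameterError
from .network import (
    ConcentrationTrajectory,
    Reaction,
    ReactionCountSeries,
    ReactionNetwork,
    Species,
)

__all__ = [
    "BondTrajectory",
    "Molecule",
    "ReactionEvent",
    "bond_states_from_coordinates",
    "hysteresis_filter",
    "filter_bond_trajectory",
    "molecules_per_frame",
    "detect_reaction_events",
    "read_xyz",
    "read_bond_list",
    "write_bond_list",
]


@dataclass
class BondTrajectory:
    """Per-frame bond-edge sets over a fixed set of typed atoms."""

    n_atoms: int
    elements: tuple  # per-atom element symbols
    frames: list  # list of frozensets of (i, j) with i < j
    frame_dt: float = 1.0

    def __post_init__(self):
        self.elements = tuple(self.elements)
        if len(self.elements) != self.n_atoms:
            raise FormatError("elements length must equal n_atoms")
        clean = []
        for f, edges in enumerate(self.frames):
            norm = set()
            for (i, j) in edges:
                if i == j:
                    raise FormatError(f"self-edge ({i},{i}) in frame {f}")
                if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                    raise FormatError(f"edge ({i},{j}) out of range in frame {f}")
                norm.add((min(i, j), max(i, j)))
            clean.append(frozenset(norm))
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Molecule:
    """A concrete molecule in one frame: its atom indices and its species."""

    atoms: frozenset
    species: Species


@dataclass
class ReactionEvent:
    """One elementary reaction event inferred between frames t and t+1."""

    interval_index: int
    reactants: tuple  # Molecule objects from frame t
    products: tuple  # Molecule objects from frame t+1

    @property
    def atom_set(self) -> frozenset:
        out: set = set()
        for mol in self.reactants:
            out |= mol.atoms
        return frozenset(out)

    @property
    def key(self) -> str:
        lhs = " + ".join(sorted(m.species.label for m in self.reactants))
        rhs = " + ".join(sorted(m.species.label for m in self.products))
        return f"{lhs} => {rhs}"


def _normalize_cutoffs(cutoffs: Mapping) -> dict:
    table = {}
    for pair, value in cutoffs.items():
        if isinstance(pair, str):
            a, b = pair.replace("–", "-").split("-")
        else:
            a, b = pair
        table[tuple(sorted((a.strip(), b.strip())))] = float(value)
    return table


def bond_states_from_coordinates(
    xyz_frames: np.ndarray,
    elements: Sequence[str],
    cutoffs: Mapping,
    frame_dt: float = 1.0,
    box: Sequence[float] | None = None,
) -> BondTrajectory:
    """Raw bond graphs: atoms i, j are bonded in a frame iff their distance
    is ≤ the cutoff for their element pair (minimum-image when ``box`` given)."""
    frames = np.asarray(xyz_frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise FormatError("xyz_frames must have shape (n_frames, n_atoms, 3)")
    n_atoms = frames.shape[1]
    if len(elements) != n_atoms:
        raise FormatError("inconsistent atom count between coordinates and elements")
    table = _normalize_cutoffs(cutoffs)
    kinds = sorted(set(elements))
    for a in kinds:
        for b in kinds:
            if a <= b and (a, b) not in table:
                raise ConfigurationError(f"missing bond cutoff for element pair {a}-{b}")
    iu, ju = np.triu_indices(n_atoms, k=1)
    cut = np.array([table[tuple(sorted((elements[i], elements[j])))] for i, j in zip(iu, ju)])
    box_arr = None if box is None else np.asarray(box, dtype=float)
    bond_frames = []
    for pos in frames:
        d = pos[iu] - pos[ju]
        if box_arr is not None:
            d -= box_arr * np.round(d / box_arr)
        dist = np.sqrt((d * d).sum(axis=1))
        sel = dist <= cut
        bond_frames.append(frozenset(zip(iu[sel].tolist(), ju[sel].tolist())))
    return BondTrajectory(n_atoms=n_atoms, elements=tuple(elements), frames=bond_frames, frame_dt=frame_dt)


def hysteresis_filter(raw: Sequence[bool], tau: int, initial: bool) -> np.ndarray:
    """Smooth a boolean bond signal with the bond duration criterion τ.

    The state flips only after the raw signal has held the opposite value for
    τ consecutive frames, and the flip is recorded retroactively from the
    first frame of that persistent run.  τ = 1 returns the raw series.
    """
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    raw_arr = np.asarray(raw, dtype=bool)
    n = raw_arr.shape[0]
    out = np.empty(n, dtype=bool)
    state = bool(initial)
    run_start = 0
    run_len = 0
    for f in range(n):
        v = bool(raw_arr[f])
        if v != state:
            if run_len == 0:
                run_start = f
            run_len += 1
            if run_len >= tau:
                out[run_start : f + 1] = v
                state = v
                run_len = 0
            else:
                out[f] = state
        else:
            run_len = 0
            out[f] = state
    return out


def filter_bond_trajectory(bond_traj: BondTrajectory, tau: int) -> BondTrajectory:
    """Apply the hysteresis filter to every bond pair ever seen raw-bonded.

    The frame-0 raw state of each pair serves as its initial smoothed state
    (there is no history before the trajectory starts).
    """
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    if tau == 1:
        return bond_traj
    n_frames = bond_traj.n_frames
    pairs = sorted(set().union(*bond_traj.frames)) if n_frames else []
    signals = {p: np.zeros(n_frames, dtype=bool) for p in pairs}
    for f, edges in enumerate(bond_traj.frames):
        for p in edges:
            signals[p][f] = True
    new_frames = [set() for _ in range(n_frames)]
    for p, sig in signals.items():
        smooth = hysteresis_filter(sig, tau, initial=bool(sig[0]))
        for f in np.flatnonzero(smooth):
            new_frames[f].add(p)
    return BondTrajectory(
        n_atoms=bond_traj.n_atoms,
        elements=bond_traj.elements,
        frames=[frozenset(fr) for fr in new_frames],
        frame_dt=bond_traj.frame_dt,
    )


def _frame_molecules(elements, edges, n_atoms, species_cache) -> list:
    if edges:
        arr = np.array(sorted(edges), dtype=np.int64)
        adj = coo_matrix(
            (np.ones(len(arr), dtype=np.int8), (arr[:, 0], arr[:, 1])),
            shape=(n_atoms, n_atoms),
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_atoms)
    groups: dict = {}
    for atom in range(n_atoms):
        groups.setdefault(labels[atom], []).append(atom)
    bonds_by_comp: dict = {}
    for (i, j) in edges:
        key = _pair = tuple(sorted((elements[i], elements[j])))
        bonds_by_comp.setdefault(labels[i], Counter())[key] += 1
    molecules = []
    for comp, atoms in groups.items():
        elem_counts = Counter(elements[a] for a in atoms)
        bond_counts = bonds_by_comp.get(comp, Counter())
        cache_key = (tuple(sorted(elem_counts.items())), tuple(sorted(bond_counts.items())))
        species = species_cache.get(cache_key)
        if species is None:
            species = Species.from_counts(elem_counts, bond_counts)
            species_cache[cache_key] = species
        molecules.append(Molecule(atoms=frozenset(atoms), species=species))
    return molecules


def molecules_per_frame(bond_traj: BondTrajectory):
    """Partition every frame into molecules (connected components).

    Returns ``(partitions, trajectory)`` where ``partitions[f]`` is the list
    of :class:`Molecule` in frame f and ``trajectory`` is the concentration
    trajectory X(t) over all species observed anywhere in the trajectory
    (columns sorted by label).
    """
    cache: dict = {}
    partitions = [
        _frame_molecules(bond_traj.elements, fr, bond_traj.n_atoms, cache)
        for fr in bond_traj.frames
    ]
    all_species = sorted({m.species for part in partitions for m in part}, key=lambda s: s.label)
    index = {s.label: i for i, s in enumerate(all_species)}
    X = np.zeros((len(partitions), len(all_species)), dtype=np.int64)
    for f, part in enumerate(partitions):
        for mol in part:
            X[f, index[mol.species.label]] += 1
    times = np.arange(len(partitions)) * bond_traj.frame_dt
    traj = ConcentrationTrajectory(times=times, X=X, species=[s.label for s in all_species])
    return partitions, traj


def detect_reaction_events(partitions: Sequence[list], frame_dt: float = 1.0):
    """Infer elementary reaction events between consecutive frame partitions.

    A molecule is *unchanged* over an interval when both its atom set and its
    species are identical in the two frames; unchanged molecules are ignored.
    Disappeared (frame t) and appeared (frame t+1) molecules are linked when
    they share atoms, and each connected component of that bipartite graph is
    one :class:`ReactionEvent`.  Distinct event types become reactions of the
    returned network skeleton; ``counts[t, j]`` is the number of events of
    type j in interval t.

    Returns ``(events, count_series, network)``.
    """
    n_frames = len(partitions)
    events: list = []
    for t in range(n_frames - 1):
        cur = {(m.atoms, m.species.label): m for m in partitions[t]}
        nxt = {(m.atoms, m.species.label): m for m in partitions[t + 1]}
        gone = [m for key, m in cur.items() if key not in nxt]
        born = [m for key, m in nxt.items() if key not in cur]
        if not gone and not born:
            continue
        # group via shared atoms (union-find keyed by atom index)
        parent: dict = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x, y):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[ry] = rx

        mols = [(0, m) for m in gone] + [(1, m) for m in born]
        for idx, (_, m) in enumerate(mols):
            parent[("mol", idx)] = ("mol", idx)
            for a in m.atoms:
                if ("atom", a) not in parent:
                    parent[("atom", a)] = ("atom", a)
                union(("mol", idx), ("atom", a))
        groups: dict = {}
        for idx in range(len(mols)):
            groups.setdefault(find(("mol", idx)), []).append(idx)
        for members in groups.values():
            reactants = tuple(mols[i][1] for i in members if mols[i][0] == 0)
            products = tuple(mols[i][1] for i in members if mols[i][0] == 1)
            ev = ReactionEvent(interval_index=t, reactants=reactants, products=products)
            balance = Counter()
            for m in products:
                balance.update(m.species.elements)
            for m in reactants:
                balance.subtract(m.species.elements)
            if any(balance.values()):
                raise InconsistencyError(f"atom imbalance within event at interval {t}: {ev.key}")
            events.append(ev)

    # build the network skeleton and the count series
    type_order: list = []
    type_index: dict = {}
    for ev in events:
        if ev.key not in type_index:
            type_index[ev.key] = len(type_order)
            type_order.append(ev)
    all_species = sorted(
        {m.species for part in partitions for m in part}, key=lambda s: s.label
    )
    reactions = []
    for ev in type_order:
        reactions.append(
            Reaction(
                reactants=tuple(m.species for m in ev.reactants),
                products=tuple(m.species for m in ev.products),
                rate_k=0.0,
            )
        )
    counts = np.zeros((max(n_frames - 1, 0), len(reactions)), dtype=np.int64)
    for ev in events:
        counts[ev.interval_index, type_index[ev.key]] += 1
    for j, rx in enumerate(reactions):
        rx.observed_count_total = int(counts[:, j].sum())
    network = ReactionNetwork(species=all_species, reactions=reactions, dt=frame_dt)
    series = ReactionCountSeries(counts=counts, reactions=[rx.key for rx in reactions])
    return events, series, network


# ---------------------------------------------------------------------------
# readers / writers

def read_xyz(path) -> tuple:
    """Read a multi-frame (extended) XYZ file → (coords (F, n, 3), elements)."""
    frames = []
    elements = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines):
        line = lines[pos].strip()
        if not line:
            pos += 1
            continue
        try:
            n = int(line)
        except ValueError as exc:
            raise FormatError(f"expected atom count at line {pos + 1}") from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise FormatError("truncated XYZ frame")
        els, coords = [], []
        for row in block:
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"malformed XYZ atom line: {row!r}")
            els.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise FormatError("inconsistent atoms across XYZ frames")
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise FormatError("empty XYZ file")
    return np.array(frames, dtype=float), tuple(elements)


def read_bond_list(path, elements: Sequence[str], frame_dt: float = 1.0) -> BondTrajectory:
    """Read the plain bond-list format: ``frame_index i j [i j ...]`` per line."""
    rows = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            idx = int(parts[0])
            atoms = [int(x) for x in parts[1:]]
            if len(atoms) % 2:
                raise FormatError(f"odd number of atom indices on line {ln}")
            rows[idx] = frozenset(
                (min(a, b), max(a, b)) for a, b in zip(atoms[::2], atoms[1::2])
            )
    if not rows:
        raise FormatError("empty bond-list file")
    n_frames = max(rows) + 1
    frames = [rows.get(i, frozenset()) for i in range(n_frames)]
    return BondTrajectory(
        n_atoms=len(elements), elements=tuple(elements), frames=frames, frame_dt=frame_dt
    )


def write_bond_list(bond_traj: BondTrajectory, path) -> None:
    with open(path, "w") as fh:
        for f, edges in enumerate(bond_traj.frames):
            flat = " ".join(f"{i} {j}" for i, j in sorted(edges))
            fh.write(f"{f} {flat}".rstrip() + "\n")
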