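"""Core domain types: species, reactions, networks, trajectories and count series.

Species are identified purely by their element composition and bond-type
counts (e.g. ``C1 H4 4(H–C)``), the same dialect used to label molecules
extracted from reactive trajectories.  This identity cannot distinguish
structural isomers that share both formula and bond-type totals; that is a
documented limitation of the labelling scheme, not a bug.

Concentrations throughout the package are dimensionless molecule counts in a
fixed simulation volume; no molarity conversion is performed.
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ConcentrationTrajectory",
    "ReactionCountSeries",
    "canonical_label",
    "validate_network",
    "network_to_json",
    "network_from_json",
    "network_to_csv",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "counts_to_csv",
]

#: Canonical element ordering for labels: carbon, hydrogen, then alphabetical.
_PRIORITY = {"C": 0, "H": 1}


def _element_key(el: str):
    return (_PRIORITY.get(el, 2), el)


def _pair_key(pair):
    a, b = sorted(pair, key=_element_key)
    return (a, b)


def _pair_text(pair) -> str:
    # Bond types render with the later element first, matching the
    # ``n(H–C)`` style: (C,C) -> "C–C", (C,H) -> "H–C", (H,H) -> "H–H".
    a, b = _pair_key(pair)
    return f"{b}–{a}" if a != b else f"{a}–{b}"


def canonical_label(element_counts: Mapping[str, int], bond_counts: Mapping | None = None) -> str:
    """Render the canonical text label of a molecule.

    Elements appear as ``<El><count>`` in fixed order (C, H, then
    alphabetical), followed by each nonzero bond type as ``<n>(<El>–<El>)``
    in fixed pair order ((C–C), (H–C), (H–H), then alphabetical).  A single
    atom has no bond part.
    """
    elements = {el: int(n) for el, n in element_counts.items() if int(n) != 0}
    if not elements:
        raise InvalidInputError("empty molecule: no atoms")
    if any(n < 0 for n in elements.values()):
        raise InvalidInputError("negative element count")
    bonds = {}
    for pair, n in (bond_counts or {}).items():
        n = int(n)
        if n < 0:
            raise InvalidInputError("negative bond count")
        if n:
            key = _pair_key(tuple(pair))
            bonds[key] = bonds.get(key, 0) + n
    parts = [f"{el}{elements[el]}" for el in sorted(elements, key=_element_key)]
    for pair in sorted(bonds, key=lambda p: (_element_key(p[0]), _element_key(p[1]))):
        parts.append(f"{bonds[pair]}({_pair_text(pair)})")
    return " ".join(parts)


@dataclass(frozen=True)
class Species:
    """A molecule type identified by element counts and bond-type counts."""

    element_counts: tuple  # sorted ((element, count), ...)
    bond_counts: tuple  # sorted (((el_a, el_b), count), ...)
    label: str

    @classmethod
    def from_counts(cls, element_counts: Mapping[str, int], bond_counts: Mapping | None = None) -> "Species":
        label = canonical_label(element_counts, bond_counts)
        elems = tuple(sorted(((el, int(n)) for el, n in element_counts.items() if n), key=lambda t: _element_key(t[0])))
        bonds = {}
        for pair, n in (bond_counts or {}).items():
            if n:
                key = _pair_key(tuple(pair))
                bonds[key] = bonds.get(key, 0) + int(n)
        bond_t = tuple(sorted(bonds.items()))
        return cls(elems, bond_t, label)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.element_counts)

    @property
    def elements(self) -> dict:
        return dict(self.element_counts)

    def __eq__(self, other):
        return isinstance(other, Species) and self.label == other.label

    def __hash__(self):
        return hash(self.label)

    def __repr__(self):
        return f"Species({self.label!r})"


@dataclass
class Reaction:
    """A reaction between species multisets, with its rate coefficient.

    ``rate_k`` carries units of count^(1-order) / time; ``observed_count_total``
    is the total number of firings seen in the trajectory the reaction was
    extracted from (0 when unknown).
    """

    reactants: tuple  # sorted tuple of Species (with multiplicity)
    products: tuple
    rate_k: float = 0.0
    observed_count_total: int = 0

    def __post_init__(self):
        self.reactants = tuple(sorted(self.reactants, key=lambda s: s.label))
        self.products = tuple(sorted(self.products, key=lambda s: s.label))
        if self.rate_k < 0:
            raise InvalidInputError("rate_k must be non-negative")
        if len(self.reactants) < 1:
            raise InvalidInputError("reaction order must be >= 1")

    @property
    def order(self) -> int:
        return len(self.reactants)

    @property
    def key(self) -> str:
        """Canonical reactant ⇒ product equation; reaction identity."""
        lhs = " + ".join(s.label for s in self.reactants)
        rhs = " + ".join(s.label for s in self.products)
        return f"{lhs} => {rhs}"

    def reactant_multiplicities(self) -> dict:
        return dict(Counter(self.reactants))

    def element_balance(self) -> dict:
        """Per-element atom difference products − reactants (all zero iff balanced)."""
        delta: Counter = Counter()
        for s in self.products:
            for el, n in s.element_counts:
                delta[el] += n
        for s in self.reactants:
            for el, n in s.element_counts:
                delta[el] -= n
        return {el: d for el, d in delta.items() if d}

    def stoich(self, species_order: Sequence[Species]) -> np.ndarray:
        """Column vector R_j: net species change per firing (products − reactants)."""
        index = {s.label: i for i, s in enumerate(species_order)}
        v = np.zeros(len(species_order), dtype=np.int64)
        for s in self.products:
            v[index[s.label]] += 1
        for s in self.reactants:
            v[index[s.label]] -= 1
        return v

    def __repr__(self):
        return f"Reaction({self.key!r}, k={self.rate_k:g})"


@dataclass
class ReactionNetwork:
    """An ordered set of m species and r reactions sampled at interval dt."""

    species: list
    reactions: list
    dt: float = 1.0

    @property
    def m(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def species_labels(self) -> list:
        return [s.label for s in self.species]

    def species_index(self) -> dict:
        return {s.label: i for i, s in enumerate(self.species)}

    def stoich_matrix(self) -> np.ndarray:
        """m × r stoichiometry matrix R; column j is reaction j's net change."""
        R = np.zeros((self.m, self.r), dtype=np.int64)
        for j, rx in enumerate(self.reactions):
            R[:, j] = rx.stoich(self.species)
        return R

    def rates(self) -> np.ndarray:
        return np.array([rx.rate_k for rx in self.reactions], dtype=float)

    def reaction_keys(self) -> list:
        return [rx.key for rx in self.reactions]


@dataclass
class ConcentrationTrajectory:
    """Species counts X(t) on a strictly increasing time grid (T+1 rows)."""

    times: np.ndarray
    X: np.ndarray
    species: list = field(default_factory=list)  # species labels, one per column

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.X = np.asarray(self.X)
        if self.X.ndim != 2 or self.X.shape[0] != self.times.shape[0]:
            raise InvalidInputError("X must be (len(times), m)")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.X < 0):
            raise InvalidInputError("species counts must be non-negative")

    @property
    def n_steps(self) -> int:
        return self.X.shape[0] - 1

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class ReactionCountSeries:
    """Per-interval firing counts: entry (t, j) = n_j(t, t+Δt)."""

    counts: np.ndarray
    reactions: list = field(default_factory=list)  # reaction keys, one per column

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidInputError("counts must be a T × r matrix")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def validate_network(network: ReactionNetwork) -> list:
    """Check atom balance and structural invariants; returns violation records.

    Empty list means the network is valid.  This is a reporting operation
    and never raises.
    """
    violations = []
    labels = network.species_labels
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        violations.append({"kind": "duplicate-species", "detail": dupes})
    index = set(labels)
    for j, rx in enumerate(network.reactions):
        imbalance = rx.element_balance()
        if imbalance:
            violations.append({"kind": "atom-balance", "reaction": j, "key": rx.key, "detail": imbalance})
        missing = [s.label for s in (*rx.reactants, *rx.products) if s.label not in index]
        if missing:
            violations.append({"kind": "unknown-species", "reaction": j, "key": rx.key, "detail": missing})
    return violations


# ---------------------------------------------------------------------------
# serialization

def _species_to_dict(s: Species) -> dict:
    return {
        "label": s.label,
        "element_counts": {el: n for el, n in s.element_counts},
        "bond_counts": {f"{a}|{b}": n for (a, b), n in s.bond_counts},
    }


def _species_from_dict(d: dict) -> Species:
    bonds = {tuple(k.split("|")): v for k, v in d.get("bond_counts", {}).items()}
    return Species.from_counts(d["element_counts"], bonds)


def network_to_json(network: ReactionNetwork) -> str:
    """Canonical JSON rendering; serialize → parse → serialize is byte-identical."""
    doc = {
        "dt": network.dt,
        "species": [_species_to_dict(s) for s in network.species],
        "reactions": [
            {
                "reactants": [s.label for s in rx.reactants],
                "products": [s.label for s in rx.products],
                "rate_k": rx.rate_k,
                "observed_count_total": rx.observed_count_total,
            }
            for rx in network.reactions
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    species = [_species_from_dict(d) for d in doc["species"]]
    by_label = {s.label: s for s in species}
    reactions = []
    for rd in doc["reactions"]:
        reactions.append(
            Reaction(
                reactants=tuple(by_label[l] for l in rd["reactants"]),
                products=tuple(by_label[l] for l in rd["products"]),
                rate_k=float(rd["rate_k"]),
                observed_count_total=int(rd.get("observed_count_total", 0)),
            )
        )
    return ReactionNetwork(species=species, reactions=reactions, dt=float(doc["dt"]))


def network_to_csv(network: ReactionNetwork) -> str:
    """Flat CSV: one reaction per row with its textual equation and rate."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["reaction", "order", "rate_k", "observed_count_total"])
    for rx in network.reactions:
        w.writerow([rx.key, rx.order, repr(rx.rate_k), rx.observed_count_total])
    return buf.getvalue()


def trajectory_to_csv(traj: ConcentrationTrajectory) -> str:
    import pandas as pd

    cols = traj.species or [f"species_{i}" for i in range(traj.m)]
    df = pd.DataFrame(traj.X, columns=cols)
    df.insert(0, "time", traj.times)
    return df.to_csv(index=False)


def trajectory_from_csv(text: str) -> ConcentrationTrajectory:
    import pandas as pd

    df = pd.read_csv(io.StringIO(text))
    times = df["time"].to_numpy()
    species = [c for c in df.columns if c != "time"]
    return ConcentrationTrajectory(times=times, X=df[species].to_numpy(), species=species)


def counts_to_csv(series: ReactionCountSeries) -> str:
    import pandas as pd

    cols = series.reactions or [f"reaction_{j}" for j in range(series.counts.shape[1])]
    df = pd.DataFrame(series.counts, columns=cols)
    df.insert(0, "interval", np.arange(series.counts.shape[0]))
    return df.to_csv(index=False)
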