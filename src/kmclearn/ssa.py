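"""Exact Gillespie stochastic simulation (direct method) of a reaction network.

Each step draws the waiting time τ ~ Exponential(a₀(x)) and the reaction index
j with probability a_j(x)/a₀(x), where a_j = k_j·h_j(x), then applies the
stoichiometric update x ← x + R_j.  Two uniform deviates per step; one seeded
generator per simulation, so identical seeds give identical trajectories.
When a₀ = 0 the system is frozen: simulation advances silently to t_end and
flags the trajectory.  By construction no reaction outside the network ever
fires, and species counts can never go negative (h_j = 0 whenever reactant
molecules are insufficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ParameterError
from .estimate import reactant_combinations, _multiplicity_matrix
from .network import ConcentrationTrajectory, ReactionCountSeries, ReactionNetwork

__all__ = [
    "EventTrajectory",
    "simulate_ssa",
    "sample_trajectory",
    "bin_event_counts",
    "simulate_ensemble",
]


@dataclass
class EventTrajectory:
    """An exact realization: initial state plus the ordered reaction events."""

    x0: np.ndarray
    times: np.ndarray  # event times, strictly increasing
    reaction_indices: np.ndarray
    t_end: float
    r: int  # number of reactions in the generating network
    species: list = field(default_factory=list)
    frozen: bool = False  # True when a₀ hit 0 before t_end

    @property
    def n_events(self) -> int:
        return len(self.times)


def _propensity_row(x, NU, k):
    h = np.ones(NU.shape[0])
    for j in range(NU.shape[0]):
        for sidx in np.flatnonzero(NU[j]):
            nu = NU[j, sidx]
            xv = float(x[sidx])
            if xv < nu:
                h[j] = 0.0
                break
            if nu == 1:
                h[j] *= xv
            elif nu == 2:
                h[j] *= xv * (xv - 1) / 2.0
            else:
                h[j] *= xv * (xv - 1) * (xv - 2) / 6.0
    return h * k


def simulate_ssa(
    network: ReactionNetwork,
    x0,
    t_end: float,
    seed: int | np.random.Generator = 0,
) -> EventTrajectory:
    """Run one exact SSA realization from x0 to t_end."""
    x = np.asarray(x0, dtype=np.int64).copy()
    if x.shape != (network.m,):
        raise InvalidInputError(f"x0 must have length m={network.m}")
    if np.any(x < 0):
        raise InvalidInputError("x0 must be non-negative")
    if t_end <= 0:
        raise ParameterError("t_end must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = network.stoich_matrix()
    NU = _multiplicity_matrix(network)
    k = network.rates()
    t = 0.0
    times: list = []
    events: list = []
    frozen = False
    while True:
        a = _propensity_row(x, NU, k)
        a0 = a.sum()
        if a0 <= 0.0:
            frozen = True
            break
        u1 = rng.random()
        u2 = rng.random()
        t += -np.log(u1) / a0
        if t > t_end:
            break
        j = int(np.searchsorted(np.cumsum(a), u2 * a0))
        x += R[:, j]
        times.append(t)
        events.append(j)
    return EventTrajectory(
        x0=np.asarray(x0, dtype=np.int64).copy(),
        times=np.array(times, dtype=float),
        reaction_indices=np.array(events, dtype=np.int64),
        t_end=float(t_end),
        r=network.r,
        species=network.species_labels,
        frozen=frozen,
    )


def sample_trajectory(
    event_traj: EventTrajectory,
    times,
    stoich_matrix: np.ndarray | None = None,
    network: ReactionNetwork | None = None,
) -> ConcentrationTrajectory:
    """Evaluate the piecewise-constant (right-continuous) state at fixed times.

    X(s) includes the effect of any event occurring exactly at time s.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() > event_traj.t_end):
        raise InvalidInputError("sample time outside [0, t_end]")
    if stoich_matrix is None:
        if network is None:
            raise InvalidInputError("need stoich_matrix or network to sample")
        stoich_matrix = network.stoich_matrix()
    m = event_traj.x0.shape[0]
    # cumulative state after each event
    if event_traj.n_events:
        deltas = stoich_matrix[:, event_traj.reaction_indices].T  # (n_events, m)
        states = event_traj.x0[None, :] + np.cumsum(deltas, axis=0)
        idx = np.searchsorted(event_traj.times, times, side="right")
        X = np.where(
            idx[:, None] == 0,
            event_traj.x0[None, :],
            states[np.maximum(idx - 1, 0)],
        )
    else:
        X = np.tile(event_traj.x0, (times.size, 1))
    return ConcentrationTrajectory(times=times, X=X.astype(np.int64), species=list(event_traj.species))


def bin_event_counts(event_traj: EventTrajectory, dt: float) -> ReactionCountSeries:
    """Bin firings into the tau-leaping observation format n_j(t, t+Δt).

    Bins are half-open [t·dt, (t+1)·dt): an event exactly on a boundary is
    assigned to the later bin.  The count total equals the event total.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    T = max(int(np.ceil(event_traj.t_end / dt)), 1)
    counts = np.zeros((T, event_traj.r), dtype=np.int64)
    if event_traj.n_events:
        bins = np.minimum((event_traj.times / dt).astype(np.int64), T - 1)
        np.add.at(counts, (bins, event_traj.reaction_indices), 1)
    return ReactionCountSeries(counts=counts)


def simulate_ensemble(
    network: ReactionNetwork,
    x0,
    t_end: float,
    n_replicates: int,
    seed: int,
    sample_times,
) -> np.ndarray:
    """Run S independent replicates (seeds seed, seed+1, ...) and sample each.

    Returns an (S, len(sample_times), m) integer array.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    R = network.stoich_matrix()
    out = np.empty((n_replicates, sample_times.size, network.m), dtype=np.int64)
    for s in range(n_replicates):
        traj = simulate_ssa(network, x0, t_end, seed=seed + s)
        out[s] = sample_trajectory(traj, sample_times, stoich_matrix=R).X
    return out
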