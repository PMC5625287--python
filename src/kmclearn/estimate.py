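"""Propensity combinatorics and Poisson maximum-likelihood rate estimation.

Under the tau-leaping approximation the number of firings of reaction j in
[t, t+Δt) is Poisson with mean μ_j = k_j · h_j(X(t)) · Δt, where h_j counts
the distinct reactant tuples available at state X(t).  The per-reaction MLE
then has the closed form

    k̂_j = Σ_t n_j(t, t+Δt) / (Δt · Σ_t h_j(X(t))).

Rates for rarely possible reactions (few intervals with h_j > 0) are likely
overestimates; they are retained here and dealt with by model reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import InconsistencyError, InvalidInputError, ParameterError
from .network import ConcentrationTrajectory, ReactionCountSeries, ReactionNetwork

__all__ = [
    "combinatorial_count",
    "reactant_combinations",
    "estimate_rates",
    "RateEstimates",
    "poisson_log_likelihood",
    "rate_table",
]


def combinatorial_count(reactant_multiplicities, X) -> int:
    """Number of distinct reactant tuples h_j at species counts X.

    ``reactant_multiplicities`` maps a species key (or column index) to its
    stoichiometric multiplicity ν; ``X`` maps the same keys to counts.
    h = Π_m C(X_m, ν_m): X_m for unimolecular, X_m·X_m' for distinct
    bimolecular pairs, C(X_m, 2) for identical pairs, and the same choose
    rule for any higher multiplicities.  Returns 0 when any X_m < ν_m.
    """
    h = 1
    for key, nu in reactant_multiplicities.items():
        if nu < 1:
            raise InvalidInputError("reactant multiplicity must be >= 1")
        x = int(X[key])
        if x < 0:
            raise InvalidInputError("negative species count")
        if x < nu:
            return 0
        h *= math.comb(x, nu)
    return h


def _multiplicity_matrix(network: ReactionNetwork) -> np.ndarray:
    """(r, m) matrix of reactant multiplicities ν."""
    index = network.species_index()
    NU = np.zeros((network.r, network.m), dtype=np.int64)
    for j, rx in enumerate(network.reactions):
        for sp, nu in rx.reactant_multiplicities().items():
            NU[j, index[sp.label]] = nu
    return NU


def reactant_combinations(network: ReactionNetwork, X: np.ndarray) -> np.ndarray:
    """Vectorized h_j(X(t)) for every row of X: returns an (T, r) float array.

    Equivalent to calling :func:`combinatorial_count` per (row, reaction);
    float-valued for speed (exact for the molecule counts this package deals
    in, far below the float53 integer limit).
    """
    X = np.atleast_2d(np.asarray(X))
    NU = _multiplicity_matrix(network)  # (r, m)
    H = np.ones((X.shape[0], network.r))
    for j in range(network.r):
        nz = np.flatnonzero(NU[j])
        for sidx in nz:
            nu = NU[j, sidx]
            x = X[:, sidx].astype(float)
            if nu == 1:
                f = x
            elif nu == 2:
                f = x * (x - 1) / 2.0
            elif nu == 3:
                f = x * (x - 1) * (x - 2) / 6.0
            else:  # pragma: no cover - orders > 3 unused in practice
                from scipy.special import comb

                f = comb(x, nu)
            H[:, j] *= np.maximum(f, 0.0)
    return H


@dataclass
class RateEstimates:
    """MLE rate coefficients with per-reaction observation diagnostics."""

    k: np.ndarray  # k̂_j; NaN where undefined (never possible, never observed)
    total_counts: np.ndarray  # Σ_t n_j
    informative_intervals: np.ndarray  # #{t : h_j(X(t)) > 0}, a confidence proxy
    total_h: np.ndarray  # Δt-free Σ_t h_j(X(t))

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.k)


def estimate_rates(
    network: ReactionNetwork,
    counts: ReactionCountSeries,
    trajectory: ConcentrationTrajectory,
    dt: float | None = None,
) -> RateEstimates:
    """Closed-form Poisson MLE of every rate coefficient.

    Row t of ``counts`` conditions on row t of ``trajectory`` (which has one
    extra trailing row).  Reactions observed in intervals where they were
    never possible raise :class:`InconsistencyError`; reactions never possible
    and never observed get k̂ = NaN (undefined, reported as absent).
    """
    dt = network.dt if dt is None else dt
    if dt <= 0:
        raise ParameterError("dt must be positive")
    n = np.asarray(counts.counts, dtype=float)
    T = n.shape[0]
    if trajectory.X.shape[0] < T:
        raise InvalidInputError("trajectory shorter than count series")
    H = reactant_combinations(network, trajectory.X[:T])
    total_n = n.sum(axis=0)
    total_h = H.sum(axis=0)
    informative = (H > 0).sum(axis=0)
    k = np.full(network.r, np.nan)
    for j in range(network.r):
        if total_h[j] > 0:
            k[j] = total_n[j] / (dt * total_h[j])
        elif total_n[j] > 0:
            raise InconsistencyError(
                f"reaction {j} ({network.reactions[j].key}) observed "
                f"{int(total_n[j])} times but never possible"
            )
    return RateEstimates(
        k=k,
        total_counts=total_n.astype(np.int64),
        informative_intervals=informative.astype(np.int64),
        total_h=total_h,
    )


def apply_rates(network: ReactionNetwork, estimates: RateEstimates) -> ReactionNetwork:
    """Return a copy of the network with estimated rates set (NaN → 0)."""
    from copy import deepcopy

    out = deepcopy(network)
    for j, rx in enumerate(out.reactions):
        rx.rate_k = 0.0 if np.isnan(estimates.k[j]) else float(estimates.k[j])
    return out


def poisson_log_likelihood(
    network: ReactionNetwork,
    counts: ReactionCountSeries,
    trajectory: ConcentrationTrajectory,
    dt: float | None = None,
) -> float:
    """Tau-leaping Poisson log-likelihood of the counts under the network rates.

    ℓ = Σ_t Σ_j [ n log μ − μ − log n! ] with μ_j = k_j h_j(X(t)) Δt.
    Terms with μ = 0 and n = 0 contribute 0; μ = 0 with n > 0 yields -inf
    (returned, not raised).
    """
    dt = network.dt if dt is None else dt
    n = np.asarray(counts.counts, dtype=float)
    T = n.shape[0]
    H = reactant_combinations(network, trajectory.X[:T])
    mu = H * network.rates()[None, :] * dt
    ll = 0.0
    impossible = (mu == 0) & (n > 0)
    if impossible.any():
        return -np.inf
    pos = mu > 0
    ll = float(
        np.sum(n[pos] * np.log(mu[pos]) - mu[pos] - gammaln(n[pos] + 1.0))
    )
    return ll


def rate_table(network: ReactionNetwork, estimates: RateEstimates):
    """Per-reaction rate table (pandas DataFrame, CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "reaction": network.reaction_keys(),
            "order": [rx.order for rx in network.reactions],
            "k_est": estimates.k,
            "total_count": estimates.total_counts,
            "informative_intervals": estimates.informative_intervals,
        }
    )
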