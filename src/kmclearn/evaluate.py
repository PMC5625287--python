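"""Error metrics, bond-duration (τ) model selection, and support comparison.

Two RMSE-style metrics are used, both per species and in molecule-count
units:

* :func:`rmse_vs_reference` — RMSE between the *mean* of S stochastic
  replicates and a single reference trajectory; the metric used against the
  source (e.g. MD-derived) concentration trajectory.
* :func:`mean_error_between_models` — the mean over replicates of each
  replicate's own RMSE against a reference mean trajectory; the metric used
  when comparing two stochastic models.  By Jensen's inequality it is never
  smaller than the first metric on the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, ParameterError
from .estimate import apply_rates, estimate_rates
from .extract import BondTrajectory, detect_reaction_events, filter_bond_trajectory, molecules_per_frame
from .network import ConcentrationTrajectory, ReactionNetwork
from .ssa import simulate_ensemble

__all__ = [
    "ErrorReport",
    "rmse_vs_reference",
    "mean_error_between_models",
    "select_bond_duration",
    "compare_supports",
    "SupportOverlap",
]


@dataclass
class ErrorReport:
    """Per-species error (molecule counts) with provenance metadata."""

    per_species: dict  # label -> error, all >= 0
    n_replicates: int
    reference: str = ""
    metric: str = ""
    burn_in: float = 0.0

    def mean(self) -> float:
        return float(np.mean(list(self.per_species.values()))) if self.per_species else 0.0


def _stack_replicates(sim_trajectories, reference: ConcentrationTrajectory):
    """Validate alignment and return (S, T, m) array restricted to ref species."""
    arrs = []
    for traj in sim_trajectories:
        if isinstance(traj, ConcentrationTrajectory):
            if traj.X.shape[0] != reference.X.shape[0] or not np.allclose(
                traj.times, reference.times
            ):
                raise InvalidInputError("replicate and reference time grids differ")
            X = traj.X
            if traj.species and reference.species and traj.species != reference.species:
                idx = [traj.species.index(l) for l in reference.species]
                X = X[:, idx]
            arrs.append(X)
        else:
            arrs.append(np.asarray(traj))
    sims = np.array(arrs, dtype=float)
    if sims.shape[1:] != reference.X.shape:
        raise InvalidInputError("replicates and reference have mismatched shapes")
    return sims


def _apply_burn_in(times, burn_in):
    keep = times >= burn_in
    if not keep.any():
        raise ParameterError("burn_in removes every sample")
    return keep


def rmse_vs_reference(
    sim_trajectories, reference: ConcentrationTrajectory, burn_in: float = 0.0
) -> ErrorReport:
    """Per-species RMSE of the replicate-ensemble mean against the reference."""
    sims = _stack_replicates(sim_trajectories, reference)
    keep = _apply_burn_in(reference.times, burn_in)
    mean_sim = sims[:, keep].mean(axis=0)
    err = np.sqrt(((mean_sim - reference.X[keep]) ** 2).mean(axis=0))
    labels = reference.species or [f"species_{i}" for i in range(reference.m)]
    return ErrorReport(
        per_species=dict(zip(labels, err.tolist())),
        n_replicates=sims.shape[0],
        metric="rmse_of_mean",
        burn_in=burn_in,
    )


def mean_error_between_models(
    sim_trajectories, reference_mean: ConcentrationTrajectory, burn_in: float = 0.0
) -> ErrorReport:
    """Mean over replicates of each replicate's RMSE against a reference mean.

    With S = 1 this reduces to the plain RMSE of that replicate.
    """
    sims = _stack_replicates(sim_trajectories, reference_mean)
    keep = _apply_burn_in(reference_mean.times, burn_in)
    per_rep = np.sqrt(((sims[:, keep] - reference_mean.X[None, keep]) ** 2).mean(axis=1))
    err = per_rep.mean(axis=0)
    labels = reference_mean.species or [f"species_{i}" for i in range(reference_mean.m)]
    return ErrorReport(
        per_species=dict(zip(labels, err.tolist())),
        n_replicates=sims.shape[0],
        metric="mean_of_rmse",
        burn_in=burn_in,
    )


def select_bond_duration(
    bond_traj: BondTrajectory,
    tau_grid,
    n_replicates: int = 10,
    seed: int = 0,
    species=None,
    burn_in: float = 0.0,
):
    """Pick the bond duration τ by model selection.

    For each τ in the grid: smooth the bond trajectory, extract the network
    and estimate its rates, run S stochastic replicates from the τ-specific
    initial state, and score the replicate mean against the τ-specific source
    concentrations (per-species RMSE averaged over ``species``, default: all
    extracted species).  Returns ``(tau_star, curve)`` where the curve is a
    list of (τ, error, n_reactions); ties go to the smaller τ.

    A τ so large that no events survive yields an empty network; the frozen
    system is simulated as-is and scored normally.  Note the degenerate limit:
    because each τ is scored against its own τ-smoothed concentrations, a τ
    exceeding every bond lifetime freezes both model and reference and scores
    a trivial 0 — keep the grid well below the data span.
    """
    tau_grid = sorted(set(int(t) for t in tau_grid))
    if len(tau_grid) < 2:
        raise ParameterError("tau_grid needs at least two values")
    curve = []
    for tau in tau_grid:
        smooth = filter_bond_trajectory(bond_traj, tau)
        partitions, conc = molecules_per_frame(smooth)
        _, series, skeleton = detect_reaction_events(partitions, frame_dt=bond_traj.frame_dt)
        est = estimate_rates(skeleton, series, conc)
        model = apply_rates(skeleton, est)
        x0 = conc.X[0]
        sims = simulate_ensemble(
            model, x0, t_end=float(conc.times[-1]) or bond_traj.frame_dt,
            n_replicates=n_replicates, seed=seed, sample_times=conc.times,
        )
        report = rmse_vs_reference(
            [ConcentrationTrajectory(conc.times, s, species=conc.species) for s in sims],
            conc,
            burn_in=burn_in,
        )
        chosen = species if species is not None else list(report.per_species)
        vals = [report.per_species[l] for l in chosen if l in report.per_species]
        err = float(np.mean(vals)) if vals else float("inf")
        curve.append((tau, err, model.r))
    tau_star = min(curve, key=lambda row: (row[1], row[0]))[0]
    return tau_star, curve


@dataclass
class SupportOverlap:
    """Overlap statistics of reaction supports across networks."""

    common_fraction: float  # |intersection| / |union|
    jaccard: np.ndarray  # pairwise Jaccard similarity matrix
    union_size: int
    common_size: int


def compare_supports(networks) -> SupportOverlap:
    """Fraction of the reaction union present in all networks + pairwise Jaccard.

    Reaction identity is the canonical ``reactants => products`` equation.
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ParameterError("need at least two networks to compare")
    supports = [set(net.reaction_keys()) for net in networks]
    union = set().union(*supports)
    common = set.intersection(*supports) if supports else set()
    n = len(supports)
    J = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u = supports[i] | supports[j]
            J[i, j] = J[j, i] = (len(supports[i] & supports[j]) / len(u)) if u else 1.0
    frac = (len(common) / len(union)) if union else 1.0
    return SupportOverlap(
        common_fraction=frac, jaccard=J, union_size=len(union), common_size=len(common)
    )
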