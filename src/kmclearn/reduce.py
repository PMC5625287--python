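"""Model reduction: count filtering, the conditional-moments IQP, and its
box-constrained LASSO relaxation.

The conditional-moments construction works with the per-step change in
species counts y_{t+1} = X(t+1) − X(t), which under the tau-leaping model is
a linear combination of independent Poisson variables.  Its conditional mean
and covariance are linear in the rate coefficients, so stacking the mean
(m rows) and upper-triangular covariance (m(m+1)/2 rows) blocks over T
sampled states gives a tall linear system A k = b, where k is the rate
vector scaled by the maximum-likelihood estimates so that k = 1 is an exact
solution (b = A·1).  Reduction then seeks a sparse k:

* IQP:   min ‖Ak − b‖²  s.t. k ∈ {0,1}^r, Σ k ≤ λ   (exact, branch-and-bound)
* LASSO: min ‖Ak − b‖²  s.t. k ∈ [0,1]^r, Σ k ≤ λ   (convex relaxation),
  followed by ε-thresholding of near-zero entries (default ε = 0.01).

Only AᵀA and Aᵀb are ever required, so the system is accumulated streaming
over sampled states; the explicit A is kept only for small problems.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass, field

import numpy as np

from .errors import CapabilityError, ConvergenceError, ParameterError
from .estimate import reactant_combinations
from .network import ConcentrationTrajectory, ReactionCountSeries, ReactionNetwork

__all__ = [
    "MomentSystem",
    "ReductionResult",
    "count_based_reduce",
    "build_moment_system",
    "reduce_iqp",
    "reduce_lasso",
    "lambda_sweep",
]

_DENSE_ROW_LIMIT = 100_000


@dataclass
class MomentSystem:
    """Normal equations AᵀA, Aᵀb of the conditional-moments linear system."""

    normal_matrix: np.ndarray  # r × r, symmetric PSD
    normal_vector: np.ndarray  # length r
    b_norm_sq: float  # bᵀb (so the full objective ‖Ak − b‖² is available)
    row_count: int  # T · (m + m(m+1)/2)
    k_est: np.ndarray  # the column scaling applied
    network: ReactionNetwork
    A: np.ndarray | None = None  # explicit system for small problems
    b: np.ndarray | None = None

    @property
    def r(self) -> int:
        return self.normal_vector.shape[0]

    def objective(self, k) -> float:
        """‖Ak − b‖² evaluated via the normal equations."""
        k = np.asarray(k, dtype=float)
        return float(k @ self.normal_matrix @ k - 2.0 * self.normal_vector @ k + self.b_norm_sq)


def _moment_basis(network: ReactionNetwork) -> np.ndarray:
    """Stack of the mean block R and covariance block: column j is
    [R_j ; triu(R_j R_jᵀ)], the state-independent part of A's column j."""
    R = network.stoich_matrix().astype(float)
    m = network.m
    iu, ju = np.triu_indices(m)
    U = R[iu, :] * R[ju, :]  # (m(m+1)/2, r)
    return np.vstack([R, U])


def _weights(network: ReactionNetwork, samples, dt: float) -> np.ndarray:
    """W (T_total, r): w_tj = k_est_j · h_j(X(t)) · Δt over all sampled states.

    ``samples`` is a ConcentrationTrajectory or a list of them (pooled
    replicates); the last row of each trajectory is not a conditioning state.
    """
    if isinstance(samples, ConcentrationTrajectory):
        samples = [samples]
    k_est = network.rates()
    if np.any(k_est <= 0):
        raise ParameterError(
            "all included reactions need k_est > 0; drop zero-rate reactions first"
        )
    order = network.species_labels
    blocks = []
    for traj in samples:
        X = traj.X[:-1]
        if traj.species and list(traj.species) != order:
            idx = [traj.species.index(l) for l in order]
            X = X[:, idx]
        blocks.append(reactant_combinations(network, X))
    H = np.vstack(blocks)
    return H * k_est[None, :] * dt


def build_moment_system(
    network: ReactionNetwork,
    samples,
    dt: float | None = None,
    reference: ReactionNetwork | None = None,
    store_dense: bool | str = "auto",
) -> MomentSystem:
    """Accumulate the conditional-moments system for ``network``.

    ``reference`` supplies the right-hand side b (the moments the reduced
    model should reproduce).  By default it is the network itself, so b = A·1
    exactly and k = 1 solves the system.  Passing a different reference (e.g.
    the data-generating subnetwork in a spurious-reaction experiment) builds
    b from that model's moments instead; it must share the species set.
    """
    dt = network.dt if dt is None else dt
    if dt <= 0:
        raise ParameterError("dt must be positive")
    ref = network if reference is None else reference
    if ref.species_labels != network.species_labels and sorted(ref.species_labels) != sorted(
        network.species_labels
    ):
        raise ParameterError("reference network must share the species set")

    B = _moment_basis(network)  # (m + m(m+1)/2, r)
    W = _weights(network, samples, dt)  # (T, r)
    if ref is network:
        B_ref, W_ref = B, W
    else:
        # align reference species order to the candidate's
        ref_aligned = ReactionNetwork(
            species=list(network.species), reactions=list(ref.reactions), dt=ref.dt
        )
        B_ref = _moment_basis(ref_aligned)
        W_ref = _weights(ref_aligned, samples, dt)

    normal_matrix = (B.T @ B) * (W.T @ W)
    G = B.T @ B_ref
    normal_vector = (W * (W_ref @ G.T)).sum(axis=0)
    G_ref = B_ref.T @ B_ref
    b_norm_sq = float(np.einsum("ti,ij,tj->", W_ref, G_ref, W_ref))

    # PSD repair: clip spurious negative eigenvalues from floating accumulation
    evals, evecs = np.linalg.eigh(normal_matrix)
    if evals[0] < 0:
        normal_matrix = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        normal_matrix = 0.5 * (normal_matrix + normal_matrix.T)

    m = network.m
    n_block = m + m * (m + 1) // 2
    row_count = W.shape[0] * n_block

    A = b = None
    want_dense = store_dense is True or (store_dense == "auto" and row_count <= _DENSE_ROW_LIMIT)
    if want_dense:
        A = (B[None, :, :] * W[:, None, :]).reshape(row_count, network.r)
        b = (B_ref[None, :, :] * W_ref[:, None, :]).sum(axis=2).reshape(row_count)

    return MomentSystem(
        normal_matrix=normal_matrix,
        normal_vector=normal_vector,
        b_norm_sq=b_norm_sq,
        row_count=row_count,
        k_est=network.rates(),
        network=network,
        A=A,
        b=b,
    )


@dataclass
class ReductionResult:
    """Outcome of one reduction: kept support, scaled rates, reduced network."""

    support: np.ndarray  # boolean, length r
    k_relaxed: np.ndarray | None  # LASSO solution in [0,1] (pre-threshold); None otherwise
    reduced_network: ReactionNetwork
    objective: float | None  # moment-matching objective of the solution (None for count)
    method: str
    param: float  # λ (iqp/lasso) or f (count)
    flags: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.support.sum())


def _reduced_network(network: ReactionNetwork, support: np.ndarray, scale=None) -> ReactionNetwork:
    out = deepcopy(network)
    kept = []
    for j, rx in enumerate(out.reactions):
        if support[j]:
            if scale is not None:
                rx.rate_k = float(rx.rate_k * scale[j])
            kept.append(rx)
    out.reactions = kept
    return out


def count_based_reduce(network: ReactionNetwork, counts, f: int) -> ReductionResult:
    """Remove every reaction whose total observed count is below f.

    ``counts`` may be a ReactionCountSeries aligned with the network or an
    explicit per-reaction total vector; with ``counts=None`` the totals stored
    on the reactions are used.  All reactions sharing a total are removed
    together — the method has no finer granularity — and this is *not* the
    same as removing the lowest-rate reactions, because counts depend on both
    the rate and how often the reaction was possible.
    """
    if f < 1:
        raise ParameterError("minimum count f must be >= 1")
    if counts is None:
        totals = np.array([rx.observed_count_total for rx in network.reactions])
    elif isinstance(counts, ReactionCountSeries):
        totals = counts.totals()
    else:
        totals = np.asarray(counts)
    if totals.shape != (network.r,):
        raise ParameterError("counts not aligned with network")
    support = totals >= f
    return ReductionResult(
        support=support,
        k_relaxed=None,
        reduced_network=_reduced_network(network, support),
        objective=None,
        method="count",
        param=float(f),
    )


# ---------------------------------------------------------------------------
# box + L1-budget quadratic programming

def _project_box_capped_simplex(v: np.ndarray, budget: float) -> np.ndarray:
    """Euclidean projection onto {k : 0 ≤ k ≤ 1, Σ k ≤ budget}."""
    w = np.clip(v, 0.0, 1.0)
    if w.sum() <= budget + 1e-12:
        return w
    lo, hi = 0.0, float(v.max())
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.clip(v - mid, 0.0, 1.0).sum() > budget:
            lo = mid
        else:
            hi = mid
    return np.clip(v - hi, 0.0, 1.0)


def _solve_box_qp(
    N: np.ndarray,
    c: np.ndarray,
    budget: float,
    fixed: dict | None = None,
    tol_kkt: float = 1e-8,
    tol_obj: float = 1e-10,
    max_iter: int = 200_000,
):
    """Minimize kᵀNk − 2cᵀk over the box-capped simplex with optional fixed
    coordinates, by FISTA with adaptive restart.  Returns (k, iterations)."""
    r = c.shape[0]
    fixed = fixed or {}
    free = np.array([j for j in range(r) if j not in fixed], dtype=np.int64)
    k_full = np.zeros(r)
    for j, v in fixed.items():
        k_full[j] = v
    fixed_sum = sum(fixed.values())
    sub_budget = budget - fixed_sum
    if sub_budget < -1e-9:
        return None, 0  # infeasible
    if free.size == 0:
        return k_full, 0
    Q = N[np.ix_(free, free)]
    lin = c[free] - N[np.ix_(free, list(fixed))] @ np.array(list(fixed.values())) if fixed else c[free]
    sub_budget = max(sub_budget, 0.0)

    L = 2.0 * max(float(np.linalg.eigvalsh(Q)[-1]), 0.0)
    if L <= 0.0:
        # degenerate quadratic: objective is linear; fill greedily by gain
        x = np.zeros(free.size)
        order = np.argsort(-lin)
        rem = sub_budget
        for j in order:
            if lin[j] <= 0 or rem <= 0:
                break
            x[j] = min(1.0, rem)
            rem -= x[j]
        k_full[free] = x
        return k_full, 0

    def grad(x):
        return 2.0 * (Q @ x - lin)

    def obj(x):
        return float(x @ Q @ x - 2.0 * lin @ x)

    x = _project_box_capped_simplex(np.ones(free.size), sub_budget)
    y = x.copy()
    t_mom = 1.0
    f_prev = obj(x)
    it = 0
    for it in range(1, max_iter + 1):
        x_new = _project_box_capped_simplex(y - grad(y) / L, sub_budget)
        f_new = obj(x_new)
        if f_new > f_prev:  # adaptive restart
            y = x.copy()
            t_mom = 1.0
            x_new = _project_box_capped_simplex(y - grad(y) / L, sub_budget)
            f_new = obj(x_new)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y = x_new + ((t_mom - 1.0) / t_next) * (x_new - x)
        t_mom = t_next
        pg = x_new - _project_box_capped_simplex(x_new - grad(x_new) / L, sub_budget)
        resid = float(np.linalg.norm(pg))
        converged = resid <= tol_kkt or abs(f_prev - f_new) <= tol_obj * max(1.0, abs(f_new))
        x, f_prev = x_new, f_new
        if converged:
            break
    else:
        raise ConvergenceError(
            "box-constrained QP did not converge",
            iterations=max_iter,
            residual=resid,
            objective=f_prev,
        )
    k_full[free] = x
    return k_full, it


def reduce_lasso(
    moment_system: MomentSystem,
    lam: float,
    epsilon: float = 0.01,
) -> ReductionResult:
    """Box-constrained LASSO relaxation with ε-thresholding.

    Solves min ‖Ak − b‖² over k ∈ [0,1]^r with the L1 budget Σ k ≤ λ
    (constrained form), then zeroes every entry below ε: a reaction whose
    estimated rate can be shrunk by more than 99% (at the default ε = 0.01)
    is removed.  Final rates are k_est ∘ k, so kept rates may shrink below
    their estimates — deliberate, since rare-reaction rates tend to be
    overestimated.
    """
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    ms = moment_system
    k, _ = _solve_box_qp(ms.normal_matrix, ms.normal_vector, float(lam))
    k_relaxed = k.copy()
    k_thr = np.where(k < epsilon, 0.0, k)
    support = k_thr > 0
    # phase-separation flag: entries are empirically near 0 or near 1
    mid = np.flatnonzero((k_relaxed >= epsilon) & (k_relaxed <= 0.5))
    flags = {}
    if mid.size:
        flags["phase_separation_violations"] = mid.tolist()
    return ReductionResult(
        support=support,
        k_relaxed=k_relaxed,
        reduced_network=_reduced_network(ms.network, support, scale=k_thr),
        objective=ms.objective(k_relaxed),
        method="lasso",
        param=float(lam),
        flags=flags,
    )


def reduce_iqp(moment_system: MomentSystem, lam: int) -> ReductionResult:
    """Exact integer quadratic program: min ‖Ak − b‖², k ∈ {0,1}^r, Σk ≤ λ.

    Solved by depth-first branch-and-bound using the convex relaxation over
    the box-capped simplex as an admissible bound (only AᵀA / Aᵀb are
    needed).  Branching is lexicographic by reaction index, include-first,
    which makes the optimizer deterministic.  Refuses r > 25 (use
    :func:`reduce_lasso` instead).
    """
    if lam < 0:
        raise ParameterError("lambda must be non-negative")
    ms = moment_system
    r = ms.r
    if r > 25:
        raise CapabilityError(
            f"exact IQP supported only for r <= 25 (got r={r}); use reduce_lasso"
        )
    lam = int(min(lam, r))
    N, c, b_sq = ms.normal_matrix, ms.normal_vector, ms.b_norm_sq

    def int_obj(kvec):
        return float(kvec @ N @ kvec - 2.0 * c @ kvec + b_sq)

    scale = max(1.0, abs(b_sq))
    # initial incumbent: relaxation solution rounded to its λ largest entries
    k_rel, _ = _solve_box_qp(N, c, float(lam), tol_kkt=1e-8)
    k_round = np.zeros(r)
    top = np.argsort(-k_rel)[:lam]
    k_round[top[k_rel[top] > 0.5]] = 1.0
    best_k = k_round
    best_obj = int_obj(k_round)
    z = int_obj(np.zeros(r))
    if z < best_obj:
        best_obj, best_k = z, np.zeros(r)

    def visit(fixed: dict, depth: int, n_one: int):
        nonlocal best_obj, best_k
        if n_one > lam:
            return
        if depth == r:
            kvec = np.array([fixed[j] for j in range(r)], dtype=float)
            val = int_obj(kvec)
            if val < best_obj - 1e-12 * scale:
                best_obj, best_k = val, kvec
            return
        sol, _ = _solve_box_qp(N, c, float(lam), fixed=fixed, tol_kkt=1e-9)
        if sol is None:
            return
        bound = float(sol @ N @ sol - 2.0 * c @ sol + b_sq)
        if bound >= best_obj - 1e-9 * scale:
            return  # cannot improve beyond numerical resolution
        if n_one == lam:
            kvec = np.array([fixed.get(j, 0.0) for j in range(r)], dtype=float)
            val = int_obj(kvec)
            if val < best_obj - 1e-12 * scale:
                best_obj, best_k = val, kvec
            return
        visit({**fixed, depth: 1.0}, depth + 1, n_one + 1)
        visit({**fixed, depth: 0.0}, depth + 1, n_one)

    visit({}, 0, 0)
    support = best_k > 0.5
    return ReductionResult(
        support=support,
        k_relaxed=None,
        reduced_network=_reduced_network(ms.network, support),
        objective=best_obj,
        method="iqp",
        param=float(lam),
    )


def lambda_sweep(moment_system: MomentSystem, lambdas, method: str = "lasso", epsilon: float = 0.01):
    """Reduce at each λ; returns (results, summary DataFrame λ/size/objective)."""
    import pandas as pd

    results = []
    for lam in lambdas:
        if method == "lasso":
            results.append(reduce_lasso(moment_system, lam, epsilon=epsilon))
        elif method == "iqp":
            results.append(reduce_iqp(moment_system, int(lam)))
        else:
            raise ParameterError(f"unknown sweep method {method!r}")
    summary = pd.DataFrame(
        {
            "lambda": [res.param for res in results],
            "n_reactions": [res.n_kept for res in results],
            "objective": [res.objective for res in results],
        }
    )
    return results, summary
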