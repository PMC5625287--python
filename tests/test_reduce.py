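import itertools

import numpy as np
import pytest

import kmclearn as km
from kmclearn.errors import CapabilityError, ParameterError
from kmclearn.network import ConcentrationTrajectory, Reaction, ReactionNetwork, Species
from kmclearn.reduce import (
    MomentSystem,
    _project_box_capped_simplex,
    build_moment_system,
    count_based_reduce,
    lambda_sweep,
    reduce_iqp,
    reduce_lasso,
)


def exhaustive_iqp(ms, lam):
    """Oracle: enumerate every binary support of size ≤ λ."""
    r = ms.r
    best = np.inf
    for size in range(lam + 1):
        for sup in itertools.combinations(range(r), size):
            k = np.zeros(r)
            k[list(sup)] = 1.0
            best = min(best, ms.objective(k))
    return best


def random_moment_system(seed, n_reactions=10, t_end=5.0):
    rng = np.random.default_rng(seed)
    net = km.random_cluster_network(rng, max_size=5, n_reactions=n_reactions)
    x0 = rng.integers(1, 30, size=net.m)
    traj = km.simulate_ssa(net, x0, t_end, seed=seed + 10_000)
    samples = km.sample_trajectory(traj, np.arange(0, t_end + 1e-9, 0.1), network=net)
    return build_moment_system(net, samples)


class TestCountBasedReduce:
    def _net(self, totals):
        a = Species.from_counts({"A": 2}, {})
        b = Species.from_counts({"A": 2}, {("A", "A"): 1})
        reactions = []
        for i, n in enumerate(totals):
            rx = Reaction((a,), (b,), rate_k=1.0) if i % 2 == 0 else Reaction((b,), (a,), rate_k=1.0)
            rx.observed_count_total = n
            reactions.append(rx)
        return ReactionNetwork([a, b], reactions, dt=0.1)

    def test_threshold_removes_infrequent(self):
        net = self._net([5, 1, 0])
        res = count_based_reduce(net, None, f=2)
        assert res.support.tolist() == [True, False, False]
        assert res.reduced_network.r == 1

    def test_f_one_keeps_every_observed_reaction(self):
        net = self._net([5, 1, 0])
        res = count_based_reduce(net, None, f=1)
        assert res.support.tolist() == [True, True, False]

    def test_equal_totals_removed_together(self):
        net = self._net([3, 3, 7])
        res = count_based_reduce(net, None, f=4)
        assert res.support.tolist() == [False, False, True]

    def test_invalid_f_rejected(self):
        with pytest.raises(ParameterError):
            count_based_reduce(self._net([1]), None, f=0)


class TestBuildMomentSystem:
    def test_hand_worked_single_reaction_column(self):
        # m = 2, one reaction A -> B, k_est = 2, h = X_A = 5, dt = 0.1:
        # weight = 2*5*0.1 = 1, so A's column is [R ; triu(RR^T)] = [-1,1,1,-1,1]
        a = Species.from_counts({"A": 2}, {})
        b = Species.from_counts({"A": 2}, {("A", "A"): 1})
        net = ReactionNetwork([a, b], [Reaction((a,), (b,), rate_k=2.0)], dt=0.1)
        traj = ConcentrationTrajectory([0.0, 0.1], [[5, 0], [4, 1]], species=net.species_labels)
        ms = build_moment_system(net, traj, dt=0.1)
        assert ms.A.shape == (5, 1)
        assert np.allclose(ms.A[:, 0], [-1, 1, 1, -1, 1])
        assert np.allclose(ms.b, ms.A @ np.ones(1))

    def test_row_count_formula(self, methane):
        net, _ = methane
        rng = np.random.default_rng(1)
        m = net.m
        X = rng.integers(1, 10, size=(8, m))  # T = 7 transitions
        traj = ConcentrationTrajectory(np.arange(8.0), X, species=net.species_labels)
        ms = build_moment_system(net, traj, dt=0.1)
        assert m == 5 and ms.row_count == 7 * (m + m * (m + 1) // 2)

    def test_all_ones_is_exact_solution(self):
        for seed in range(5):
            ms = random_moment_system(seed)
            assert np.linalg.norm(ms.A @ np.ones(ms.r) - ms.b) < 1e-9
            assert abs(ms.objective(np.ones(ms.r))) < 1e-8 * max(1.0, ms.b_norm_sq)

    def test_normal_matrix_is_symmetric_psd(self):
        ms = random_moment_system(3)
        N = ms.normal_matrix
        assert np.allclose(N, N.T)
        assert np.linalg.eigvalsh(N)[0] >= -1e-9
        # streaming normal equations agree with the explicit system
        assert np.allclose(N, ms.A.T @ ms.A, rtol=1e-10, atol=1e-8)
        assert np.allclose(ms.normal_vector, ms.A.T @ ms.b, rtol=1e-10, atol=1e-8)

    def test_zero_rate_reactions_rejected(self, methane):
        net, _ = methane
        import copy

        bad = copy.deepcopy(net)
        bad.reactions[0].rate_k = 0.0
        traj = ConcentrationTrajectory(
            np.arange(3.0), np.ones((3, net.m), dtype=int), species=net.species_labels
        )
        with pytest.raises(ParameterError):
            build_moment_system(bad, traj, dt=0.1)


class TestProjection:
    def test_projection_feasible_and_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            v = rng.normal(0, 2, size=rng.integers(1, 12))
            lam = float(rng.uniform(0.1, len(v)))
            p = _project_box_capped_simplex(v, lam)
            assert p.min() >= 0 and p.max() <= 1
            assert p.sum() <= lam + 1e-8
            assert np.allclose(_project_box_capped_simplex(p, lam), p, atol=1e-7)

    def test_projection_is_euclidean_nearest(self):
        # compare against a fine grid search in 2-D
        rng = np.random.default_rng(1)
        grid = np.linspace(0, 1, 201)
        G = np.array(np.meshgrid(grid, grid)).reshape(2, -1).T
        for _ in range(20):
            v = rng.normal(0, 1.5, size=2)
            lam = float(rng.uniform(0.2, 2.0))
            feasible = G[G.sum(axis=1) <= lam]
            best = feasible[np.argmin(((feasible - v) ** 2).sum(axis=1))]
            p = _project_box_capped_simplex(v, lam)
            assert np.linalg.norm(p - best) < 0.02


class TestReduceIqp:
    def test_full_budget_keeps_everything(self):
        ms = random_moment_system(11)
        res = reduce_iqp(ms, ms.r)
        assert res.support.all()
        assert res.objective == pytest.approx(0.0, abs=1e-6 * max(1, ms.b_norm_sq))

    def test_duplicate_column_drops_exactly_one(self):
        # two identical reactions share one true process; at λ = r−1 the
        # optimizer can drop either copy without changing the objective
        a = Species.from_counts({"A": 2}, {})
        b = Species.from_counts({"A": 2}, {("A", "A"): 1})
        fwd1 = Reaction((a,), (b,), rate_k=1.0)
        fwd2 = Reaction((a,), (b,), rate_k=1.0)
        rev = Reaction((b,), (a,), rate_k=0.5)
        net = ReactionNetwork([a, b], [fwd1, fwd2, rev], dt=0.1)
        single = ReactionNetwork([a, b], [fwd1, rev], dt=0.1)  # the true process once
        rng = np.random.default_rng(2)
        X = rng.integers(1, 15, size=(30, 2))
        traj = ConcentrationTrajectory(np.arange(30.0), X, species=net.species_labels)
        ms = build_moment_system(net, traj, dt=0.1, reference=single)
        res = reduce_iqp(ms, lam=2)
        assert res.n_kept == 2
        assert res.support[:2].sum() == 1  # one of the twins dropped
        assert res.support[2]
        assert res.objective == pytest.approx(0.0, abs=1e-8 * max(1, ms.b_norm_sq))
        assert res.objective == pytest.approx(exhaustive_iqp(ms, 2), abs=1e-8 * max(1, ms.b_norm_sq))

    @pytest.mark.parametrize("lam", [2, 4])
    def test_matches_exhaustive_enumeration(self, lam):
        for seed in range(6):
            ms = random_moment_system(seed + 50)
            res = reduce_iqp(ms, lam)
            oracle = exhaustive_iqp(ms, lam)
            assert res.objective == pytest.approx(oracle, rel=1e-6, abs=1e-8 * max(1, ms.b_norm_sq))

    def test_capability_error_above_25_reactions(self):
        r = 26
        ms = MomentSystem(
            normal_matrix=np.eye(r),
            normal_vector=np.zeros(r),
            b_norm_sq=0.0,
            row_count=r,
            k_est=np.ones(r),
            network=None,
        )
        with pytest.raises(CapabilityError):
            reduce_iqp(ms, 3)

    def test_negative_lambda_rejected(self):
        ms = random_moment_system(1)
        with pytest.raises(ParameterError):
            reduce_iqp(ms, -1)


class TestReduceLasso:
    def test_full_budget_recovers_all_ones(self):
        ms = random_moment_system(21)
        res = reduce_lasso(ms, lam=float(ms.r))
        assert np.allclose(res.k_relaxed, 1.0, atol=1e-5)
        assert res.objective == pytest.approx(0.0, abs=1e-6 * max(1, ms.b_norm_sq))

    def test_single_column_exact(self):
        a = Species.from_counts({"A": 2}, {})
        b = Species.from_counts({"A": 2}, {("A", "A"): 1})
        net = ReactionNetwork([a, b], [Reaction((a,), (b,), rate_k=2.0)], dt=0.1)
        traj = ConcentrationTrajectory([0.0, 0.1, 0.2], [[5, 0], [4, 1], [3, 2]],
                                       species=net.species_labels)
        ms = build_moment_system(net, traj, dt=0.1)
        res = reduce_lasso(ms, lam=1.0)
        assert res.k_relaxed[0] == pytest.approx(1.0, abs=1e-7)

    def test_spurious_reaction_support_recovery(self, methane):
        """Injected never-firing reactions with inflated rates are discarded."""
        net, _ = methane
        x0 = np.zeros(net.m, dtype=int)
        x0[net.species_labels.index("C1 H4 4(H–C)")] = 20
        traj = km.simulate_ssa(net, x0, t_end=20.0, seed=31)
        samples = km.sample_trajectory(traj, np.arange(0, 20.0001, 0.05), network=net)
        injected, mask = km.inject_spurious_reactions(net, d=6, rate_inflation=5.0, seed=7)
        ms = build_moment_system(injected, samples, reference=net)
        res = reduce_lasso(ms, lam=6.0)
        assert np.array_equal(res.support, mask)
        # removed reactions carry rate exactly 0 (they are gone entirely)
        assert res.reduced_network.r == 6
        assert all(rx.rate_k > 0 for rx in res.reduced_network.reactions)

    def test_invalid_lambda_rejected(self):
        ms = random_moment_system(1)
        with pytest.raises(ParameterError):
            reduce_lasso(ms, 0.0)


class TestRelaxationProperties:
    def test_iqp_at_most_rounded_lasso_objective(self):
        for seed in (61, 62, 63):
            ms = random_moment_system(seed)
            for lam in (3, 5):
                lasso = reduce_lasso(ms, float(lam))
                rounded = lasso.support.astype(float)
                if rounded.sum() > lam:  # rounding may exceed the budget
                    keep = np.argsort(-lasso.k_relaxed)[:lam]
                    rounded = np.zeros(ms.r)
                    rounded[keep] = 1.0
                iqp = reduce_iqp(ms, lam)
                assert iqp.objective <= ms.objective(rounded) + 1e-7 * max(1, ms.b_norm_sq)

    def test_objective_non_increasing_in_lambda(self):
        ms = random_moment_system(71)
        lams = [1, 2, 3, 4, 6, 8, 10]
        _, lasso_summary = lambda_sweep(ms, lams, method="lasso")
        assert (np.diff(lasso_summary["objective"]) <= 1e-7 * max(1, ms.b_norm_sq)).all()
        _, iqp_summary = lambda_sweep(ms, [1, 2, 4, 6], method="iqp")
        assert (np.diff(iqp_summary["objective"]) <= 1e-7 * max(1, ms.b_norm_sq)).all()
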