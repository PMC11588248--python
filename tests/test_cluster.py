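"""FRECL runs, consensus aggregation and model selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from frecl import (BasisSpec, ConsensusMatrix, FoFModel, FreclConfig,
                   Partition, adjusted_rand_index, consensus_cluster,
                   consensus_matrix, fit_partition_models, frecl_consensus,
                   frecl_run, mse_profile, random_partition, reassign_step,
                   select_k_elbow)
from frecl.cluster import _residual_matrix

from conftest import make_dataset


class TestRandomPartition:
    def test_forced_singletons(self):
        part = random_partition(4, 4, np.random.default_rng(0))
        assert sorted(part.labels) == [1, 2, 3, 4]

    def test_infeasible(self):
        with pytest.raises(ValueError):
            random_partition(3, 4, np.random.default_rng(0))

    def test_deterministic(self):
        p1 = random_partition(50, 3, np.random.default_rng(7))
        p2 = random_partition(50, 3, np.random.default_rng(7))
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_nonempty_and_near_uniform(self):
        rng = np.random.default_rng(1)
        m, K, draws = 100, 3, 3000
        counts = np.zeros(K)
        first_obs = np.zeros(K)
        for _ in range(draws):
            part = random_partition(m, K, rng)
            assert part.n_clusters == K
            sizes = part.sizes()
            counts += [sizes[k] for k in range(1, K + 1)]
            first_obs[part.labels[0] - 1] += 1
        np.testing.assert_allclose(counts / draws, m / K, rtol=0.02)
        # marginal assignment of a fixed observation is uniform
        assert chisquare(first_obs).pvalue > 0.01


def _models_with_offsets(grid, basis, offsets):
    """Constant-intercept models: observation fits model with the nearest
    offset, giving full control over reassignment."""
    T = grid.T
    return [FoFModel(np.full(T, o), [np.zeros((T, T))], basis, grid)
            for o in offsets]


class TestReassign:
    def test_single_model_takes_all(self, grid24, small_basis):
        ds = make_dataset(8, 1, grid24)
        models = _models_with_offsets(grid24, small_basis, [0.0])
        part = reassign_step(ds, models)
        assert part.n_clusters == 1

    def test_argmin_and_tie_break(self, grid24, small_basis):
        from frecl import CurveSet, FRDataset
        x = CurveSet(["a"], np.zeros((1, grid24.T)), grid24)
        y = CurveSet(["a"], np.full((1, grid24.T), 1.0), grid24)
        ds = FRDataset(y, [x])
        # residuals: |1-0.5| < |1-3|  -> model 1
        models = _models_with_offsets(grid24, small_basis, [0.5, 3.0])
        assert reassign_step(ds, models).labels[0] == 1
        # exact tie |1-0| == |1-2| -> smallest cluster index
        models = _models_with_offsets(grid24, small_basis, [0.0, 2.0])
        assert reassign_step(ds, models).labels[0] == 1


class TestFreclRun:
    def test_truth_is_fixed_point_of_noise_free_data(self, grid24):
        from frecl import ScenarioConfig, ErrorConfig, simulate_dataset
        sim = simulate_dataset(ScenarioConfig(
            m=90, k_true=3, seed=3, error=ErrorConfig("iid", 1e-12)))
        fc = FreclConfig(K=3, basis=BasisSpec(n_basis_t=6, n_basis_s=6))
        res = frecl_run(sim.dataset, fc, np.random.default_rng(0),
                        init=sim.truth)
        assert res.converged and res.n_iter <= 2
        assert adjusted_rand_index(sim.truth, res.partition) == 1.0

    def test_max_iter_cap(self, k3_dataset):
        fc = FreclConfig(K=3, max_iter=1,
                         basis=BasisSpec(n_basis_t=5, n_basis_s=5))
        res = frecl_run(k3_dataset.dataset, fc, np.random.default_rng(5))
        assert res.n_iter == 1
        assert not res.converged or res.n_iter == 1

    def test_nonincreasing_cluster_count_and_objective(self, k3_dataset):
        """Within a run the number of non-empty clusters never grows, and
        reassignment is greedy-optimal given the fitted models."""
        ds = k3_dataset.dataset
        fc = FreclConfig(K=5, basis=BasisSpec(n_basis_t=5, n_basis_s=5))
        res = frecl_run(ds, fc, np.random.default_rng(2), keep_trace=True)
        counts = [p.n_clusters for p in res.trace]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        # greedy optimality: assigned residual is the row minimum
        models = fit_partition_models(ds, res.partition, fc.basis)
        R = _residual_matrix(ds, models, fc.norm)
        assigned = R[np.arange(ds.m), res.partition.compact().labels - 1]
        np.testing.assert_allclose(assigned, R.min(axis=1))

    def test_run_determinism(self, k3_dataset):
        fc = FreclConfig(K=3, basis=BasisSpec(n_basis_t=5, n_basis_s=5))
        r1 = frecl_run(k3_dataset.dataset, fc, np.random.default_rng(9))
        r2 = frecl_run(k3_dataset.dataset, fc, np.random.default_rng(9))
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)

    def test_models_match_cluster_count_and_log(self, k3_dataset):
        fc = FreclConfig(K=4, basis=BasisSpec(n_basis_t=5, n_basis_s=5))
        res = frecl_run(k3_dataset.dataset, fc, np.random.default_rng(1))
        assert len(res.models) == res.partition.n_clusters
        assert len(res.log) == res.n_iter
        assert {"iteration", "cluster_sizes", "total_sq_residual"} <= set(
            res.log[0])

    def test_ari_trace_predominantly_increases(self):
        """Final ARI is at least the initial ARI in nearly every run."""
        from frecl import ScenarioConfig, simulate_dataset
        sim = simulate_dataset(ScenarioConfig(m=240, k_true=3, seed=17))
        fc = FreclConfig(K=3, basis=BasisSpec(n_basis_t=6, n_basis_s=6))
        wins = 0
        n_runs = 20
        for s in range(n_runs):
            res = frecl_run(sim.dataset, fc, np.random.default_rng(s),
                            keep_trace=True)
            first = adjusted_rand_index(sim.truth, res.trace[0])
            last = adjusted_rand_index(sim.truth, res.trace[-1])
            wins += last >= first
        assert wins >= 0.95 * n_runs


class TestConsensus:
    def test_consensus_matrix_definition(self):
        part = Partition(np.array([1, 1, 2]), K=2)
        cm = consensus_matrix([part] * 3)
        np.testing.assert_array_equal(cm.B, [[3, 3, 0], [3, 3, 0], [0, 0, 3]])
        assert cm.L_effective == 3

    def test_consensus_matrix_invariants(self):
        rng = np.random.default_rng(3)
        parts = [Partition(rng.integers(1, 4, size=30), K=3)
                 for _ in range(7)]
        cm = consensus_matrix(parts)
        assert np.array_equal(cm.B, cm.B.T)
        np.testing.assert_array_equal(np.diag(cm.B), 7)
        assert cm.B.min() >= 0 and cm.B.max() <= 7

    def test_identical_partitions_recovered(self):
        rng = np.random.default_rng(4)
        part = Partition(rng.integers(1, 4, size=40), K=3)
        out = consensus_cluster([part] * 10, K=3, rng=np.random.default_rng(0))
        assert adjusted_rand_index(part, out) == 1.0

    def test_majority_structure_recovered(self):
        rng = np.random.default_rng(5)
        part = Partition(rng.integers(1, 4, size=60), K=3)
        noise = Partition(rng.integers(1, 4, size=60), K=3)
        out = consensus_cluster([part] * 9 + [noise], K=3,
                                rng=np.random.default_rng(1))
        assert adjusted_rand_index(part, out) == 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        parts = [Partition(rng.integers(1, 4, size=50), K=3)
                 for _ in range(8)]
        relabeled = [Partition(4 - p.labels, K=3) for p in parts]
        ref = Partition(rng.integers(1, 4, size=50), K=3)
        a = consensus_cluster(parts, K=3, rng=np.random.default_rng(2))
        b = consensus_cluster(relabeled, K=3, rng=np.random.default_rng(2))
        assert adjusted_rand_index(ref, a) == pytest.approx(
            adjusted_rand_index(ref, b))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            consensus_cluster([], K=3, rng=np.random.default_rng(0))

    def test_bad_consensus_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConsensusMatrix(np.array([[1, 2], [3, 1]]), L_effective=3)


class TestFreclConsensus:
    def test_single_run_consensus_equals_run(self, k3_dataset):
        fc = FreclConfig(K=3, L=1, seed=42,
                         basis=BasisSpec(n_basis_t=6, n_basis_s=6))
        part, cm, runs = frecl_consensus(k3_dataset.dataset, fc)
        assert len(runs) == 1
        assert cm.L_effective == 1
        assert adjusted_rand_index(runs[0].partition, part) == 1.0

    def test_bitwise_determinism(self, k3_dataset):
        fc = FreclConfig(K=3, L=4, seed=123,
                         basis=BasisSpec(n_basis_t=5, n_basis_s=5))
        p1, _, _ = frecl_consensus(k3_dataset.dataset, fc)
        p2, _, _ = frecl_consensus(k3_dataset.dataset, fc)
        np.testing.assert_array_equal(p1.labels, p2.labels)


class TestModelSelection:
    def test_mse_fixture(self):
        # residual norms {1, 2, 2} over m = 3: MSE = (1 + 4 + 4)/3 = 3
        r = np.array([1.0, 2.0, 2.0])
        assert np.mean(r**2) == pytest.approx(3.0)

    def test_elbow_on_constructed_knee(self):
        assert select_k_elbow([(2, 10.0), (3, 4.0), (4, 3.6), (5, 3.5)]) == 3

    def test_elbow_linear_profile_warns(self):
        with pytest.warns(UserWarning, match="no elbow"):
            assert select_k_elbow([(2, 9.0), (3, 7.0), (4, 5.0), (5, 3.0)]) == 3

    def test_elbow_needs_three_points(self):
        with pytest.raises(ValueError):
            select_k_elbow([(2, 1.0), (3, 0.5)])

    def test_profile_near_zero_at_true_k_noiseless(self, grid24):
        """Noise-free clusters exactly representable by the fitting basis:
        MSE at the true K is numerically zero relative to the signal."""
        from frecl import CurveSet, FRDataset, build_design, lp_norm
        basis = BasisSpec(n_basis_t=6, n_basis_s=6)
        rng = np.random.default_rng(13)
        m = 240
        ds0 = make_dataset(m, 2, grid24, seed=13)
        D = build_design(ds0.predictors, basis, grid24)
        labels = rng.integers(1, 4, size=m)
        thetas = rng.normal(0, 0.4, size=(3, D.shape[1]))
        Y = np.vstack([(D[i * grid24.T:(i + 1) * grid24.T]
                        @ thetas[labels[i] - 1]) for i in range(m)])
        Y = Y.reshape(m, grid24.T)
        ds = FRDataset(CurveSet(ds0.ids, Y, grid24), ds0.predictors)
        fc = FreclConfig(K=3, L=4, seed=5, basis=basis)
        profile = mse_profile(ds, [3], fc)
        signal = np.mean(lp_norm(Y, grid24, 2) ** 2)
        assert profile[0][1] <= 1e-6 * signal
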