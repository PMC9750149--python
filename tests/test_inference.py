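"""Spatial inference: empirical distributions, KL objective, optimizer."""

import numpy as np
import pandas as pd
import pytest

import tattooseq as tq
from tattooseq.inference import (EmpiricalFluorescence,
                                 UnobservablePatternError,
                                 empirical_distribution,
                                 infer_sbin_distribution, kl_objective,
                                 missed_probability, predict_fluorescence)


class TestEmpiricalDistribution:
    def test_pseudocount_arithmetic(self):
        emp = EmpiricalFluorescence("g", {"PD": np.array([10, 0, 0])},
                                    epsilon=1.0)
        assert np.allclose(emp.distribution("PD"),
                           [11 / 13, 1 / 13, 1 / 13])

    def test_zero_epsilon(self):
        emp = EmpiricalFluorescence("g", {"PD": np.array([2, 3, 5])},
                                    epsilon=0.0)
        assert np.allclose(emp.distribution("PD"), [0.2, 0.3, 0.5])

    def test_empty_pattern_omitted(self):
        calls = pd.DataFrame({
            "cell_id": ["a", "b"], "pattern": ["PD", "PD"],
            "color": ["green", "red"]})
        emp = empirical_distribution(calls, "g", ["a", "b"])
        assert emp.patterns == ["PD"]
        assert emp.n_cells("AP") == 0

    def test_counts_match_calls(self, calls_small, groups_small):
        groups, _ = groups_small
        gid = groups.group_id.iloc[0]
        cells = groups[groups.group_id == gid].cell_id
        emp = empirical_distribution(calls_small, gid, cells)
        sub = calls_small[calls_small.cell_id.isin(set(cells))]
        for p in emp.patterns:
            assert emp.n_cells(p) == (sub.pattern == p).sum()


class TestPredictFluorescence:
    def test_point_mass_on_deterministic_sbin(self, toy_forward):
        theta = np.array([1.0, 0.0, 0.0])
        assert np.allclose(predict_fluorescence(theta, toy_forward["PD"]),
                           [1, 0, 0])

    def test_linearity(self, toy_forward):
        theta = np.array([0.5, 0.5, 0.0])
        assert np.allclose(predict_fluorescence(theta, toy_forward["PD"]),
                           [0.5, 0.5, 0])

    def test_matches_bruteforce_sum(self, model):
        rng = np.random.default_rng(0)
        theta = rng.dirichlet(np.ones(model.n_sbins))
        A = model.grid.forward["AP"]
        brute = np.zeros(3)
        for s in range(model.n_sbins):
            brute += A[s, :3] * theta[s]
        assert np.allclose(predict_fluorescence(theta, A), brute,
                           atol=1e-12)

    def test_all_missed_raises(self):
        fwd = np.array([[0, 0, 0, 1.0]])
        with pytest.raises(UnobservablePatternError):
            predict_fluorescence(np.array([1.0]), fwd,
                                 condition_on_capture=True)

    def test_missed_probability(self, model):
        theta = np.zeros(model.n_sbins)
        prox = np.argmax(model.grid.forward["AER"][:, 3])
        theta[prox] = 1.0
        assert missed_probability(theta, model.grid.forward["AER"]) \
            == pytest.approx(1.0, abs=1e-9)


class TestKLObjective:
    def test_zero_at_generating_theta(self, toy_forward):
        theta = np.array([0.2, 0.5, 0.3])
        counts = {}
        for p in ("PD", "AP"):
            pred = predict_fluorescence(theta, toy_forward[p])
            counts[p] = np.round(pred * 100000).astype(int)
        emp = EmpiricalFluorescence("g", counts, epsilon=0.0)
        assert kl_objective(theta, emp, toy_forward) < 1e-6

    def test_nonnegative_up_to_clamping_bias(self, toy_forward):
        rng = np.random.default_rng(1)
        floor = -3 * 1e-3 * abs(np.log(1e-3))
        for _ in range(20):
            theta = rng.dirichlet(np.ones(3))
            counts = {p: rng.integers(0, 50, 3) + 1 for p in toy_forward}
            emp = EmpiricalFluorescence("g", counts, epsilon=1.0)
            assert kl_objective(theta, emp, toy_forward) >= floor

    def test_matches_standalone_reimplementation(self, toy_forward):
        """Scalar oracle over a 1001-point slice of the simplex."""
        emp = EmpiricalFluorescence(
            "g", {"PD": np.array([30, 50, 20]),
                  "AP": np.array([55, 15, 30]),
                  "AER": np.array([35, 40, 25])}, epsilon=1.0)

        def oracle(theta):
            tot = 0.0
            for p in emp.patterns:
                A = toy_forward[p]
                pred = [sum(A[s, f] * theta[s] for s in range(3))
                        for f in range(3)]
                if p == "AER":
                    z = sum(pred)
                    pred = [v / z for v in pred]
                q = emp.distribution(p)
                for f in range(3):
                    pc = min(max(pred[f], 1e-3), 1.0)
                    qc = min(max(q[f], 1e-3), 1.0)
                    tot += pc * (np.log(pc) - np.log(qc))
            return tot

        for t1 in np.linspace(0, 1, 101):
            for t2 in (0.0, (1 - t1) / 2):
                theta = np.array([t1, t2, 1 - t1 - t2])
                assert kl_objective(theta, emp, toy_forward) \
                    == pytest.approx(oracle(theta), abs=1e-9)


class TestInferSbinDistribution:
    def test_valid_distribution_for_every_group(self, posts_small):
        for p in posts_small:
            assert np.all(p.theta >= 0)
            assert p.theta.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_simplex_grid_search(self, toy_forward):
        emp = EmpiricalFluorescence(
            "toy", {"PD": np.array([30, 50, 20]),
                    "AP": np.array([55, 15, 30]),
                    "AER": np.array([35, 40, 25])}, epsilon=1.0)
        post = infer_sbin_distribution(emp, toy_forward, seed=0)
        best = min(
            kl_objective(np.array([i, j, 100 - i - j]) / 100.0, emp,
                         toy_forward)
            for i in range(101) for j in range(101 - i))
        assert post.objective <= best + 1e-3

    def test_concentrated_group_recovered(self, model, calls_small,
                                          sim_small):
        """Cells drawn from a single sbin put nearly all mass there."""
        _, _, _, truth = sim_small
        sbin_counts = truth.cells.sbin.value_counts()
        target = int(sbin_counts.index[0])
        cells = truth.cells[truth.cells.sbin == target].cell_id
        emp = empirical_distribution(calls_small, "one-sbin", cells)
        post = infer_sbin_distribution(emp, model.grid.forward, seed=0)
        assert post.theta[target] >= 0.95

    def test_uniform_empiricals_give_near_uniform_theta(self):
        """When uniform theta maps to uniform colors, uniform data should
        return (close to) uniform theta."""
        fwd = {"PD": np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]],
                              float),
               "AP": np.array([[0, 1, 0, 0], [0, 0, 1, 0], [1, 0, 0, 0]],
                              float)}
        emp = EmpiricalFluorescence(
            "u", {"PD": np.array([100, 100, 100]),
                  "AP": np.array([100, 100, 100])}, epsilon=1.0)
        post = infer_sbin_distribution(emp, fwd, seed=0)
        tv = 0.5 * np.abs(post.theta - 1 / 3).sum()
        assert tv <= 0.05

    def test_objective_not_worse_than_start_points(self, model,
                                                   posts_small,
                                                   calls_small,
                                                   groups_small):
        groups, _ = groups_small
        uniform = np.full(model.n_sbins, 1.0 / model.n_sbins)
        for p in posts_small[:5]:
            cells = groups[groups.group_id == p.group_id].cell_id
            emp = empirical_distribution(calls_small, p.group_id, cells)
            assert p.objective <= kl_objective(uniform, emp,
                                               model.grid.forward) + 1e-9

    def test_degenerate_sbin_pair_identified_only_jointly(self):
        """Sbins with identical forward rows share mass arbitrarily but
        their combined mass is pinned down."""
        fwd = {"PD": np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 1, 0, 0],
                               [0, 0, 1, 0]], float)}
        emp = EmpiricalFluorescence("d", {"PD": np.array([100, 300, 100])},
                                    epsilon=0.0)
        post = infer_sbin_distribution(emp, fwd, seed=0)
        assert post.theta[1] + post.theta[2] == pytest.approx(0.6,
                                                              abs=0.02)

    def test_no_patterns_raises(self, toy_forward):
        emp = EmpiricalFluorescence("empty", {})
        with pytest.raises(ValueError):
            infer_sbin_distribution(emp, toy_forward)


class TestThickness:
    def test_normalized_to_max_one(self):
        t = tq.estimate_thickness(np.array([0.2, 0.3, 0.5]),
                                  np.array([1.0, 1.0, 2.0]))
        assert t.max() == 1.0

    def test_uniform_slab_gives_flat_profile(self, model):
        """Uniform cell density over uniform thickness: per-area density
        is constant across sbins (exact color compositions, no sampling
        noise)."""
        areas = model.grid.areas
        prior = areas / areas.sum()
        counts = {}
        for p in ("PD", "AP", "AER"):
            pred = predict_fluorescence(prior, model.grid.forward[p],
                                        condition_on_capture=(p == "AER"))
            counts[p] = np.round(pred * 1_000_000).astype(int)
        emp = EmpiricalFluorescence("all", counts, epsilon=1.0)
        post = infer_sbin_distribution(
            emp, model.grid.forward, theta0=prior.copy(), seed=0,
            prior=prior, prior_weight=1e-3)
        thick = tq.estimate_thickness(post.theta, areas)
        assert np.all(thick > 0.9)

    def test_half_ellipse_profile_recovered(self, model):
        """Sampled experiment: inferred thickness ranks match the
        generating half-ellipse profile."""
        from tattooseq import benchmarks as bm
        out = bm.thickness_study(model, seed=2, n_cells_total=50_000)
        assert out["spearman"] >= 0.9

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            tq.estimate_thickness(np.array([0.5, 0.5]),
                                  np.array([1.0, 0.0]))
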