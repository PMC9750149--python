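"""Expression statistics: QC, vISH, regression, trends, AUC, batch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import tattooseq as tq
from tattooseq.stats import (CountMatrix, MetacellProfile, spatial_trend,
                             tf_specificity_auc, tf_specificity_table)


def _toy_cm(counts, genes=None, batch=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = pd.DataFrame(index=pd.Index(
        [f"c{i}" for i in range(counts.shape[1])], name="cell_id"))
    if batch is not None:
        cells["batch"] = batch
    return CountMatrix(counts=counts,
                       genes=pd.DataFrame(index=pd.Index(genes,
                                                         name="gene")),
                       cells=cells)


class TestQCFilter:
    def test_threshold_example(self):
        totals = [1500, 2500, 16000, 5000, 3000]
        counts = np.array([totals])
        cm = _toy_cm(counts)
        out = tq.qc_filter(cm, min_umi=2000, max_umi=15000)
        assert out.n_cells == 3
        assert set(out.umi_per_cell()) == {2500, 5000, 3000}

    def test_mito_genes_dropped(self):
        cm = _toy_cm(np.full((2, 3), 2000), genes=["mt-Nd1", "Sox9"])
        out = tq.qc_filter(cm, min_umi=100, max_umi=100000)
        assert list(out.genes.index) == ["Sox9"]

    def test_idempotent(self, sim_small):
        _, _, cm, _ = sim_small
        once = tq.qc_filter(cm, min_umi=2000, max_umi=15000)
        twice = tq.qc_filter(once, min_umi=2000, max_umi=15000)
        assert once.n_cells == twice.n_cells
        assert once.n_genes == twice.n_genes

    def test_per_batch_thresholds(self):
        counts = np.array([[2200, 2200, 2600, 2600]])
        cm = _toy_cm(counts, batch=[0, 1, 0, 1])
        out = tq.qc_filter(cm, min_umi={0: 2000, 1: 2500}, max_umi=15000)
        assert out.n_cells == 3

    def test_empty_input_passes_through(self):
        cm = _toy_cm(np.zeros((3, 0), dtype=int))
        out = tq.qc_filter(cm)
        assert out.n_cells == 0


class TestMetacellProfile:
    def test_fractions_and_enrichment_invariants(self, sim_small,
                                                 groups_small):
        _, _, cm, _ = sim_small
        groups, _ = groups_small
        prof = MetacellProfile.from_counts(cm, groups)
        assert np.allclose(prof.fraction.sum(axis=0), 1.0)
        finite = prof.enrichment.replace(np.inf, np.nan).dropna(how="any")
        med = finite.median(axis=1)
        detected = prof.totals.loc[finite.index].sum(axis=1) > 0
        assert np.allclose(med[detected], 1.0, atol=1e-12)


class TestVish:
    def _theta(self):
        return pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["A", "B"],
                            columns=["sbin_0", "sbin_1"])

    def test_single_group_gene(self):
        w = pd.DataFrame({"A": [3.0], "B": [0.0]}, index=["g"])
        v = tq.vish("g", w, self._theta())
        assert np.allclose(v, [1.0, 0.0])

    def test_weighted_two_group_mixture(self):
        w = pd.DataFrame({"A": [30.0], "B": [10.0]}, index=["g"])
        v = tq.vish("g", w, self._theta())
        assert np.allclose(v, [0.75, 0.25])

    def test_normalization_many_genes(self, sim_small, groups_small,
                                      posts_small, model):
        _, _, cm, _ = sim_small
        groups, _ = groups_small
        theta = tq.posteriors_to_frame(posts_small, model.n_sbins)
        sbin_cols = [c for c in theta.columns if c.startswith("sbin_")]
        weights = tq.gene_group_weights(cm, groups)
        detected = cm.umi_per_gene() > 0
        rng = np.random.default_rng(0)
        pick = rng.choice(np.flatnonzero(detected), 100, replace=False)
        for gi in pick:
            v = tq.vish(cm.genes.index[gi], weights, theta[sbin_cols])
            assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_aggregate_singleton_equals_vish(self):
        w = pd.DataFrame({"A": [3.0, 1.0], "B": [1.0, 2.0]},
                         index=["g1", "g2"])
        th = self._theta()
        assert np.array_equal(tq.aggregate_vish(["g1"], w, th),
                              tq.vish("g1", w, th))

    def test_celltype_restriction_renormalizes(self):
        w = pd.DataFrame({"A": [30.0], "B": [10.0]}, index=["g"])
        ann = pd.Series({"A": "mesenchyme", "B": "ectoderm"})
        v = tq.celltype_vish("g", w, self._theta(), ann, "mesenchyme")
        assert np.allclose(v, [1.0, 0.0])

    def test_zero_umi_gene_rejected(self):
        w = pd.DataFrame({"A": [0.0], "B": [0.0]}, index=["g"])
        with pytest.raises(ValueError):
            tq.vish("g", w, self._theta())


class TestSpatialRegression:
    def _theta(self, n_groups=30, n_sbins=5, seed=0):
        rng = np.random.default_rng(seed)
        th = rng.dirichlet(np.ones(n_sbins), size=n_groups)
        return pd.DataFrame(th,
                            index=[f"m{i}" for i in range(n_groups)],
                            columns=[f"sbin_{j}" for j in range(n_sbins)])

    def test_constant_gene_not_spatial(self):
        theta = self._theta()
        expr = pd.DataFrame([[2.0] * 30], index=["flat"],
                            columns=theta.index)
        res = tq.spatial_regression(expr, theta)
        assert res.loc["flat", "r_squared"] == 0.0
        assert res.loc["flat", "p_value"] == 1.0
        assert not res.loc["flat", "is_spatial"]

    def test_exact_linear_gene_detected(self):
        rng = np.random.default_rng(1)
        theta = self._theta(seed=1)
        y = theta.to_numpy() @ np.array([1.0, 4.0, 2.0, 0.5, 3.0])
        y = y + rng.normal(0, 1e-3, len(y))
        expr = pd.DataFrame([y], index=["grad"], columns=theta.index)
        res = tq.spatial_regression(expr, theta)
        assert res.loc["grad", "r_squared"] > 0.99
        assert res.loc["grad", "is_spatial"]

    def test_bonferroni_arithmetic(self):
        theta = self._theta()
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(50, 30)),
                            index=[f"g{i}" for i in range(50)],
                            columns=theta.index)
        res = tq.spatial_regression(expr, theta)
        assert np.allclose(res.p_adjusted,
                           np.minimum(res.p_value * 50, 1.0))

    def test_collinear_columns_dropped(self):
        theta = self._theta(n_sbins=4)
        theta["sbin_3"] = theta["sbin_2"]  # exact collinearity
        expr = pd.DataFrame([theta.to_numpy() @ np.ones(4)],
                            index=["g"], columns=theta.index)
        res = tq.spatial_regression(expr, theta)  # must not raise
        assert np.isfinite(res.loc["g", "p_value"])


class TestSpatialTrend:
    def _run(self, values, coord):
        theta = pd.DataFrame(np.eye(len(coord)),
                             index=[f"m{i}" for i in range(len(coord))],
                             columns=[f"s{i}" for i in range(len(coord))])
        expr = pd.DataFrame([values],
                            index=["g"], columns=theta.index)
        return spatial_trend(expr, theta, np.asarray(coord, float))

    def test_monotone_rho_one(self):
        res = self._run([1, 2, 3, 5, 8], [1, 2, 3, 4, 5])
        assert res.loc["g", "spearman_rho"] == pytest.approx(1.0)

    def test_rank_formula_example(self):
        # one swapped pair among five: rho = 1 - 6*2/(5*24) = 0.9
        res = self._run([1, 3, 2, 4, 5], [1, 2, 3, 4, 5])
        assert res.loc["g", "spearman_rho"] == pytest.approx(0.9)

    def test_constant_expression_degenerate(self):
        res = self._run([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])
        assert res.loc["g", "spearman_rho"] == 0.0
        assert bool(res.loc["g", "degenerate"])

    def test_sign_flips_with_axis(self):
        a = self._run([1, 3, 2, 4, 5], [1, 2, 3, 4, 5])
        b = self._run([1, 3, 2, 4, 5], [-1, -2, -3, -4, -5])
        assert a.loc["g", "spearman_rho"] == pytest.approx(
            -b.loc["g", "spearman_rho"])

    def test_matches_scipy_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        coord = rng.uniform(size=12)
        theta = pd.DataFrame(np.eye(12),
                             index=[f"m{i}" for i in range(12)],
                             columns=[f"s{i}" for i in range(12)])
        expr = pd.DataFrame(rng.integers(0, 4, size=(20, 12)).astype(float),
                            index=[f"g{i}" for i in range(20)],
                            columns=theta.index)
        res = spatial_trend(expr, theta, coord)
        for g in expr.index:
            if res.loc[g, "degenerate"]:
                continue
            rho = sps.spearmanr(expr.loc[g], coord).statistic
            assert res.loc[g, "spearman_rho"] == pytest.approx(rho,
                                                               abs=1e-12)

    def test_too_few_groups_rejected(self):
        theta = pd.DataFrame(np.eye(4))
        expr = pd.DataFrame([[1, 2, 3, 4]], index=["g"],
                            columns=theta.index)
        with pytest.raises(ValueError):
            spatial_trend(expr, theta, np.arange(4.0))

    def test_expected_coordinate_weighting(self, model, posts_small):
        theta = tq.posteriors_to_frame(posts_small, model.n_sbins)
        sbin_cols = [c for c in theta.columns if c.startswith("sbin_")]
        coord = model.sbin_coords()["pd"]
        from tattooseq.stats import expected_coordinate
        c = expected_coordinate(theta[sbin_cols], coord)
        assert ((c >= 0) & (c <= 1)).all()


class TestTFSpecificity:
    def test_one_hot_auc(self):
        v = np.zeros(10)
        v[3] = 5.0
        auc, degenerate = tf_specificity_auc(v)
        assert auc == pytest.approx(0.9, abs=1e-9)
        assert not degenerate

    def test_symmetric_two_group(self):
        auc, _ = tf_specificity_auc([0.0, 1.0])
        assert auc == pytest.approx(0.5, abs=1e-9)

    def test_equally_spaced_values(self):
        auc, _ = tf_specificity_auc(np.linspace(0, 1, 101))
        assert auc == pytest.approx(0.5, abs=0.01)

    def test_constant_gene_degenerate(self):
        auc, degenerate = tf_specificity_auc([2.0, 2.0, 2.0])
        assert auc == 0.5
        assert degenerate

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=30),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, values, a, b):
        from hypothesis import assume
        v = np.asarray(values)
        # a well-separated range keeps the min-max rescaling numerically
        # meaningful after the shift
        assume(np.ptp(v) >= 1e-3)
        auc1, _ = tf_specificity_auc(v)
        auc2, _ = tf_specificity_auc(a * v + b)
        assert auc1 == pytest.approx(auc2, abs=1e-6)

    def test_table_matches_scalar(self):
        expr = pd.DataFrame([[0, 0, 1.0], [1, 2, 3.0]],
                            index=["a", "b"])
        tab = tf_specificity_table(expr)
        assert tab.loc["a", "auc"] == tf_specificity_auc([0, 0, 1.0])[0]


class TestBatchyGenes:
    def test_requires_two_batches(self):
        cm = _toy_cm(np.full((3, 4), 100), batch=[0, 0, 0, 0])
        groups = pd.DataFrame({"cell_id": [f"c{i}" for i in range(4)],
                               "group_id": "g"})
        with pytest.raises(ValueError):
            tq.detect_batchy_genes(cm, groups)

    def test_no_eligible_group_warns(self):
        cm = _toy_cm(np.full((3, 6), 100), batch=[0, 1, 0, 1, 0, 1])
        groups = pd.DataFrame({"cell_id": [f"c{i}" for i in range(6)],
                               "group_id": "g"})
        msgs = []
        res = tq.detect_batchy_genes(cm, groups, warn=msgs.append)
        assert msgs and not res.batchy.any()

    def test_detects_engineered_effect(self, model):
        cfg = tq.SimulationConfig(
            seed=9, n_limbs_per_pattern=2, n_cells_per_limb=400,
            n_genes=300, n_types=2, n_spatial=0,
            program_concentration=30.0, depth_log_sd=0.05,
            batch_effect={7: 4.0})
        _, cm, truth = tq.simulate_limb_dataset(cfg, model)
        groups, _ = tq.make_metacells(truth, model, scheme="by-position",
                                      n_regions=8, seed=9)
        res = tq.detect_batchy_genes(cm, groups, seed=9)
        assert bool(res.batchy.iloc[7])
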