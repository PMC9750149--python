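"""Self-contained validation studies exercising the whole pipeline.

Each function builds its own synthetic inputs at a stated problem size,
runs the relevant stages end to end, and returns summary metrics.  They
back both the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import skewnorm

from . import colors as _colors
from . import inference as _inf
from . import simulate as _sim
from . import stats as _stats
from .geometry import LimbModel


def recovery_study(model: LimbModel, seed: int = 0,
                   n_limbs_per_pattern: int = 4,
                   n_cells_per_limb: int = 3500,
                   min_group_size: int = 300) -> dict:
    """Position recovery for spatially coherent metacells.

    Simulates a full experiment, forms metacells of at least
    ``min_group_size`` cells (cells of one type concentrated in one sbin),
    runs color calling and KL inference, and reports the total-variation
    distance between inferred and true sbin distributions.
    """
    cfg = _sim.SimulationConfig(seed=seed,
                                n_limbs_per_pattern=n_limbs_per_pattern,
                                n_cells_per_limb=n_cells_per_limb,
                                n_genes=30, n_spatial=0, n_types=6)
    facs, _, truth = _sim.simulate_limb_dataset(cfg, model)
    calls = _colors.call_colors(facs, seed=seed)
    groups, theta_true = _sim.make_metacells(truth, model,
                                             min_size=min_group_size,
                                             seed=seed)
    posts = _inf.infer_groups(calls, groups, model.grid.forward, seed=seed)
    tvs = np.array([
        0.5 * np.abs(p.theta - theta_true.loc[p.group_id].to_numpy()).sum()
        for p in posts])
    return {
        "n_groups": len(posts),
        "min_group_size": int(groups.groupby("group_id").size().min()),
        "median_tv": float(np.median(tvs)),
        "p90_tv": float(np.quantile(tvs, 0.9)),
        "tvs": tvs,
    }


def toy_optimizer_gap(seed: int = 0, grid_step: float = 0.01) -> dict:
    """Constrained minimizer vs exhaustive simplex grid on 3 sbins."""
    forward = {
        "PD": np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], float),
        "AP": np.array([[0, 0, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0]], float),
        "AER": np.array([[0.6, 0.3, 0.1, 0], [0.2, 0.5, 0.3, 0],
                         [0.1, 0.2, 0.7, 0]], float),
    }
    emp = _inf.EmpiricalFluorescence(
        "toy", {"PD": np.array([30, 50, 20]),
                "AP": np.array([55, 15, 30]),
                "AER": np.array([35, 40, 25])}, epsilon=1.0)
    post = _inf.infer_sbin_distribution(emp, forward, seed=seed)
    steps = int(round(1.0 / grid_step))
    best = np.inf
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            theta = np.array([i, j, steps - i - j]) / steps
            best = min(best, _inf.kl_objective(theta, emp, forward))
    return {"optimizer_objective": post.objective,
            "grid_objective": float(best),
            "gap": float(post.objective - best)}


def em_recovery_study(seed: int = 0, n_sims: int = 20, n: int = 2000,
                      omega: float = 0.5, alpha: float = 2.0,
                      separation: float = 4.0) -> dict:
    """Mean recovery of seeded 3-component skew-normal mixtures.

    Component locations are spaced ``separation * omega`` apart with
    mixing weights (0.5, 0.3, 0.2); reports the worst absolute error of
    the recovered component means across ``n_sims`` seeded fits.
    """
    locs = np.array([0.0, 1.0, 2.0]) * separation * omega
    weights = (0.5, 0.3, 0.2)
    worst = 0.0
    for k in range(n_sims):
        rng = np.random.default_rng(seed + k)
        ns = rng.multinomial(n, weights)
        x = np.concatenate([
            skewnorm.rvs(alpha, loc=loc, scale=omega, size=m,
                         random_state=rng)
            for loc, m in zip(locs, ns)])
        true_means = [skewnorm.mean(alpha, loc=loc, scale=omega)
                      for loc in locs]
        fit = _colors.fit_skew_normal_mixture(x, 3, seed=seed + k)
        err = max(abs(c.mean - t)
                  for c, t in zip(fit.components, true_means))
        worst = max(worst, err)
    return {"max_mean_error": float(worst), "n_sims": n_sims}


def color_accuracy_study(model: LimbModel, seed: int = 0,
                         n_limbs_per_pattern: int = 2,
                         n_cells_per_limb: int = 1500) -> dict:
    """End-to-end color-call accuracy at default fluorescence noise."""
    cfg = _sim.SimulationConfig(seed=seed,
                                n_limbs_per_pattern=n_limbs_per_pattern,
                                n_cells_per_limb=n_cells_per_limb,
                                n_genes=20, n_spatial=0)
    facs, _, truth = _sim.simulate_limb_dataset(cfg, model)
    calls = _colors.call_colors(facs, seed=seed)
    merged = calls.merge(truth.cells[["cell_id", "true_color"]],
                         on="cell_id")
    return {"accuracy": float((merged.color == merged.true_color).mean()),
            "n_cells": len(merged)}


def _regression_run(model, seed, n_spatial, detection_umi=100):
    cfg = _sim.SimulationConfig(
        seed=seed, n_limbs_per_pattern=2, n_cells_per_limb=500,
        n_genes=2000, n_types=1, n_spatial=n_spatial,
        spatial_axes=("pd",), spatial_kinds=("linear",))
    _, cm, truth = _sim.simulate_limb_dataset(cfg, model)
    groups, theta_true = _sim.make_metacells(
        truth, model, scheme="by-position", min_size=20, seed=seed,
        n_regions=40)
    prof = _stats.MetacellProfile.from_counts(cm, groups)
    detected = prof.totals.sum(axis=1) > detection_umi
    res = _stats.spatial_regression(prof.log_expression()[detected],
                                    theta_true.loc[prof.totals.columns])
    return res, truth


def regression_null_study(model: LimbModel, seed: int = 0,
                          n_runs: int = 100) -> dict:
    """Type-I control: fraction of null runs with any Bonferroni hit.

    Each run simulates 2000 genes with no spatial structure across about
    40 spatially coherent groups and tests every detected gene at
    Bonferroni-adjusted alpha = 0.01.
    """
    hits = 0
    for r in range(n_runs):
        res, _ = _regression_run(model, seed + 10_000 + r, n_spatial=0)
        hits += int(res.is_spatial.sum() > 0)
    return {"runs_with_false_positive": hits, "n_runs": n_runs,
            "fraction": hits / n_runs}


def regression_power_study(model: LimbModel, seed: int = 0,
                           n_runs: int = 20) -> dict:
    """Power for 4x proximal-distal gradient genes, plus false positives
    among the non-spatial genes of the same runs."""
    powers, fp_runs = [], 0
    for r in range(n_runs):
        res, truth = _regression_run(model, seed + 20_000 + r,
                                     n_spatial=40)
        spatial = set(truth.genes[truth.genes.is_spatial].gene)
        in_universe = res.index.isin(spatial)
        powers.append(float(res.loc[in_universe, "is_spatial"].mean()))
        fp_runs += int(res.loc[~in_universe, "is_spatial"].sum() > 0)
    return {"mean_power": float(np.mean(powers)),
            "runs_with_false_positive": fp_runs, "n_runs": n_runs}


def thickness_study(model: LimbModel, seed: int = 0,
                    n_cells_total: int = 50_000) -> dict:
    """Spearman agreement of inferred and generating thickness profiles."""
    from scipy.stats import spearmanr

    per_limb = int(np.ceil(n_cells_total / 12 * 1.12))
    cfg = _sim.SimulationConfig(seed=seed, n_limbs_per_pattern=4,
                                n_cells_per_limb=per_limb, n_genes=20,
                                n_spatial=0)
    facs, _, truth = _sim.simulate_limb_dataset(cfg, model)
    calls = _colors.call_colors(facs, seed=seed)
    thick, _ = _inf.infer_thickness(calls, model.grid.forward,
                                    model.grid.areas, seed=seed)
    field = _sim._thickness_field(cfg.thickness, model)
    px = np.asarray(model.shape.pd_coord(truth.cells.x.to_numpy()))
    py = np.asarray(model.shape.ap_coord(truth.cells.y.to_numpy()))
    per_cell = field(px, py)
    true_thick = pd.Series(per_cell).groupby(
        truth.cells.sbin.to_numpy()).mean().reindex(
        range(model.n_sbins)).to_numpy()
    rho = spearmanr(thick, true_thick).statistic
    return {"spearman": float(rho), "n_cells": len(facs)}
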