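"""Synthetic photoconversion-indexed scRNA-seq experiments with ground truth.

The generator emulates the data-generating process the inference assumes:
cells occupy positions in the 2D limb model (sampled proportionally to a
configurable thickness field), each limb is photoconverted with one
pattern, the cell's color follows deterministically from its position and
the pattern's regions, and the measured fluorescence is produced by drawing
the ratio-of-logs statistic s from a per-color skew-normal component and
inverting it at a drawn FITC intensity (PE = 2^(s * log2 FITC)).  UMI
counts are multinomial draws from cell-type expression programs modulated
multiplicatively by spatial gene gradients at the cell's position.

Every output row is tied to ground truth (position, sbin, true color, cell
type, batch, spatial-gene flags and per-group sbin occupancy), so each
downstream stage can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import skewnorm

from .geometry import COLORS, LimbModel
from .stats import CountMatrix


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Fluorescence defaults put adjacent color components about 4.3 scale
    units apart (xi spacing 0.3, omega 0.07), a separation at which the
    mixture modes are distinct but overlapping, comparable to well-resolved
    sorter data.  The AER pattern lays down four degrees; the two red-most
    components (xi 1.6 and 1.9) are generated separately and merged by the
    caller, mirroring the acquisition.
    """

    n_limbs_per_pattern: int = 2
    n_cells_per_limb: int = 1500
    # ratio-of-logs component locations for effective colors green/yellow/red
    s_xi: tuple = (1.0, 1.3, 1.6)
    s_xi_red4: float = 1.9       # red-most AER degree
    s_omega: float = 0.07
    s_alpha: float = 2.0
    misassignment_rate: float = 0.0
    thickness: str = "half_ellipse"  # or "uniform"
    # gene panel
    n_genes: int = 600
    n_types: int = 4
    # Dirichlet concentration of the per-type expression programs; small
    # values give skewed, sparse panels, large values near-flat ones
    program_concentration: float = 0.5
    n_spatial: int = 60
    spatial_effect: float = 4.0
    spatial_axes: tuple = ("pd", "ap", "aer")
    spatial_kinds: tuple = ("linear", "logistic")
    depth_log_mean: float = np.log(3000.0)
    depth_log_sd: float = 0.35
    fitc_log_mean: float = np.log(500.0)
    fitc_log_sd: float = 0.4
    n_batches: int = 2
    # gene index -> multiplicative fold applied in batch 1
    batch_effect: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-cell, per-gene and per-group generating truth."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    config: SimulationConfig


def _thickness_field(kind: str, model: LimbModel):
    if kind == "uniform":
        return lambda px, py: np.ones_like(px)
    if kind == "half_ellipse":
        # limb thins from the flank toward the distal tip, like the section
        # of a flattened half-ellipsoid
        return lambda px, py: np.sqrt(np.clip(1.0 - 0.9 * px ** 2,
                                              0.05, None))
    raise ValueError(f"unknown thickness field: {kind}")


def _sample_positions(model: LimbModel, n: int, thickness, rng):
    x0, y0, x1, y1 = model.shape.bounds
    xs, ys = [], []
    need = n
    while need > 0:
        m = max(4 * need, 256)
        px = rng.uniform(x0, x1, m)
        py = rng.uniform(y0, y1, m)
        inside = shapely.contains_xy(model.shape.polygon, px, py)
        t = thickness(np.asarray(model.shape.pd_coord(px)),
                      np.asarray(model.shape.ap_coord(py)))
        keep = inside & (rng.uniform(size=m) < t)
        xs.append(px[keep])
        ys.append(py[keep])
        need = n - sum(len(a) for a in xs)
    return np.concatenate(xs)[:n], np.concatenate(ys)[:n]


def _true_colors(model: LimbModel, pattern: str, x, y):
    """Deterministic color of each position under one pattern.

    Returns color index 0/1/2 (green/yellow/red) or -1 for missed; under
    the AER pattern, index 3 marks the red-most (fourth) degree.
    """
    pts = shapely.points(x, y)
    pat = model.patterns[pattern]
    out = np.full(len(x), -1, dtype=int)
    for ci, c in enumerate(COLORS):
        hit = shapely.covers(pat.regions[c], pts)
        out[hit & (out < 0)] = ci
    if pattern != "AER":
        # boundary points can be missed by covers(); snap via distance
        for idx in np.flatnonzero(out < 0):
            d = [pat.regions[c].distance(pts[idx]) for c in COLORS]
            out[idx] = int(np.argmin(d))
    else:
        w = model.shape.config["aer_band_width"]
        d = np.array([model.shape.aer_arc.distance(p)
                      for p in pts])
        out[(out == 2) & (d < w)] = 3
    return out


def _spatial_factor(kind, coord, effect):
    if kind == "linear":
        g = coord
    elif kind == "logistic":
        g = 1.0 / (1.0 + np.exp(-10.0 * (coord - 0.5)))
    else:
        raise ValueError(f"unknown gradient kind: {kind}")
    return effect ** g


def simulate_limb_dataset(config: SimulationConfig, model: LimbModel):
    """Generate one synthetic experiment.

    Returns ``(facs, counts, truth)``: the per-cell FACS index table, the
    genes-by-cells UMI count matrix with metadata, and the ground truth.
    Cells in the proximal third of AER-patterned limbs are dropped (never
    collected), so those limbs yield fewer cells than sampled.
    """
    rng = np.random.default_rng(config.seed)
    thick = _thickness_field(config.thickness, model)

    gene_names = [f"gene_{i:04d}" for i in range(config.n_genes)]
    programs = rng.dirichlet(
        np.full(config.n_genes, config.program_concentration),
        size=config.n_types)
    # spatial genes are drawn from the better-expressed half of the panel:
    # a positional gradient on a gene nobody detects is not a usable truth
    mean_prog = programs.mean(axis=0)
    eligible = np.flatnonzero(mean_prog >= np.median(mean_prog))
    spatial_idx = rng.choice(eligible, size=min(config.n_spatial,
                                                len(eligible)),
                             replace=False)
    axes = np.array(config.spatial_axes)[
        np.arange(config.n_spatial) % len(config.spatial_axes)]
    kinds = np.array(config.spatial_kinds)[
        (np.arange(config.n_spatial) // len(config.spatial_axes))
        % len(config.spatial_kinds)]
    genes = pd.DataFrame({"gene": gene_names})
    genes["is_spatial"] = False
    genes.loc[spatial_idx, "is_spatial"] = True
    genes["axis"] = ""
    genes.loc[spatial_idx, "axis"] = axes
    genes["kind"] = ""
    genes.loc[spatial_idx, "kind"] = kinds
    # gradient orientation alternates so that spatially regulated genes
    # rise toward either end of their axis, as real patterning genes do;
    # this also keeps the panel's total UMI mass roughly position-neutral
    directions = np.where(np.arange(config.n_spatial) % 2 == 0, 1, -1)
    genes["direction"] = 0
    genes.loc[spatial_idx, "direction"] = directions
    genes["effect"] = 1.0
    genes.loc[spatial_idx, "effect"] = config.spatial_effect

    cell_rows, facs_rows, count_blocks = [], [], []
    limb_no = 0
    for pattern in ("PD", "AP", "AER"):
        for _ in range(config.n_limbs_per_pattern):
            limb = f"limb_{limb_no:02d}"
            batch = limb_no % config.n_batches
            limb_no += 1
            x, y = _sample_positions(model, config.n_cells_per_limb,
                                     thick, rng)
            col4 = _true_colors(model, pattern, x, y)
            keep = col4 >= 0
            x, y, col4 = x[keep], y[keep], col4[keep]
            n = len(x)
            eff = np.minimum(col4, 2)   # effective color (merged red)
            if config.misassignment_rate > 0:
                flip = rng.uniform(size=n) < config.misassignment_rate
                eff[flip] = rng.integers(0, 3, size=flip.sum())
            xi = np.choose(np.minimum(col4, 2),
                           np.asarray(config.s_xi))
            xi = np.where(col4 == 3, config.s_xi_red4, xi)
            s = skewnorm.rvs(config.s_alpha, loc=xi, scale=config.s_omega,
                             size=n, random_state=rng)
            fitc = np.exp(rng.normal(config.fitc_log_mean,
                                     config.fitc_log_sd, n))
            fitc = np.maximum(fitc, 2.0)
            pe = 2.0 ** (s * np.log2(fitc))
            sbin = model.sbin_of_points(x, y)
            ctype = rng.integers(0, config.n_types, size=n)
            depth = np.exp(rng.normal(config.depth_log_mean,
                                      config.depth_log_sd, n))
            depth = np.clip(depth, 200, 30000).astype(int)

            px = np.asarray(model.shape.pd_coord(x))
            py = np.asarray(model.shape.ap_coord(y))
            dd = np.array([model.shape.aer_arc.distance(p)
                           for p in shapely.points(x, y)])
            da = dd / dd.max() if dd.max() > 0 else dd
            coords = {"pd": px, "ap": py, "aer": da}
            probs = programs[ctype]          # n x n_genes
            factors = np.ones((n, len(spatial_idx)))
            for j in range(len(spatial_idx)):
                c = coords[axes[j]]
                if directions[j] < 0:
                    c = 1.0 - c
                factors[:, j] = _spatial_factor(kinds[j], c,
                                                config.spatial_effect)
            probs = probs.copy()
            probs[:, spatial_idx] *= factors
            if config.batch_effect and batch == 1:
                for gi, fold in config.batch_effect.items():
                    probs[:, gi] *= fold
            probs /= probs.sum(axis=1, keepdims=True)
            counts = np.vstack([rng.multinomial(depth[i], probs[i])
                                for i in range(n)])
            count_blocks.append(counts)

            ids = [f"{limb}_c{i:05d}" for i in range(n)]
            facs_rows.append(pd.DataFrame({
                "cell_id": ids, "limb_id": limb, "pattern": pattern,
                "pe": pe, "fitc": fitc}))
            cell_rows.append(pd.DataFrame({
                "cell_id": ids, "limb_id": limb, "pattern": pattern,
                "batch": batch, "x": x, "y": y, "sbin": sbin,
                "true_color": np.array(COLORS)[eff],
                "true_degree": col4, "cell_type": ctype,
                "depth": depth, "s_true": s}))

    facs = pd.concat(facs_rows, ignore_index=True)
    cells = pd.concat(cell_rows, ignore_index=True)
    counts = np.vstack(count_blocks).T   # genes x cells
    cm = CountMatrix(
        counts=counts,
        genes=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
        cells=cells.set_index("cell_id")[
            ["limb_id", "pattern", "batch", "cell_type"]].copy(),
    )
    truth = GroundTruth(cells=cells, genes=genes, config=config)
    return facs, cm, truth


def true_theta(cells: pd.DataFrame, groups: pd.DataFrame,
               n_sbins: int) -> pd.DataFrame:
    """Ground-truth sbin occupancy per group from member positions."""
    merged = groups.merge(cells[["cell_id", "sbin"]], on="cell_id")
    rows = {}
    for gid, sub in merged.groupby("group_id", sort=True):
        counts = np.bincount(sub["sbin"], minlength=n_sbins).astype(float)
        rows[gid] = counts / counts.sum()
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"sbin_{i}" for i in range(n_sbins)])
    df.index.name = "group_id"
    return df


def make_metacells(truth: GroundTruth, model: LimbModel,
                   scheme: str = "by-type-and-region",
                   min_size: int = 20, seed: int = 0, n_regions: int = 40):
    """Partition simulated cells into metacell-like groups.

    ``by-type-and-region`` groups cells sharing a cell type and a sbin
    (spatially coherent, as real metacells are); ``by-position`` clusters
    cells into ``n_regions`` spatial clusters irrespective of type;
    ``random`` shuffles cells into the same number of groups.  Groups smaller than ``min_size`` are
    merged into the spatially nearest group.  Returns the assignment table
    and the ground-truth theta per group.
    """
    cells = truth.cells
    rng = np.random.default_rng(seed)
    if scheme == "by-type-and-region":
        key = cells["cell_type"].astype(str) + ":" + cells["sbin"].astype(str)
    elif scheme == "by-position":
        # fine spatial clusters regardless of type: k-means on positions,
        # seeded from a quantile grid (deterministic given seed)
        from scipy.cluster.vq import kmeans2

        pts = cells[["x", "y"]].to_numpy()
        k = int(n_regions)
        _, lab = kmeans2(pts, k, minit="++", seed=seed)
        key = pd.Series(lab, index=cells.index).astype(str)
    elif scheme == "random":
        n_groups = max(cells["cell_type"].nunique() * model.n_sbins // 2, 2)
        key = pd.Series(rng.integers(0, n_groups, size=len(cells)),
                        index=cells.index).astype(str)
    else:
        raise ValueError(f"unknown scheme: {scheme}")
    assign = pd.DataFrame({"cell_id": cells["cell_id"], "key": key.values,
                           "x": cells["x"], "y": cells["y"]})
    centroids = assign.groupby("key")[["x", "y"]].mean()
    sizes = assign["key"].value_counts()
    big = sizes[sizes >= min_size].index
    if len(big) == 0:
        raise ValueError("no group reaches the minimum size")
    remap = {}
    for k in sizes.index:
        if k in set(big):
            remap[k] = k
        else:
            d = ((centroids.loc[big] - centroids.loc[k]) ** 2).sum(axis=1)
            remap[k] = d.idxmin()
    assign["group_id"] = assign["key"].map(remap)
    ids = {k: f"mc_{i:03d}" for i, k in
           enumerate(sorted(assign["group_id"].unique()))}
    assign["group_id"] = assign["group_id"].map(ids)
    groups = assign[["cell_id", "group_id"]].reset_index(drop=True)
    theta = true_theta(cells, groups, model.n_sbins)
    return groups, theta
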