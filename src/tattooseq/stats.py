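"""Spatial and cell-state statistics on UMI counts.

Projects gene expression into space through the inferred per-group sbin
distributions (virtual in situ hybridization), classifies genes as
spatially regulated by regressing expression on the sbin distributions
(overall F-test, Bonferroni-corrected), scores monotonic positional trends
by Spearman correlation against expected coordinates, quantifies
transcription-factor specificity by the area under the empirical CDF of
rescaled expression, and detects batch-driven genes by resampling
aggregated UMIs between batches within metacells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps


def _dense(a):
    return a.toarray() if sp.issparse(a) else np.asarray(a)


@dataclass
class CountMatrix:
    """Genes-by-cells UMI counts with aligned metadata.

    ``counts`` may be dense or scipy-sparse; ``genes`` is indexed by gene
    symbol and ``cells`` by cell id, in matrix order.
    """

    counts: object
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self):
        ng, nc = self.counts.shape
        if len(self.genes) != ng or len(self.cells) != nc:
            raise ValueError("metadata rows do not match matrix dimensions")
        vals = self.counts.data if sp.issparse(self.counts) \
            else np.asarray(self.counts)
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be nonnegative integers")

    @property
    def n_genes(self):
        return self.counts.shape[0]

    @property
    def n_cells(self):
        return self.counts.shape[1]

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def umi_per_gene(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        c = self.counts
        genes, cells = self.genes, self.cells
        if gene_mask is not None:
            c = c[gene_mask, :]
            genes = genes.loc[gene_mask] if gene_mask.dtype == bool \
                else genes.iloc[gene_mask]
        if cell_mask is not None:
            c = c[:, cell_mask]
            cells = cells.loc[cell_mask] if cell_mask.dtype == bool \
                else cells.iloc[cell_mask]
        return CountMatrix(counts=c, genes=genes.copy(), cells=cells.copy())


def qc_filter(cm: CountMatrix, min_umi=2000, max_umi=15000,
              drop_mito: bool = True, mito_prefix: str = "mt-",
              warn=None) -> CountMatrix:
    """Remove low/high-depth cells and mitochondrial genes.

    ``min_umi`` may be a scalar or a mapping from batch label to threshold
    (plates processed in separate batches can warrant different cutoffs).
    Cells with totals outside [min_umi, max_umi] are dropped (low-quality
    transcriptomes and potential doublets respectively); genes whose symbol
    starts with ``mito_prefix`` are removed before downstream totals are
    recomputed.  The operation is idempotent.
    """
    if cm.n_cells == 0:
        return cm
    totals = cm.umi_per_cell()
    if isinstance(min_umi, dict):
        lo = cm.cells["batch"].map(min_umi).to_numpy(float)
    else:
        lo = float(min_umi)
    if np.any(np.asarray(lo) >= max_umi):
        raise ValueError("min_umi must be below max_umi")
    keep_cells = (totals >= lo) & (totals <= max_umi)
    keep_genes = np.ones(cm.n_genes, dtype=bool)
    if drop_mito:
        keep_genes = ~cm.genes.index.astype(str).str.startswith(mito_prefix)
        keep_genes = keep_genes.to_numpy() if hasattr(keep_genes, "to_numpy") \
            else np.asarray(keep_genes)
    out = cm.subset(gene_mask=keep_genes, cell_mask=keep_cells)
    if out.n_cells == 0 and warn is not None:
        warn("QC filter removed every cell")
    return out


@dataclass
class MetacellProfile:
    """Aggregated per-group expression: totals, fractions, enrichment.

    ``fraction`` columns sum to 1 per group; ``enrichment`` is each group's
    fraction divided by the gene's median fraction across groups (infinite
    where the median is 0 but the gene is detected in the group).
    """

    totals: pd.DataFrame       # genes x groups, UMI sums
    fraction: pd.DataFrame
    enrichment: pd.DataFrame

    @classmethod
    def from_counts(cls, cm: CountMatrix,
                    groups: pd.DataFrame) -> "MetacellProfile":
        gmap = groups.set_index("cell_id")["group_id"]
        labels = cm.cells.index.map(gmap)
        keep = ~labels.isna()
        mat = _dense(cm.counts)[:, np.asarray(keep)]
        labels = np.asarray(labels[keep])
        ids = np.unique(labels)
        tot = np.column_stack([mat[:, labels == g].sum(axis=1) for g in ids])
        totals = pd.DataFrame(tot, index=cm.genes.index, columns=ids)
        frac = totals / totals.sum(axis=0)
        med = frac.median(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = frac.div(med, axis=0)
        enr = enr.where(~((med == 0).to_numpy()[:, None] & (frac > 0)),
                        np.inf)
        enr = enr.fillna(1.0)  # genes absent everywhere
        return cls(totals=totals, fraction=frac, enrichment=enr)

    def log_expression(self, scale: float = 1e4) -> pd.DataFrame:
        """log2(fraction * scale + 1), the transform used for regression
        and trend statistics."""
        return np.log2(self.fraction * scale + 1.0)


# ---------------------------------------------------------------------------
# virtual in situ hybridization


def gene_group_weights(cm: CountMatrix, groups: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalized per-group gene weights (genes x groups).

    Each cell's counts are divided by its total UMIs before summing per
    group, so that a "random UMI" is not dominated by deep cells.
    """
    gmap = groups.set_index("cell_id")["group_id"]
    labels = cm.cells.index.map(gmap)
    keep = ~labels.isna()
    mat = _dense(cm.counts)[:, np.asarray(keep)].astype(float)
    depth = mat.sum(axis=0)
    depth[depth == 0] = 1.0
    mat = mat / depth
    labels = np.asarray(labels[keep])
    ids = np.unique(labels)
    w = np.column_stack([mat[:, labels == g].sum(axis=1) for g in ids])
    return pd.DataFrame(w, index=cm.genes.index, columns=ids)


def vish(gene, weights: pd.DataFrame, theta: pd.DataFrame) -> np.ndarray:
    """Virtual in situ hybridization map of one gene.

    The probability that a random UMI of ``gene`` lies in each sbin:
    a mixture of the groups' sbin distributions weighted by the gene's
    depth-normalized expression per group.
    """
    return aggregate_vish([gene], weights, theta)


def aggregate_vish(genes, weights: pd.DataFrame,
                   theta: pd.DataFrame) -> np.ndarray:
    """vISH of a gene set: group weights summed over the member genes."""
    w = weights.loc[list(genes)].sum(axis=0)
    w = w.reindex(theta.index).fillna(0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("gene set has no UMIs; vISH undefined")
    mix = (w / total).to_numpy()
    return mix @ theta.to_numpy()


def celltype_vish(gene, weights: pd.DataFrame, theta: pd.DataFrame,
                  annotation: pd.Series, cell_type) -> np.ndarray:
    """vISH of a gene restricted to groups of one annotation, renormalized."""
    keep = annotation[annotation == cell_type].index
    keep = [g for g in theta.index if g in set(keep)]
    if not keep:
        raise ValueError(f"no groups annotated {cell_type!r}")
    return vish(gene, weights.loc[:, keep], theta.loc[keep])


# ---------------------------------------------------------------------------
# spatial regression


def spatial_regression(expression: pd.DataFrame, theta: pd.DataFrame,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Classify genes as spatially regulated by regression on sbin space.

    Ordinary least squares of each gene's transformed expression (rows of
    ``expression``: genes; columns: groups) on the groups' sbin
    distributions.  The sbin rows sum to 1, so the intercept lies in the
    column space and the overall F-test compares against the best constant
    fit.  Collinear sbin columns are dropped via pivoted QR.  P-values are
    Bonferroni-corrected over all tested genes; a gene is called spatial
    when the adjusted p-value is below ``alpha``.
    """
    groups = theta.index
    Y = expression.loc[:, groups].to_numpy(float).T   # n_groups x n_genes
    X = theta.to_numpy(float)
    n, k_full = X.shape
    # pivoted QR to drop collinear columns
    from scipy.linalg import qr as _qr
    _, r, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > max(X.shape) * np.finfo(float).eps * diag[0]))
    Xr = X[:, np.sort(piv[:rank])]
    if n <= rank + 1:
        raise ValueError("need more groups than retained sbin columns")
    beta, _, _, _ = np.linalg.lstsq(Xr, Y, rcond=None)
    resid = Y - Xr @ beta
    rss1 = (resid ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df1, df0 = n - rank, n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss1) / (df0 - df1)) / (rss1 / df1)
        r2 = 1.0 - rss1 / rss0
    constant = rss0 <= 1e-300
    f = np.where(constant, 0.0, f)
    r2 = np.clip(np.where(constant, 0.0, r2), 0.0, 1.0)
    p = sps.f.sf(f, df0 - df1, df1)
    p = np.where(constant, 1.0, p)
    p_adj = np.minimum(p * len(expression), 1.0)
    return pd.DataFrame({
        "gene": expression.index,
        "r_squared": r2,
        "f_statistic": f,
        "p_value": p,
        "p_adjusted": p_adj,
        "is_spatial": p_adj < alpha,
    }).set_index("gene")


# ---------------------------------------------------------------------------
# positional trends


def expected_coordinate(theta: pd.DataFrame, coord: np.ndarray) -> pd.Series:
    """Expected axis coordinate of each group, sum_s theta(s) * coord(s)."""
    return pd.Series(theta.to_numpy() @ np.asarray(coord, float),
                     index=theta.index)


def spatial_trend(expression: pd.DataFrame, theta: pd.DataFrame,
                  coord: np.ndarray, totals: pd.DataFrame | None = None,
                  enrichment: pd.DataFrame | None = None,
                  min_umi: int = 100,
                  variability_fold: float = 1.5) -> pd.DataFrame:
    """Monotonic positional trends of gene expression (Spearman).

    For each gene, correlates expression across groups with the groups'
    expected coordinate along one axis.  Also reports the detection filter
    (more than ``min_umi`` UMIs in total over the groups) and the
    variability filter (at least one group above ``variability_fold`` times
    the median expression).  Genes constant across groups get rho = 0 and a
    degenerate flag.
    """
    groups = theta.index
    if len(groups) < 5:
        raise ValueError("need at least 5 groups for a trend")
    c = expected_coordinate(theta, coord)
    E = expression.loc[:, groups].to_numpy(float)
    rc = sps.rankdata(c.to_numpy())
    rE = sps.rankdata(E, axis=1)
    rc_c = rc - rc.mean()
    rE_c = rE - rE.mean(axis=1, keepdims=True)
    denom = np.sqrt((rE_c ** 2).sum(axis=1) * (rc_c ** 2).sum())
    degenerate = denom <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rE_c @ rc_c) / denom
    rho = np.where(degenerate, 0.0, rho)
    n = len(groups)
    # t approximation for the Spearman p-value
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame({
        "gene": expression.index,
        "spearman_rho": rho,
        "p_value": p,
        "degenerate": degenerate,
    }).set_index("gene")
    if totals is not None:
        out["passes_detection"] = \
            totals.loc[out.index, groups].sum(axis=1) > min_umi
    if enrichment is not None:
        out["passes_variability"] = \
            (enrichment.loc[out.index, groups] > variability_fold).any(axis=1)
    return out


# ---------------------------------------------------------------------------
# TF specificity


def tf_specificity_auc(values) -> tuple[float, bool]:
    """Specificity score of a gene across groups: AUC of the empirical CDF.

    Expression values are min-max rescaled to [0, 1]; the area under the
    empirical CDF over [0, 1] is returned.  Genes expressed in few groups
    have a CDF hugging 1 over most of the interval, hence a large AUC.
    Constant genes return (0.5, degenerate=True).  The score is invariant
    to affine transforms of the input.
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least two groups")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return 0.5, True
    u = np.sort((v - lo) / (hi - lo))
    m = u.size
    # exact integral of the step CDF F(x) = #{u_i <= x}/m over [0, 1]
    knots = np.concatenate([u, [1.0]])
    auc = float(np.sum((knots[1:] - knots[:-1]) * np.arange(1, m + 1) / m))
    return auc, False


def tf_specificity_table(expression: pd.DataFrame) -> pd.DataFrame:
    """AUC specificity for every gene (rows) across groups (columns)."""
    recs = [tf_specificity_auc(row) for row in expression.to_numpy()]
    return pd.DataFrame(
        {"auc": [r[0] for r in recs], "degenerate": [r[1] for r in recs]},
        index=expression.index)


# ---------------------------------------------------------------------------
# batch-driven genes


def detect_batchy_genes(cm: CountMatrix, groups: pd.DataFrame,
                        batch: pd.Series | None = None,
                        min_cells_per_batch: int = 16,
                        n_repeats: int = 10, n_sample: int = 10,
                        fold_threshold: float = 1.6,
                        seed: int = 0, warn=None) -> pd.DataFrame:
    """Flag genes whose expression differs systematically between batches.

    For each metacell with enough cells from both batches, UMIs of single
    cells are downsampled to a common depth, ``n_sample`` cells per batch
    are drawn and aggregated, and the per-gene fold change between batch
    aggregates (pseudocount 1, orientation-free) is recorded; this is
    repeated ``n_repeats`` times.  A gene is flagged batchy when its median
    fold change exceeds ``fold_threshold`` in at least one metacell.
    """
    rng = np.random.default_rng(seed)
    if batch is None:
        batch = cm.cells["batch"]
    gmap = groups.set_index("cell_id")["group_id"]
    labels = cm.cells.index.map(gmap)
    mat = _dense(cm.counts)
    batches = np.sort(batch.unique())
    if len(batches) != 2:
        raise ValueError("batchy-gene detection expects exactly two batches")
    med_folds = {}
    for gid in np.unique(labels.dropna()):
        in_g = np.asarray(labels == gid)
        idx_a = np.flatnonzero(in_g & np.asarray(batch == batches[0]))
        idx_b = np.flatnonzero(in_g & np.asarray(batch == batches[1]))
        if len(idx_a) < min_cells_per_batch or \
                len(idx_b) < min_cells_per_batch:
            continue
        cells_idx = np.concatenate([idx_a, idx_b])
        target = int(mat[:, cells_idx].sum(axis=0).min())
        folds = np.empty((n_repeats, cm.n_genes))
        for r in range(n_repeats):
            sa = rng.choice(idx_a, n_sample, replace=False)
            sb = rng.choice(idx_b, n_sample, replace=False)
            agg = []
            for sel in (sa, sb):
                acc = np.zeros(cm.n_genes, dtype=np.int64)
                for ci in sel:
                    col = mat[:, ci].astype(np.int64)
                    acc += rng.multivariate_hypergeometric(col, target)
                agg.append(acc)
            folds[r] = (agg[0] + 1.0) / (agg[1] + 1.0)
        # median of the signed fold: only a consistent direction across
        # resamples counts as a batch effect
        med = np.median(folds, axis=0)
        med_folds[gid] = np.maximum(med, 1.0 / med)
    if not med_folds:
        if warn is not None:
            warn("no metacell has enough cells from both batches")
        return pd.DataFrame({"batchy": np.zeros(cm.n_genes, bool),
                             "max_median_fold": np.full(cm.n_genes, np.nan)},
                            index=cm.genes.index)
    fold_mat = np.vstack(list(med_folds.values()))
    max_fold = fold_mat.max(axis=0)
    return pd.DataFrame({"batchy": max_fold > fold_threshold,
                         "max_median_fold": max_fold},
                        index=cm.genes.index)
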