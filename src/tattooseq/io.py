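"""Readers, writers and rendering for pipeline artifacts.

All small tables are TSV; counts are MatrixMarket triplets with companion
gene/cell TSVs (a dense TSV is accepted for toy inputs); configuration is
YAML.  Output tables carry provenance headers (seed, model checksum) as
``#``-prefixed comment lines.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml
from shapely import wkt as _wkt

from .geometry import (LimbModel, PATTERNS, Sbin, SbinGrid,
                       build_patterns)
from .stats import CountMatrix


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# ---------------------------------------------------------------------------
# counts


def write_counts(cm: CountMatrix, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.counts)
    sio.mmwrite(outdir / "counts.mtx", mat, field="integer")
    cm.genes.to_csv(outdir / "genes.tsv", sep="\t")
    cm.cells.to_csv(outdir / "cells.tsv", sep="\t")


def load_counts(path) -> CountMatrix:
    """Load a count matrix from an MTX directory or a dense TSV.

    An MTX directory holds ``counts.mtx``, ``genes.tsv`` and ``cells.tsv``
    (first columns: gene symbol / cell id).  A dense TSV has genes as rows
    and cells as columns; metadata defaults are filled in.
    """
    path = Path(path)
    if path.is_dir():
        mat = sio.mmread(path / "counts.mtx").tocsr()
        if np.any(mat.data < 0) or not np.allclose(mat.data,
                                                   np.round(mat.data)):
            raise ValueError("counts must be nonnegative integers")
        genes = pd.read_csv(path / "genes.tsv", sep="\t", index_col=0)
        cells = pd.read_csv(path / "cells.tsv", sep="\t", index_col=0)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {mat.shape} but metadata describe "
                f"{(len(genes), len(cells))}")
        return CountMatrix(counts=mat, genes=genes, cells=cells)
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be nonnegative integers")
    return CountMatrix(
        counts=vals.astype(np.int64),
        genes=pd.DataFrame(index=df.index.rename("gene")),
        cells=pd.DataFrame(index=df.columns.rename("cell_id")))


# ---------------------------------------------------------------------------
# limb model


def save_model(model: LimbModel, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(model.config_json())
    rows = []
    for s in model.grid.sbins:
        rows.append({
            "sbin": s.id, "area": s.area,
            "centroid_x": s.centroid[0], "centroid_y": s.centroid[1],
            "members": ";".join(f"{r},{c}" for r, c in s.members),
            "wkt": s.polygon.wkt,
        })
    pd.DataFrame(rows).to_csv(outdir / "sbins.tsv", sep="\t", index=False)
    for p in PATTERNS:
        pd.DataFrame(
            model.grid.forward[p],
            columns=["green", "yellow", "red", "missed"],
        ).to_csv(outdir / f"forward_{p}.tsv", sep="\t", index_label="sbin")
    meta = {"checksum": model.checksum(),
            "n_raw": model.grid.n_raw,
            "n_unmerged": model.grid.n_unmerged}
    (outdir / "meta.json").write_text(json.dumps(meta))


def load_model(indir) -> LimbModel:
    indir = Path(indir)
    cfg = json.loads((indir / "config.json").read_text())
    from .geometry import build_default_limb

    shape = build_default_limb(cfg)
    patterns = build_patterns(shape)
    sb = pd.read_csv(indir / "sbins.tsv", sep="\t")
    sbins = []
    for _, r in sb.iterrows():
        members = [tuple(int(v) for v in m.split(","))
                   for m in str(r["members"]).split(";")]
        sbins.append(Sbin(int(r["sbin"]), _wkt.loads(r["wkt"]), members))
    forward = {}
    for p in PATTERNS:
        forward[p] = pd.read_csv(indir / f"forward_{p}.tsv", sep="\t",
                                 index_col=0).to_numpy()
    meta = json.loads((indir / "meta.json").read_text())
    grid = SbinGrid(sbins=sbins, forward=forward, n_raw=meta["n_raw"],
                    n_unmerged=meta["n_unmerged"], config=cfg)
    model = LimbModel(shape=shape, patterns=patterns, grid=grid)
    if model.checksum() != meta["checksum"]:
        raise ValueError("model directory checksum mismatch")
    return model


# ---------------------------------------------------------------------------
# theta tables


class ChecksumMismatchError(ValueError):
    """Theta table was produced with a different limb model."""


def write_theta(theta_frame: pd.DataFrame, path, model: LimbModel,
                seed=None):
    """Write a per-group sbin-distribution table with provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# model_checksum: {model.checksum()}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        theta_frame.to_csv(fh, sep="\t", float_format="%.12g")


def read_theta(path, model: LimbModel | None = None) -> pd.DataFrame:
    """Read a theta table, verifying the model checksum if a model is given.

    Rows whose sbin probabilities sum to 1 within 1e-9 are accepted as-is;
    deviations up to 1e-6 are renormalized; larger deviations are errors.
    """
    path = Path(path)
    header = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                header[k.strip()] = v.strip()
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t",
                     index_col="group_id")
    if model is not None:
        want = model.checksum()
        got = header.get("model_checksum")
        if got is not None and got != want:
            raise ChecksumMismatchError(
                f"theta table was built against model {got}, not {want}; "
                "re-run inference with the current model directory")
        sbin_cols = [c for c in df.columns if c.startswith("sbin_")]
        if len(sbin_cols) != model.n_sbins:
            raise ValueError(
                f"theta table has {len(sbin_cols)} sbin columns; model has "
                f"{model.n_sbins}")
    sbin_cols = [c for c in df.columns if c.startswith("sbin_")]
    sums = df[sbin_cols].sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-6
    if bad.any():
        raise ValueError(
            f"rows do not sum to 1: {list(df.index[bad])[:5]}")
    fix = np.abs(sums - 1.0) > 1e-9
    if fix.any():
        df.loc[fix, sbin_cols] = df.loc[fix, sbin_cols].div(sums[fix],
                                                            axis=0)
    return df


# ---------------------------------------------------------------------------
# rendering


def render_map(probabilities, model: LimbModel, path=None, ax=None,
               density: bool = True, cmap: str = "viridis", title=None):
    """Draw a probability vector over sbins on the limb shape.

    With ``density`` (default) each sbin's fill encodes probability per
    unit area, the natural scale for comparing sbins of unequal size;
    otherwise raw probability is shown.  Returns the matplotlib axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon
    from matplotlib import colormaps

    p = np.asarray(probabilities, float)
    if p.shape[0] != model.n_sbins:
        raise ValueError(
            f"probability vector length {p.shape[0]} != {model.n_sbins} "
            "sbins")
    vals = p / model.grid.areas if density else p
    vmax = vals.max() if vals.max() > 0 else 1.0
    cm = colormaps[cmap]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for s, v in zip(model.grid.sbins, vals):
        geoms = getattr(s.polygon, "geoms", [s.polygon])
        for g in geoms:
            ax.add_patch(MplPolygon(np.asarray(g.exterior.coords),
                                    facecolor=cm(v / vmax),
                                    edgecolor="0.3", linewidth=0.4))
    bx = np.asarray(model.shape.polygon.exterior.coords)
    ax.plot(bx[:, 0], bx[:, 1], color="black", linewidth=1.0)
    ar = np.asarray(model.shape.aer_arc.coords)
    ax.plot(ar[:, 0], ar[:, 1], color="crimson", linewidth=2.0)
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
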