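"""2D limb-bud model: shape, photoconversion patterns, spatial bins, forward model.

The limb bud is modeled as a planar shape bounded by a closed chain of cubic
Bezier segments.  Three photoconversion layouts ("patterns") are defined on
it:

* ``PD`` — three bands of equal length along the proximal-distal axis
  (flank -> tip), colored green / yellow / red from proximal to distal;
* ``AP`` — three bands of equal length along the anterior-posterior axis,
  colored green / yellow / red from anterior to posterior;
* ``AER`` — bands of equal width by Euclidean distance to the apical
  ectodermal ridge (the marked distal arc of the boundary), defined only on
  the dissected distal two-thirds of the limb.  Four photoconversion degrees
  are laid down but the two nearest (red-most) are merged, giving three
  effective colors; cells in the proximal third are never collected under
  this pattern ("missed").

The shape is discretized into spatial bins (sbins) from an equidistant
grid along the AP-PD bounding box; each sbin carries, per pattern, a
forward distribution over {green, yellow, red, missed} proportional to the
areas photoconverted to each color.  Sbins whose forward distributions are
indistinguishable (total-variation distance below a threshold under every
pattern) are agglomeratively merged.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

COLORS = ("green", "yellow", "red")
OUTCOMES = ("green", "yellow", "red", "missed")
PATTERNS = ("PD", "AP", "AER")

#: Default geometry: a paddle-shaped limb bud, flank on the left (x = 0),
#: rounded hand plate distally.  Control points are in arbitrary planar
#: units; the PD axis is +x, the AP axis is +y (anterior -> posterior).
#: Segment 0 is the flank edge (straight); segment 3 is the distal cap
#: marked as the AER arc.
DEFAULT_GEOMETRY = {
    "segments": [
        {"kind": "line", "p0": [0.0, 0.72], "p3": [0.0, 0.28]},
        {"kind": "cubic", "p0": [0.0, 0.28], "c1": [0.22, 0.24],
         "c2": [0.38, 0.10], "p3": [0.55, 0.03]},
        {"kind": "cubic", "p0": [0.55, 0.03], "c1": [0.78, -0.01],
         "c2": [0.93, 0.12], "p3": [0.97, 0.30]},
        {"kind": "cubic", "p0": [0.97, 0.30], "c1": [1.07, 0.40],
         "c2": [1.07, 0.60], "p3": [0.97, 0.70]},
        {"kind": "cubic", "p0": [0.97, 0.70], "c1": [0.93, 0.88],
         "c2": [0.78, 1.01], "p3": [0.55, 0.97]},
        {"kind": "cubic", "p0": [0.55, 0.97], "c1": [0.38, 0.90],
         "c2": [0.22, 0.76], "p3": [0.0, 0.72]},
    ],
    "flank_segments": [0],
    "aer_segments": [3],
    # width of one photoconversion degree by distance to the AER arc,
    # roughly a quarter of the half-width ("radius") of the dissected part
    "aer_band_width": 0.115,
    # PD coordinate (fraction of limb length) of the dissection line that
    # separates the discarded proximal third from the distal part kept for
    # AER-pattern sorting
    "dissection_fraction": 1.0 / 3.0,
    "grid_n": 6,
    # total-variation threshold under which the forward distributions of two
    # adjacent sbins are considered indistinguishable and the sbins merged
    "merge_tau": 0.32,
    "bezier_points_per_segment": 64,
}


class GeometryError(ValueError):
    """Raised for invalid limb-shape configurations."""


def _cubic_bezier(p0, c1, c2, p3, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, c1, c2, p3 = (np.asarray(p, float) for p in (p0, c1, c2, p3))
    return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * c1
            + 3 * (1 - t) * t ** 2 * c2 + t ** 3 * p3)


@dataclass
class LimbShape:
    """Closed limb-bud outline with its marked AER arc and flank edge."""

    polygon: Polygon
    aer_arc: LineString
    flank_edge: LineString
    config: dict

    @property
    def bounds(self):
        return self.polygon.bounds

    @property
    def pd_length(self) -> float:
        x0, _, x1, _ = self.bounds
        return x1 - x0

    @property
    def ap_length(self) -> float:
        _, y0, _, y1 = self.bounds
        return y1 - y0

    @property
    def area(self) -> float:
        return self.polygon.area

    def pd_coord(self, x):
        """Normalized PD coordinate in [0, 1], flank -> tip."""
        x0, _, x1, _ = self.bounds
        return (np.asarray(x) - x0) / (x1 - x0)

    def ap_coord(self, y):
        """Normalized AP coordinate in [0, 1], anterior -> posterior."""
        _, y0, _, y1 = self.bounds
        return (np.asarray(y) - y0) / (y1 - y0)


@dataclass
class PhotoconversionPattern:
    """One photoconversion layout: color regions plus the captured region."""

    name: str
    regions: dict  # color -> shapely geometry
    covered_region: Polygon


def build_default_limb(config: dict | None = None) -> LimbShape:
    """Construct the limb-bud shape from a Bezier-segment configuration.

    Parameters
    ----------
    config
        Geometry configuration (see :data:`DEFAULT_GEOMETRY`); ``None``
        uses the packaged default paddle shape.
    """
    cfg = copy.deepcopy(DEFAULT_GEOMETRY)
    if config:
        cfg.update(copy.deepcopy(config))
    npts = int(cfg.get("bezier_points_per_segment", 64))
    seg_points = []
    for seg in cfg["segments"]:
        if seg.get("kind", "cubic") == "line":
            pts = np.linspace(seg["p0"], seg["p3"], npts)
        else:
            pts = _cubic_bezier(seg["p0"], seg["c1"], seg["c2"], seg["p3"],
                                npts)
        seg_points.append(pts)
    if not np.allclose(seg_points[-1][-1], seg_points[0][0], atol=1e-9):
        raise GeometryError("boundary segments do not close")
    ring = np.vstack([p[:-1] for p in seg_points])
    poly = Polygon(ring)
    if (not poly.is_valid) or poly.area <= 0:
        raise GeometryError("boundary is self-intersecting or degenerate")

    def _subpath(idx):
        pts = np.vstack([seg_points[i] for i in idx])
        return LineString(pts)

    shape = LimbShape(
        polygon=poly,
        aer_arc=_subpath(cfg["aer_segments"]),
        flank_edge=_subpath(cfg["flank_segments"]),
        config=cfg,
    )
    return shape


def _slab(shape: LimbShape, axis: str, lo_frac: float, hi_frac: float):
    x0, y0, x1, y1 = shape.bounds
    pad = 1e-6 * max(x1 - x0, y1 - y0)
    if axis == "x":
        lo = x0 + lo_frac * (x1 - x0)
        hi = x0 + hi_frac * (x1 - x0)
        b = box(lo, y0 - pad, hi, y1 + pad)
    else:
        lo = y0 + lo_frac * (y1 - y0)
        hi = y0 + hi_frac * (y1 - y0)
        b = box(x0 - pad, lo, x1 + pad, hi)
    return b.intersection(shape.polygon)


def build_patterns(shape: LimbShape) -> dict:
    """Build the three photoconversion patterns on a limb shape.

    Returns a mapping ``{"PD": ..., "AP": ..., "AER": ...}`` of
    :class:`PhotoconversionPattern`.  PD and AP bands are equal-length
    thirds along their axis and cover the whole shape.  AER bands are
    equal-width distance bands from the AER arc over the dissected distal
    part only; the two red-most degrees are merged into one red band.
    """
    cfg = shape.config
    thirds = [(0.0, 1.0 / 3.0), (1.0 / 3.0, 2.0 / 3.0), (2.0 / 3.0, 1.0)]
    pd = PhotoconversionPattern(
        name="PD",
        regions={c: _slab(shape, "x", lo, hi)
                 for c, (lo, hi) in zip(COLORS, thirds)},
        covered_region=shape.polygon,
    )
    ap = PhotoconversionPattern(
        name="AP",
        regions={c: _slab(shape, "y", lo, hi)
                 for c, (lo, hi) in zip(COLORS, thirds)},
        covered_region=shape.polygon,
    )
    w = float(cfg["aer_band_width"])
    dfrac = float(cfg["dissection_fraction"])
    covered = _slab(shape, "x", dfrac, 1.0)
    b2 = shape.aer_arc.buffer(2.0 * w, quad_segs=32)
    b3 = shape.aer_arc.buffer(3.0 * w, quad_segs=32)
    aer = PhotoconversionPattern(
        name="AER",
        regions={
            "red": covered.intersection(b2),
            "yellow": covered.intersection(b3.difference(b2)),
            "green": covered.difference(b3),
        },
        covered_region=covered,
    )
    return {"PD": pd, "AP": ap, "AER": aer}


def forward_distribution(poly, pattern: PhotoconversionPattern) -> np.ndarray:
    """Fluorescence distribution of a cell uniformly distributed in ``poly``.

    Returns a length-4 probability vector over (green, yellow, red, missed),
    each entry proportional to the area of ``poly`` photoconverted to that
    color under ``pattern``; mass outside the pattern's covered region goes
    to ``missed``.
    """
    area = poly.area
    if area <= 0:
        raise GeometryError("zero-area sbin")
    fracs = np.array([poly.intersection(pattern.regions[c]).area
                      for c in COLORS])
    missed = max(area - fracs.sum(), 0.0)
    row = np.append(fracs, missed) / area
    return row / row.sum()


@dataclass
class Sbin:
    id: int
    polygon: Polygon
    members: list  # (row, col) grid indices composing this sbin
    area: float = field(init=False)
    centroid: tuple = field(init=False)

    def __post_init__(self):
        self.area = self.polygon.area
        c = self.polygon.centroid
        self.centroid = (c.x, c.y)


def _tv(a, b):
    return 0.5 * float(np.abs(np.asarray(a) - np.asarray(b)).sum())


def _adjacent(p, q) -> bool:
    inter = p.boundary.intersection(q.boundary)
    return inter.length > 1e-9


@dataclass
class SbinGrid:
    """Partition of the limb shape into sbins with forward matrices.

    ``forward[pattern]`` is an ``(n_sbins, 4)`` row-stochastic matrix over
    (green, yellow, red, missed).
    """

    sbins: list
    forward: dict  # pattern name -> (n_sbins, 4) array
    n_raw: int     # grid cells before clipping (n x n)
    n_unmerged: int  # nonempty clipped cells before merging
    config: dict

    @property
    def n_sbins(self) -> int:
        return len(self.sbins)

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.sbins])

    def centroids(self) -> np.ndarray:
        return np.array([s.centroid for s in self.sbins])

    def forward_matrix(self, pattern: str) -> np.ndarray:
        return self.forward[pattern]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for p in PATTERNS:
            h.update(np.round(self.forward[p], 12).tobytes())
        h.update(np.round(self.areas, 12).tobytes())
        return h.hexdigest()[:16]


def build_sbin_grid(shape: LimbShape, patterns: dict, n: int | None = None,
                    tau: float | None = None) -> SbinGrid:
    """Grid the shape into sbins and merge indistinguishable neighbors.

    An ``n`` x ``n`` equidistant grid is laid over the AP-PD bounding box,
    clipped to the shape, and empty cells are dropped.  Adjacent sbins whose
    forward distributions differ by total-variation distance below ``tau``
    under *all three* patterns are merged agglomeratively, closest pair
    first, and merged forward rows are recomputed from the merged geometry.
    """
    cfg = shape.config
    if n is None:
        n = int(cfg["grid_n"])
    if tau is None:
        tau = float(cfg["merge_tau"])
    if n < 2:
        raise GeometryError("grid must be at least 2 x 2")
    if not (0.0 <= tau < 1.0):
        raise GeometryError("merge threshold must be in [0, 1)")
    x0, y0, x1, y1 = shape.bounds
    xs = np.linspace(x0, x1, n + 1)
    ys = np.linspace(y0, y1, n + 1)
    min_area = 1e-9 * shape.area
    sbins = []
    for j in range(n):        # rows: AP (anterior -> posterior)
        for i in range(n):    # cols: PD (flank -> tip)
            cell = box(xs[i], ys[j], xs[i + 1], ys[j + 1])
            clipped = cell.intersection(shape.polygon)
            if clipped.area > min_area:
                sbins.append(Sbin(len(sbins), clipped, [(j, i)]))
    n_unmerged = len(sbins)

    def rows_of(poly):
        return {p: forward_distribution(poly, patterns[p]) for p in PATTERNS}

    rows = [rows_of(s.polygon) for s in sbins]

    while True:
        best = None
        for a in range(len(sbins)):
            for b in range(a + 1, len(sbins)):
                if not _adjacent(sbins[a].polygon, sbins[b].polygon):
                    continue
                d = max(_tv(rows[a][p], rows[b][p]) for p in PATTERNS)
                if d < tau and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        merged_poly = unary_union([sbins[a].polygon, sbins[b].polygon])
        merged = Sbin(sbins[a].id, merged_poly,
                      sbins[a].members + sbins[b].members)
        sbins[a] = merged
        rows[a] = rows_of(merged_poly)
        del sbins[b], rows[b]

    if len(sbins) <= 1:
        raise GeometryError("merge threshold collapsed all sbins into one")
    for k, s in enumerate(sbins):
        s.id = k
    forward = {p: np.vstack([rows[k][p] for k in range(len(sbins))])
               for p in PATTERNS}
    return SbinGrid(sbins=sbins, forward=forward, n_raw=n * n,
                    n_unmerged=n_unmerged, config=cfg)


def deterministic_regions(shape: LimbShape, patterns: dict,
                          min_area_frac: float = 1e-6):
    """Enumerate regions with a deterministic color under every pattern.

    Intersects every (PD color) x (AP color) x (AER outcome) combination,
    where the AER outcome is one of the three effective colors or
    ``missed`` (the proximal part discarded before AER-pattern sorting),
    and returns the nonempty combinations with their geometry.
    """
    aer_outcomes = dict(patterns["AER"].regions)
    aer_outcomes["missed"] = shape.polygon.difference(
        patterns["AER"].covered_region)
    tol = min_area_frac * shape.area
    regions = []
    for pd_c in COLORS:
        for ap_c in COLORS:
            base = patterns["PD"].regions[pd_c].intersection(
                patterns["AP"].regions[ap_c])
            if base.area <= tol:
                continue
            for aer_c, aer_g in aer_outcomes.items():
                r = base.intersection(aer_g)
                if r.area > tol:
                    regions.append({"pd": pd_c, "ap": ap_c, "aer": aer_c,
                                    "geometry": r, "area": r.area})
    return regions


@dataclass
class LimbModel:
    """Bundled limb-bud model: shape, patterns, and sbin grid."""

    shape: LimbShape
    patterns: dict
    grid: SbinGrid

    @classmethod
    def build(cls, config: dict | None = None, n: int | None = None,
              tau: float | None = None) -> "LimbModel":
        shape = build_default_limb(config)
        patterns = build_patterns(shape)
        grid = build_sbin_grid(shape, patterns, n=n, tau=tau)
        return cls(shape=shape, patterns=patterns, grid=grid)

    @property
    def n_sbins(self) -> int:
        return self.grid.n_sbins

    def checksum(self) -> str:
        return self.grid.checksum()

    def sbin_of_points(self, x, y) -> np.ndarray:
        """Index of the sbin containing each point (-1 if outside)."""
        import shapely

        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.full(x.shape, -1, dtype=int)
        pts = shapely.points(x, y)
        for k, s in enumerate(self.grid.sbins):
            hit = shapely.covers(s.polygon, pts)
            out[hit & (out < 0)] = k
        miss = out < 0
        if miss.any():
            # points on shared sbin edges / numerical boundary: snap to the
            # nearest sbin
            for idx in np.flatnonzero(miss):
                d = [s.polygon.distance(pts[idx]) for s in self.grid.sbins]
                out[idx] = int(np.argmin(d))
        return out

    def sbin_coords(self) -> dict:
        """Per-sbin spatial coordinates used for positional trends.

        Returns normalized PD / AP centroid coordinates and the Euclidean
        distance of each sbin centroid to the AER arc.
        """
        cent = self.grid.centroids()
        dist = np.array([self.shape.aer_arc.distance(s.polygon.centroid)
                         for s in self.grid.sbins])
        return {
            "pd": np.asarray(self.shape.pd_coord(cent[:, 0])),
            "ap": np.asarray(self.shape.ap_coord(cent[:, 1])),
            "aer_distance": dist,
        }

    def config_json(self) -> str:
        return json.dumps(self.shape.config, sort_keys=True)
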