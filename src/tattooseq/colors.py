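"""Photoconversion color calling from FACS fluorescence intensities.

Each sorted cell carries a red (PE, photoconverted) and a green (FITC,
non-photoconverted) intensity.  The positional readout is the ratio of logs

    s = log2(PE) / log2(FITC)

whose per-limb distribution is multimodal: one mode per photoconversion
degree.  The distribution of each limb is modeled separately as a mixture
of skew-normal components fitted by expectation-maximization, and each cell
is assigned the color of the component with the highest posterior
responsibility.  PD- and AP-patterned limbs use three components
(green / yellow / red); AER-patterned limbs use four degrees whose two
red-most (highest-s) components are merged into a single red bin, because
fully photoconverted cells are rare under that pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, skewnorm

COLOR_LABELS = ("green", "yellow", "red")


class LowFluorescenceError(ValueError):
    """Cell intensity too low for the ratio-of-logs statistic."""


class DegenerateDataError(ValueError):
    """All ratio values identical; mixture fit impossible."""


def compute_log_ratio(pe, fitc):
    """Ratio-of-logs color statistic ``s = log2(pe) / log2(fitc)``.

    Both intensities must exceed 1 (cells low in both channels are gated
    out upstream; an intensity at or below 1 makes the statistic undefined
    or unstable).
    """
    pe = np.asarray(pe, float)
    fitc = np.asarray(fitc, float)
    if np.any(pe <= 1.0) or np.any(fitc <= 1.0):
        raise LowFluorescenceError(
            "PE and FITC intensities must both exceed 1")
    return np.log2(pe) / np.log2(fitc)


@dataclass
class SkewNormalComponent:
    """One skew-normal mixture component: location xi, scale omega,
    shape alpha, mixture weight."""

    xi: float
    omega: float
    alpha: float
    weight: float

    @property
    def delta(self) -> float:
        return self.alpha / np.sqrt(1.0 + self.alpha ** 2)

    @property
    def mean(self) -> float:
        return self.xi + self.omega * self.delta * np.sqrt(2.0 / np.pi)

    def pdf(self, x):
        return skewnorm.pdf(x, self.alpha, loc=self.xi, scale=self.omega)


@dataclass
class ColorMixtureFit:
    """Fitted per-limb skew-normal mixture, components in ascending mean."""

    components: list
    log_likelihood: float
    n_iter: int
    converged: bool
    limb_id: str | None = None
    pattern: str | None = None
    ll_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    def responsibilities(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        dens = np.column_stack([c.weight * c.pdf(x) for c in self.components])
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return dens / tot


def _em_skew_normal(x, k, init_labels=None, tol=1e-6, max_iter=500):
    """ECM for a k-component skew-normal mixture.

    Uses the stochastic representation x = xi + omega*delta*|t| + e with
    t ~ N(0,1) truncated to t > 0 and e ~ N(0, omega^2 (1 - delta^2)); the
    E-step needs only the first two truncated-normal moments of t.
    Components start from the per-group moments of an initial hard
    partition (``init_labels``; default a k-quantile split of the sorted
    data), with alpha = 0.
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    if init_labels is None:
        init_labels = np.repeat(np.arange(k), [len(a) for a in
                                               np.array_split(x, k)])
    groups = [x[init_labels == j] for j in range(k)]
    floor = 1e-3 * (np.std(x) + 1e-12)
    xi = np.array([np.mean(g) if g.size else np.mean(x) for g in groups])
    omega = np.array([max(np.std(g), floor) if g.size else np.std(x)
                      for g in groups])
    delta = np.zeros(k)
    w = np.maximum(np.array([g.size for g in groups], float), 1.0)
    w = w / w.sum()

    def params():
        Delta = omega * delta
        Gamma = omega ** 2 * (1.0 - delta ** 2)
        return Delta, Gamma

    def loglik():
        alpha = delta / np.sqrt(np.maximum(1.0 - delta ** 2, 1e-12))
        dens = np.column_stack([
            w[j] * skewnorm.pdf(x, alpha[j], loc=xi[j], scale=omega[j])
            for j in range(k)])
        return float(np.log(np.maximum(dens.sum(axis=1), 1e-300)).sum()), dens

    ll_old, dens = loglik()
    trace = [ll_old]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = dens / np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
        Delta, Gamma = params()
        # truncated-normal moments of the latent t given x, per component
        var_t = Gamma / np.maximum(Gamma + Delta ** 2, 1e-300)
        m_t = (Delta * (x[:, None] - xi)) / np.maximum(Gamma + Delta ** 2,
                                                       1e-300)
        s_t = np.sqrt(np.maximum(var_t, 1e-300))
        z = m_t / s_t
        ratio = norm.pdf(z) / np.maximum(norm.cdf(z), 1e-300)
        e1 = m_t + s_t * ratio
        e2 = m_t ** 2 + s_t ** 2 + m_t * s_t * ratio

        nj = r.sum(axis=0)
        nj = np.maximum(nj, 1e-12)
        w = nj / n
        xi = ((r * (x[:, None] - Delta * e1)).sum(axis=0)) / nj
        resid = x[:, None] - xi
        Delta = (r * e1 * resid).sum(axis=0) / np.maximum(
            (r * e2).sum(axis=0), 1e-300)
        Gamma = (r * (resid ** 2 - 2.0 * Delta * e1 * resid
                      + Delta ** 2 * e2)).sum(axis=0) / nj
        Gamma = np.maximum(Gamma, 1e-10)
        omega = np.sqrt(Gamma + Delta ** 2)
        delta = np.clip(Delta / omega, -0.995, 0.995)

        ll, dens = loglik()
        trace.append(ll)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            ll_old = ll
            converged = True
            break
        ll_old = ll
    alpha = delta / np.sqrt(np.maximum(1.0 - delta ** 2, 1e-12))
    comps = [SkewNormalComponent(xi=float(xi[j]), omega=float(omega[j]),
                                 alpha=float(alpha[j]), weight=float(w[j]))
             for j in range(k)]
    return comps, ll_old, it, converged, trace


def _kde_mode_labels(x, k):
    """Hard partition of sorted x by nearest of the k strongest KDE modes.

    Returns None when fewer than k local maxima exist (e.g. heavily
    overlapping components); callers then fall back to other inits.
    """
    from scipy.stats import gaussian_kde

    grid = np.linspace(x.min(), x.max(), 512)
    d = gaussian_kde(x)(grid)
    peaks = [i for i in range(1, len(grid) - 1)
             if d[i] > d[i - 1] and d[i] >= d[i + 1]]
    if len(peaks) < k:
        return None
    centers = np.sort(grid[sorted(peaks, key=lambda i: -d[i])[:k]])
    return np.argmin(np.abs(x[:, None] - centers), axis=1)


def fit_skew_normal_mixture(values, k, seed=0, tol=1e-6, max_iter=500,
                            n_random_init=2, limb_id=None,
                            pattern=None) -> ColorMixtureFit:
    """Fit a k-component skew-normal mixture to ratio-of-logs values.

    ``k`` is 3 for PD/AP-patterned limbs and 4 for AER-patterned limbs.
    EM is run from several initial partitions — a k-quantile split, the k
    strongest density modes, and ``n_random_init`` seeded random center
    draws — and the solution with the best log-likelihood is kept; unequal
    mixing proportions otherwise trap the quantile init in local optima
    that split the dominant mode.  Components of the returned fit are
    sorted by ascending component mean, which makes the labeling invariant
    to initialization order.
    """
    x = np.sort(np.asarray(values, float))
    if not np.all(np.isfinite(x)):
        raise ValueError("ratio values must be finite")
    if k not in (2, 3, 4):
        raise ValueError("component count must be 2, 3 or 4")
    if x.size < 50 * k:
        raise ValueError(f"need at least {50 * k} cells to fit {k} "
                         "components")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all ratio values identical")
    inits = [None]
    kde_labels = _kde_mode_labels(x, k)
    if kde_labels is not None:
        inits.append(kde_labels)
    rng = np.random.default_rng(seed)
    for _ in range(n_random_init):
        centers = np.sort(rng.choice(x, size=k, replace=False))
        inits.append(np.argmin(np.abs(x[:, None] - centers), axis=1))
    best = None
    for labels in inits:
        fit = _em_skew_normal(x, k, init_labels=labels, tol=tol,
                              max_iter=max_iter)
        if best is None or fit[1] > best[1]:
            best = fit
    comps, ll, it, converged, trace = best
    comps.sort(key=lambda c: c.mean)
    return ColorMixtureFit(components=comps, log_likelihood=ll, n_iter=it,
                           converged=converged, limb_id=limb_id,
                           pattern=pattern, ll_trace=trace)


def assign_colors(fit: ColorMixtureFit, values, merge_top_two: bool = False,
                  outlier_sd: float = 6.0) -> pd.DataFrame:
    """Posterior color calls from a fitted mixture.

    Component responsibilities are the per-cell posteriors.  With
    ``merge_top_two`` (AER-patterned limbs) the two highest-mean components
    are summed into a single red bin.  Effective colors are labeled
    green / yellow / red in ascending component mean.  Values farther than
    ``outlier_sd`` fitted scales from every component mean are flagged
    unassignable.

    Returns a data frame with columns ``color``, ``posterior_green``,
    ``posterior_yellow``, ``posterior_red``, ``unassignable``.
    """
    x = np.asarray(values, float)
    resp = fit.responsibilities(x)
    if merge_top_two:
        if fit.k < 3:
            raise ValueError("merging requires at least 3 components")
        resp = np.column_stack([resp[:, :-2], resp[:, -2:].sum(axis=1)])
    if resp.shape[1] != 3:
        raise ValueError(
            "expected 3 effective colors; use merge_top_two for 4-component "
            "(AER) fits")
    means = np.array([c.mean for c in fit.components])
    omegas = np.array([c.omega for c in fit.components])
    outlier = np.all(
        np.abs(x[:, None] - means) > outlier_sd * omegas, axis=1)
    labels = np.array(COLOR_LABELS)[np.argmax(resp, axis=1)]
    return pd.DataFrame({
        "color": labels,
        "posterior_green": resp[:, 0],
        "posterior_yellow": resp[:, 1],
        "posterior_red": resp[:, 2],
        "unassignable": outlier,
    })


def call_colors(facs: pd.DataFrame, seed: int = 0,
                k_by_pattern: dict | None = None) -> pd.DataFrame:
    """End-to-end color calling for a FACS index table.

    ``facs`` needs columns ``cell_id``, ``limb_id``, ``pattern`` (PD, AP or
    AER), ``pe`` and ``fitc``.  Each limb is fitted separately; AER limbs
    use four components with the two red-most merged.  Returns one row per
    cell with the color call, posteriors and fit convergence flag.
    """
    required = {"cell_id", "limb_id", "pattern", "pe", "fitc"}
    missing = required - set(facs.columns)
    if missing:
        raise ValueError(f"FACS table missing columns: {sorted(missing)}")
    if facs["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    k_by_pattern = k_by_pattern or {"PD": 3, "AP": 3, "AER": 4}
    out = []
    for (limb, pattern), sub in facs.groupby(["limb_id", "pattern"],
                                             sort=True):
        s = compute_log_ratio(sub["pe"].to_numpy(), sub["fitc"].to_numpy())
        k = k_by_pattern[pattern]
        fit = fit_skew_normal_mixture(s, k, seed=seed, limb_id=limb,
                                      pattern=pattern)
        calls = assign_colors(fit, s, merge_top_two=(pattern == "AER"))
        calls.insert(0, "cell_id", sub["cell_id"].to_numpy())
        calls["limb_id"] = limb
        calls["pattern"] = pattern
        calls["s"] = s
        calls["converged"] = fit.converged
        out.append(calls)
    return pd.concat(out, ignore_index=True)
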