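"""Inference of spatial distributions over sbins from color compositions.

A single cell's fluorescence only narrows its position to one of three or
four broad regions.  Groups of transcriptionally similar cells (metacells),
however, pool cells collected from limbs photoconverted with different
patterns; assuming the group occupies a reproducible spatial domain across
limbs, its per-pattern color composition constrains a full distribution
theta over the model's sbins.

For a group M and pattern lambda, the forward model predicts

    P_theta,lambda(F | M) = sum_s P_lambda(F | S = s) * theta_s

and theta is estimated by minimizing the summed Kullback-Leibler divergence
between predicted and regularized empirical color distributions over the
available patterns, subject to sum(theta) = 1 and
-0.00005 <= theta_s <= 1 (a box slightly wider than [0, 1] that helps the
interior-point optimizer).  Probabilities entering the log ratios are
clamped to [0.001, 1].  After convergence, negative entries are zeroed and
theta is renormalized.

Under the AER pattern, cells in the proximal third are never collected, so
the empirical distribution is conditional on capture; the predicted
distribution is renormalized over the observed colors, and the predicted
missed probability is reported separately as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, minimize

from .geometry import COLORS, PATTERNS

CLAMP_LO, CLAMP_HI = 1e-3, 1.0
THETA_LO = -5e-5


class UnobservablePatternError(ValueError):
    """Predicted capture probability is zero under a pattern."""


@dataclass
class EmpiricalFluorescence:
    """Per-pattern regularized color composition of one cell group."""

    group_id: str
    counts: dict = field(default_factory=dict)  # pattern -> len-3 int array
    epsilon: float = 1.0

    @property
    def patterns(self):
        return [p for p in PATTERNS if p in self.counts]

    def n_cells(self, pattern: str) -> int:
        return int(np.sum(self.counts[pattern])) if pattern in self.counts \
            else 0

    def distribution(self, pattern: str) -> np.ndarray:
        c = np.asarray(self.counts[pattern], float)
        return (c + self.epsilon) / (c.sum() + len(c) * self.epsilon)


def empirical_distribution(color_calls: pd.DataFrame, group_id: str,
                           cells: pd.Index | np.ndarray | list,
                           epsilon: float = 1.0) -> EmpiricalFluorescence:
    """Regularized empirical color distributions for one cell group.

    Counts colors per pattern among ``cells`` (cell_ids) in the color-call
    table and applies a pseudocount ``epsilon`` per color.  Patterns with
    zero cells are omitted (they contribute no divergence term downstream).
    """
    sub = color_calls[color_calls["cell_id"].isin(set(cells))]
    emp = EmpiricalFluorescence(group_id=group_id, epsilon=epsilon)
    for pattern, g in sub.groupby("pattern"):
        counts = np.array([(g["color"] == c).sum() for c in COLORS],
                          dtype=int)
        if counts.sum() > 0:
            emp.counts[pattern] = counts
    return emp


def predict_fluorescence(theta, forward_matrix, condition_on_capture=False):
    """Predicted color distribution ``P(F | M)`` for a sbin distribution.

    ``forward_matrix`` is the (n_sbins, 4) row-stochastic matrix over
    (green, yellow, red, missed).  Returns a length-3 vector over the
    observable colors; with ``condition_on_capture`` the missed mass is
    removed and the remainder renormalized (AER pattern).
    """
    theta = np.asarray(theta, float)
    p = forward_matrix[:, :3].T @ theta
    if condition_on_capture:
        captured = p.sum()
        if captured <= 1e-12:
            raise UnobservablePatternError(
                "all probability mass falls in the missed region")
        p = p / captured
    return p


def missed_probability(theta, forward_matrix) -> float:
    """Probability that a cell of this group is missed under the pattern."""
    return float(forward_matrix[:, 3] @ np.asarray(theta, float))


def _clamp(p):
    return np.clip(p, CLAMP_LO, CLAMP_HI)


def kl_objective(theta, empiricals: EmpiricalFluorescence,
                 forward: dict) -> float:
    """Summed KL divergence between predicted and empirical distributions.

    Both the predicted and the empirical probabilities are clamped to
    [0.001, 1] before entering the logs, so the objective carries a small
    clamping-induced floor but is bounded and smooth near the simplex
    boundary.
    """
    total = 0.0
    for pattern in empiricals.patterns:
        p = predict_fluorescence(theta, forward[pattern],
                                 condition_on_capture=(pattern == "AER"))
        q = empiricals.distribution(pattern)
        pc, qc = _clamp(p), _clamp(q)
        total += float(np.sum(pc * (np.log(pc) - np.log(qc))))
    return total


def _kl_gradient(theta, empiricals, forward):
    grad = np.zeros(len(theta))
    for pattern in empiricals.patterns:
        A = forward[pattern][:, :3]  # n_sbins x 3
        q = empiricals.distribution(pattern)
        raw = A.T @ theta
        if pattern == "AER":
            kappa = raw.sum()
            p = raw / kappa
            # dp_F/dtheta = A[:,F]/kappa - raw_F * (A @ 1)/kappa^2
            dkap = A.sum(axis=1)
        else:
            p = raw
        pc = _clamp(p)
        inner = np.where((p > CLAMP_LO) & (p < CLAMP_HI),
                         1.0 + np.log(pc) - np.log(_clamp(q)), 0.0)
        if pattern == "AER":
            grad += A @ (inner / kappa) - (inner @ raw) / kappa ** 2 * dkap
        else:
            grad += A @ inner
    return grad


@dataclass
class SbinPosterior:
    """Inferred sbin distribution for one cell group."""

    group_id: str
    theta: np.ndarray
    objective: float
    converged: bool
    n_cells_per_pattern: dict
    missed_probability: float | None = None
    low_confidence: bool = False
    message: str = ""


def infer_sbin_distribution(empiricals: EmpiricalFluorescence,
                            forward: dict, theta0=None, seed: int = 0,
                            n_restarts: int = 3, min_cells: int = 10,
                            prior=None,
                            prior_weight: float = 0.0) -> SbinPosterior:
    """Constrained KL minimization of the sbin distribution of a group.

    Runs a trust-region constrained interior-point minimization with the
    analytic gradient, the equality constraint sum(theta) = 1 and bounds
    -0.00005 <= theta_s <= 1.  If the optimizer fails, up to ``n_restarts``
    Dirichlet-perturbed restarts are tried; a non-converged result is
    returned (with diagnostics) rather than raising.  Negative entries of
    the solution are zeroed and theta renormalized.

    Three color distributions cannot pin down more than a few linear
    functionals of theta, so the minimizer generally lies on a degenerate
    optimal set.  ``prior`` with a small ``prior_weight`` adds
    ``prior_weight * KL(theta || prior)`` as a tie-break selecting, among
    near-minimizers, the one closest to the reference distribution (e.g.
    uniform cell density: prior proportional to sbin areas).  The reported
    objective excludes the tie-break term.
    """
    if not empiricals.patterns:
        raise ValueError("group has no cells under any pattern")
    n_sbins = next(iter(forward.values())).shape[0]
    if theta0 is None:
        theta0 = np.full(n_sbins, 1.0 / n_sbins)
    rng = np.random.default_rng(seed)
    constraint = LinearConstraint(np.ones((1, n_sbins)), 1.0, 1.0)
    bounds = [(THETA_LO, 1.0)] * n_sbins

    if prior is not None and prior_weight > 0:
        prior = np.asarray(prior, float)
        prior = prior / prior.sum()

        def objective(th, emp, fwd):
            t = np.clip(th, 1e-9, 1.0)
            return kl_objective(th, emp, fwd) + prior_weight * float(
                np.sum(t * (np.log(t) - np.log(prior))))

        def gradient(th, emp, fwd):
            t = np.clip(th, 1e-9, 1.0)
            return _kl_gradient(th, emp, fwd) + prior_weight * (
                np.log(t) - np.log(prior) + 1.0)
    else:
        objective, gradient = kl_objective, _kl_gradient

    def solve(x0):
        return minimize(
            objective, x0, args=(empiricals, forward),
            jac=gradient, method="trust-constr",
            constraints=[constraint], bounds=bounds,
            options={"gtol": 1e-8, "xtol": 1e-10, "maxiter": 2000})

    res = solve(theta0)
    tries = 0
    best = res
    while not res.success and tries < n_restarts:
        tries += 1
        x0 = rng.dirichlet(np.ones(n_sbins))
        res = solve(x0)
        if res.fun < best.fun:
            best = res
    res = best
    theta = np.asarray(res.x, float)
    theta[theta < 0] = 0.0
    theta = theta / theta.sum()
    n_cells = {p: empiricals.n_cells(p) for p in empiricals.patterns}
    missed = missed_probability(theta, forward["AER"]) \
        if "AER" in forward else None
    return SbinPosterior(
        group_id=empiricals.group_id, theta=theta,
        objective=float(kl_objective(theta, empiricals, forward)),
        converged=bool(res.success),
        n_cells_per_pattern=n_cells, missed_probability=missed,
        low_confidence=sum(n_cells.values()) < min_cells,
        message=str(getattr(res, "message", "")))


def infer_groups(color_calls: pd.DataFrame, groups: pd.DataFrame,
                 forward: dict, epsilon: float = 1.0,
                 seed: int = 0) -> list:
    """Infer sbin distributions for every group in an assignment table.

    ``groups`` maps ``cell_id`` to ``group_id``.  Returns a list of
    :class:`SbinPosterior`, one per group (sorted by group id).
    """
    out = []
    for gid, sub in groups.groupby("group_id", sort=True):
        emp = empirical_distribution(color_calls, str(gid),
                                     sub["cell_id"], epsilon=epsilon)
        if not emp.patterns:
            continue
        out.append(infer_sbin_distribution(emp, forward, seed=seed))
    return out


def posteriors_to_frame(posteriors: list, n_sbins: int) -> pd.DataFrame:
    """Tabulate posteriors: one row per group, one column per sbin."""
    rows = {}
    meta = {}
    for p in posteriors:
        rows[p.group_id] = p.theta
        meta[p.group_id] = (p.objective, p.converged,
                            p.n_cells_per_pattern.get("PD", 0),
                            p.n_cells_per_pattern.get("AP", 0),
                            p.n_cells_per_pattern.get("AER", 0))
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"sbin_{i}" for i in range(n_sbins)])
    df.index.name = "group_id"
    m = pd.DataFrame.from_dict(
        meta, orient="index",
        columns=["objective", "converged", "n_PD", "n_AP", "n_AER"])
    out = pd.concat([df, m], axis=1)
    out.index.name = "group_id"
    return out


def infer_thickness(color_calls: pd.DataFrame, forward: dict,
                    sbin_areas, epsilon: float = 1.0, seed: int = 0,
                    prior_weight: float = 1e-3):
    """Relative limb thickness per sbin from the full cell collection.

    Treats all collected cells as one group, infers its sbin distribution
    with a uniform-density (area-proportional) tie-break — the natural
    reference when every cell of the tissue is pooled — and converts the
    result to a thickness profile.  Returns ``(thickness, posterior)``.
    """
    emp = empirical_distribution(color_calls, "all",
                                 color_calls["cell_id"], epsilon=epsilon)
    areas = np.asarray(sbin_areas, float)
    prior = areas / areas.sum()
    post = infer_sbin_distribution(emp, forward, theta0=prior.copy(),
                                   seed=seed, prior=prior,
                                   prior_weight=prior_weight)
    return estimate_thickness(post.theta, areas), post


def estimate_thickness(theta_all_cells, sbin_areas) -> np.ndarray:
    """Relative tissue thickness per sbin from the all-cells distribution.

    With cells sampled uniformly per unit volume, the fraction of all
    cells in a sbin divided by its area is proportional to the local
    tissue thickness; the profile is normalized to a maximum of 1.
    """
    theta = np.asarray(theta_all_cells, float)
    areas = np.asarray(sbin_areas, float)
    if np.any(areas <= 0):
        raise ValueError("sbin areas must be positive")
    t = theta / areas
    return t / t.max()
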