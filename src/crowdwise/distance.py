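"""The distance effect: V-shaped dependence of mean sensitivity on D.

Mean sensitivity grows roughly linearly with the distance between the
social information and the personal estimate, with a vertex that need
not sit at D = 0 and possibly different slopes on either side:

    <S>(D) = alpha + beta_(+/-) |D - D0|.

With a few hundred records per condition, fixed bins of width 1 are too
coarse to locate the vertex and narrower bins too noisy.  The moving-bin
device reuses the same data in overlapping bins of width 1 whose centres
advance in steps of 0.1 from -2 to +2, yielding 41 replicated points.
The cusp is then fitted by weighted least squares: for every candidate
vertex on a grid, (alpha, beta_minus, beta_plus) solve the 3x3 weighted
normal equations in closed form, and the grid minimiser of the weighted
sum of squared residuals Q wins.  (The absolute value makes the model
non-smooth in D0, which is why generic smooth optimisers struggle and a
grid is used instead.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import saturating

D0_GRID_LOW = -1.5
D0_GRID_HIGH = 1.5
D0_GRID_STEP = 0.01


@dataclass(frozen=True)
class BinnedPoints:
    """Moving-bin means of S against D.

    ``weights`` hold the fraction of records per bin, normalised over
    non-empty bins (the normalisation cancels in the arg-min of Q).
    """

    centers: np.ndarray
    mean_s: np.ndarray
    weights: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.centers.size)

    def nonempty(self) -> "BinnedPoints":
        m = self.weights > 0
        return BinnedPoints(self.centers[m], self.mean_s[m], self.weights[m])


@dataclass(frozen=True)
class CuspFit:
    """Weighted-least-squares cusp fit <S>(D) = alpha + beta_(+/-)|D - D0|."""

    alpha: float
    beta_minus: float
    beta_plus: float
    d0: float
    q_value: float

    def predict(self, D):
        D = np.asarray(D, dtype=float)
        beta = np.where(D < self.d0, self.beta_minus, self.beta_plus)
        return self.alpha + beta * np.abs(D - self.d0)


def bin_moving_centers(
    records: pd.DataFrame,
    bin_size: float = 1.0,
    start: float = -2.0,
    end: float = 2.0,
    step: float = 0.1,
) -> BinnedPoints:
    """Mean restricted S per moving bin of width ``bin_size``.

    Centres run from ``start`` to ``end`` in steps of ``step`` (41 points
    with the defaults).  A record enters every bin whose centre is within
    ``bin_size / 2`` of its D, deliberately replicating the data across
    overlapping bins.  Empty bins get weight 0 and are skipped by the
    fitter.
    """
    if len(records) == 0:
        raise ValueError("no records to bin")
    d = records["distance"].to_numpy(dtype=float)
    s = records["sensitivity"].to_numpy(dtype=float)
    n_centers = int(round((end - start) / step)) + 1
    centers = start + step * np.arange(n_centers)
    half = bin_size / 2
    mean_s = np.full(n_centers, np.nan)
    counts = np.zeros(n_centers)
    for i, c in enumerate(centers):
        m = np.abs(d - c) <= half
        counts[i] = m.sum()
        if counts[i]:
            mean_s[i] = s[m].mean()
    total = counts.sum()
    weights = counts / total if total else counts
    return BinnedPoints(centers, mean_s, weights)


def _solve_at_vertex(c, y, w, d0):
    """Closed-form WLS of alpha, beta_minus, beta_plus at fixed vertex.

    Solves the 3x3 weighted normal equations for the design
    [1, (d0 - c)_+, (c - d0)_+].  A side with no points leaves that
    slope unidentifiable (NaN) and the remaining parameters are solved
    on the reduced system.
    """
    u = np.maximum(d0 - c, 0.0)
    v = np.maximum(c - d0, 0.0)
    cols = [np.ones_like(c), u, v]
    active = [True, bool(np.any(u > 0)), bool(np.any(v > 0))]
    A = np.column_stack([col for col, a in zip(cols, active) if a])
    atw = A.T * w
    theta = np.linalg.solve(atw @ A, atw @ y)
    full = np.full(3, np.nan)
    full[np.flatnonzero(active)] = theta
    resid = y - A @ theta
    q = float(np.sum(w * resid**2))
    return full, q


def fit_cusp(
    points: BinnedPoints,
    d0_low: float = D0_GRID_LOW,
    d0_high: float = D0_GRID_HIGH,
    d0_step: float = D0_GRID_STEP,
) -> CuspFit:
    """Grid search over the vertex D0 with closed-form slopes.

    For each grid value of D0 the three linear parameters come from the
    weighted normal equations; the candidate with the smallest weighted
    sum of squared residuals wins, ties broken toward the smallest |D0|.
    """
    pts = points.nonempty()
    if pts.n_points < 4:
        raise ValueError("need at least 4 non-empty binned points")
    c, y, w = pts.centers, pts.mean_s, pts.weights
    n_grid = int(round((d0_high - d0_low) / d0_step)) + 1
    grid = np.round(d0_low + d0_step * np.arange(n_grid), 10)

    best = None
    for d0 in grid:
        theta, q = _solve_at_vertex(c, y, w, d0)
        if best is None:
            best = (q, abs(d0), d0, theta)
            continue
        q_best = best[0]
        if q < q_best - 1e-12 or (abs(q - q_best) <= 1e-12 and abs(d0) < best[1]):
            best = (q, abs(d0), d0, theta)
    q, _, d0, theta = best
    # a side with no data past the vertex has slope 0 contribution; report
    # it as 0 only in the degenerate all-flat case, NaN otherwise
    alpha, bm, bp = theta
    return CuspFit(alpha=float(alpha), beta_minus=float(bm), beta_plus=float(bp),
                   d0=float(d0), q_value=float(q))


def fit_cusp_by_condition(records: pd.DataFrame, **bin_kwargs) -> dict[int, CuspFit]:
    """Per-tau cusp fits for one treatment's restricted records."""
    fits = {}
    for tau, g in records.groupby("tau", sort=True):
        fits[int(tau)] = fit_cusp(bin_moving_centers(g, **bin_kwargs))
    return fits


def fit_alpha_saturation(
    alpha_by_tau: pd.Series | dict[int, float],
    epsilon: float,
) -> tuple[float, float]:
    """Fit alpha(tau) with the saturation form at a fixed shared rate.

    With eps fixed, alpha(tau) = r alpha_1 + (1 - r) alpha_inf where
    r = (1 - eps)^(tau - 1) is linear in (alpha_1, alpha_inf); ordinary
    least squares solves it exactly.
    """
    items = sorted(dict(alpha_by_tau).items())
    if len(items) < 2:
        raise ValueError("need at least 2 tau levels")
    tau = np.array([t for t, _ in items], dtype=float)
    a = np.array([v for _, v in items], dtype=float)
    r = (1.0 - epsilon) ** (tau - 1.0)
    A = np.column_stack([r, 1.0 - r])
    theta, *_ = np.linalg.lstsq(A, a, rcond=None)
    return float(theta[0]), float(theta[1])


def summarize_constants(fits: Sequence[CuspFit]) -> tuple[float, float, float]:
    """Unweighted means of (D0, beta_minus, beta_plus) across tau levels,
    the values treated as tau-independent in the agent model."""
    if not fits:
        raise ValueError("need at least one cusp fit")
    return (
        float(np.mean([f.d0 for f in fits])),
        float(np.mean([f.beta_minus for f in fits])),
        float(np.mean([f.beta_plus for f in fits])),
    )
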