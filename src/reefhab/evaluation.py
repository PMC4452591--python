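"""Model evaluation: confusion counts, ROC distance, and the I_min sweep.

Predicted and observed presence are compared on the 1° grid as binary
matrices (presence = habitat fraction strictly above zero).  Subtracting
prediction from observation yields a signed map: −1 false positive, +1
false negative, 0 agreement.  Skill is summarized by the true/false
positive rates and the Euclidean distance of the operating point
(FPR, TPR) to the perfect-classification corner (0, 1).  The one free
model parameter, the minimum light intensity I_min, is chosen by sweeping
a coarse grid (50…500 by 50 μmol photons m⁻² s⁻¹), then refining at
10-unit steps around the coarse optimum, and taking the distance argmin
(ties resolved toward the smaller, less restrictive I_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import Raster
from .habitat import EnvStack, HabitatEvaluator, RegionMask, ToleranceLimits


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class RocPoint:
    i_min: float
    counts: ConfusionCounts
    TPR: float
    FPR: float
    distance: float
    area_km2: float


@dataclass
class SweepResult:
    """ROC points ordered by I_min and the distance-minimizing value."""

    points: list[RocPoint]
    best_i_min: float

    @property
    def best(self) -> RocPoint:
        return next(p for p in self.points if p.i_min == self.best_i_min)


def presence_matrix(fraction: Raster) -> Raster:
    """Binary presence: 1 where the habitat fraction is strictly above zero."""
    vals = fraction.values
    with np.errstate(invalid="ignore"):
        if np.any((vals[~np.isnan(vals)] < 0) | (vals[~np.isnan(vals)] > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        out = (vals > 0).astype(np.int8)
    return Raster(fraction.spec, out)


def confusion(observed: Raster, predicted: Raster) -> tuple[ConfusionCounts, Raster]:
    """Confusion counts plus the signed observed−predicted map.

    In the signed map −1 marks a false positive, +1 a false negative and 0
    agreement (true positive where observed is 1, true negative where 0).
    """
    if observed.spec != predicted.spec:
        raise ValueError("observed and predicted grids differ")
    obs = observed.values.astype(np.int8)
    pred = predicted.values.astype(np.int8)
    signed = obs - pred
    tp = int(((obs == 1) & (pred == 1)).sum())
    tn = int(((obs == 0) & (pred == 0)).sum())
    fp = int((signed == -1).sum())
    fn = int((signed == 1).sum())
    return ConfusionCounts(tp, fp, fn, tn), Raster(observed.spec, signed)


def rates(c: ConfusionCounts) -> tuple[float, float]:
    """(TPR, FPR) = (TP/(TP+FN), FP/(FP+TN))."""
    p = c.TP + c.FN
    n = c.FP + c.TN
    if p == 0 or n == 0:
        raise ValueError(
            f"rates undefined: positives={p}, negatives={n} (degenerate world)"
        )
    return c.TP / p, c.FP / n


def roc_distance(tpr: float, fpr: float) -> float:
    """Euclidean distance of (FPR, TPR) to the perfect corner (0, 1)."""
    return math.hypot(fpr, 1.0 - tpr)


def default_sweep_grid() -> np.ndarray:
    return np.arange(50.0, 500.0 + 1, 50.0)


def _evaluate_point(
    ev: HabitatEvaluator, observed_presence: Raster, i_min: float
) -> RocPoint:
    res = ev.result(i_min)
    pred = presence_matrix(res.coarse_fraction)
    counts, _ = confusion(observed_presence, pred)
    tpr, fpr = rates(counts)
    return RocPoint(i_min, counts, tpr, fpr, roc_distance(tpr, fpr), res.total_area_km2)


def sweep_imin(
    env: EnvStack,
    limits: ToleranceLimits,
    observed_presence: Raster,
    omega_mask: RegionMask | None = None,
    grid: Sequence[float] | None = None,
    refine_step: float = 10.0,
) -> SweepResult:
    """Optimize I_min by ROC distance.

    With ``grid=None`` the default protocol runs: coarse grid 50…500 at
    step 50, then a refinement at ``refine_step`` across the interval
    bracketing the coarse optimum.  An explicit ``grid`` (strictly
    increasing) is evaluated as-is, without refinement.  The envelope and
    bathymetry screens are computed once; only Z_max is re-evaluated per
    candidate.
    """
    ev = HabitatEvaluator(env, limits, omega_mask)

    def run(values: Sequence[float]) -> list[RocPoint]:
        return [_evaluate_point(ev, observed_presence, float(v)) for v in values]

    if grid is not None:
        g = np.asarray(grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        points = run(g)
    else:
        coarse = default_sweep_grid()
        points = run(coarse)
        dists = np.array([p.distance for p in points])
        k = int(np.argmin(dists))  # first minimum = smallest i_min on ties
        lo = coarse[max(k - 1, 0)]
        hi = coarse[min(k + 1, len(coarse) - 1)]
        fine = np.arange(lo, hi + refine_step / 2, refine_step)
        seen = {p.i_min for p in points}
        points.extend(run([v for v in fine if float(v) not in seen]))
        points.sort(key=lambda p: p.i_min)

    dists = np.array([p.distance for p in points])
    best = points[int(np.argmin(dists))].i_min
    return SweepResult(points, best)


def observed_presence_from_fraction(fraction: Raster) -> Raster:
    """Convenience alias for :func:`presence_matrix` on an observed fraction."""
    return presence_matrix(fraction)
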