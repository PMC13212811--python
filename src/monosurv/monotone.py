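"""Covariate-adjusted monotone MLE of the baseline hazard for LTRC data.

Given Cox coefficients ``beta`` fitted on left-truncated right-censored
data, the conditional likelihood for a nondecreasing baseline hazard
``lambda_0`` reduces, on the merged grid ``v_1 < ... < v_k`` of entry and
follow-up times, to

    l*(lambda_0) = sum_{i=1}^{k-1} { s_i log lambda_0(v_i) - lambda_0(v_i) } w_i,

with interval weights and levels

    w_i = (v_{i+1} - v_i) * sum_l exp(beta' z_l) 1{t_l <= v_i < y_l},
    s_i = d(v_i) / w_i.

Its maximizer subject to monotonicity is the weighted isotonic regression
of ``s`` with weights ``w`` — equivalently the left-derivative sequence of
the greatest convex minorant (GCM) of the cumulative-sum diagram (CSD), or
the max–min windows formula

    lambda_j = max_{r <= j} min_{j <= s <= k-1}
               (sum_{i=r}^{s} d(v_i)) / (sum_{i=r}^{s} w_i).

The fitted hazard is a left-closed, piecewise-constant, nondecreasing step
function; its integral is a continuous piecewise-linear cumulative hazard,
and ``S(y|z) = exp(-Lambda_0(y) exp(beta'z))`` is a continuous survival
curve.

Special cases: with empty ``beta`` (or a single covariate stratum) the
estimator reduces to Tsai's univariate monotone MLE; with all entries zero
it coincides with the Lopuhaä–Nane monotone estimator for right-censored
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .data import LTRCSample, TimeGrid, _as_beta, build_grid

__all__ = [
    "DegenerateGridError",
    "WeightedLevels",
    "CumSumDiagram",
    "StepHazard",
    "compute_weights",
    "build_csd",
    "isotonic_rates",
    "gcm_left_derivatives",
    "maxmin_oracle",
    "monotone_baseline",
    "cumulative_hazard",
    "survival_monotone",
    "tsai_estimator",
    "lopuhaa_estimator",
    "conditional_loglik",
]


class DegenerateGridError(ValueError):
    """Grid has fewer than two knots (all times identical)."""


@dataclass(frozen=True)
class WeightedLevels:
    """Interval weights ``w_i`` and levels ``s_i = d(v_i)/w_i``, i=1..k-1."""

    weights: np.ndarray
    levels: np.ndarray
    failures: np.ndarray  # d(v_i) for i = 1..k-1
    grid: TimeGrid
    beta_used: np.ndarray


@dataclass(frozen=True)
class CumSumDiagram:
    """CSD points P_0=(0,0), P_i=((1/n) sum w_j, (1/n) sum w_j s_j)."""

    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class StepHazard:
    """Left-closed nondecreasing step baseline hazard on a time grid.

    ``rates[j-1]`` is the hazard on ``[v_j, v_{j+1})`` for j = 1..k-1; the
    hazard is 0 before ``v_1`` and extends at ``rates[-1]`` beyond ``v_k``.
    """

    grid: TimeGrid
    rates: np.ndarray

    def hazard_at(self, y):
        y = np.asarray(y, dtype=float)
        padded = np.concatenate([[0.0], self.rates, [self.rates[-1]]])
        idx = np.searchsorted(self.grid.knots, y, side="right")
        out = padded[idx]
        return out if out.ndim else float(out)

    def cumulative_hazard(self, y):
        """Integral of the step hazard from 0 to y (piecewise linear)."""
        y = np.asarray(y, dtype=float)
        v = self.grid.knots
        # cumulative hazard at each knot; 0 at and before v_1
        cum_at_knots = np.concatenate(
            [[0.0], np.cumsum(np.diff(v) * self.rates)]
        )
        rate_padded = np.concatenate([[0.0], self.rates, [self.rates[-1]]])
        idx = np.searchsorted(v, y, side="right")
        base = np.concatenate([[0.0], cum_at_knots])[idx]
        anchor = np.concatenate([[0.0], v])[idx]
        out = base + (y - anchor) * rate_padded[idx]
        # below v_1 the hazard is 0 and anchor is 0, so out is 0 there
        return out if out.ndim else float(out)

    def survival(self, y, beta=None, z=None):
        from .classical import predict_survival

        return predict_survival(self.cumulative_hazard(y), beta, z)


def compute_weights(sample: LTRCSample, grid: TimeGrid, beta=None) -> WeightedLevels:
    """Interval weights and levels on the merged grid (right-open risk set).

    ``w_i = (v_{i+1}-v_i) * sum_l exp(beta'z_l) 1{t_l <= v_i < y_l}`` for
    i = 1..k-1 and ``s_i = d(v_i)/w_i``, set to 0 when ``w_i = 0``.  Note a
    failure CAN sit on a zero-weight interval: a subject failing at ``v_i``
    leaves the right-open risk set at its own failure time, so an isolated
    early entrant failing before anyone else has entered yields
    ``w_i = 0 < d(v_i)``.  The raw counts ``failures`` are kept alongside
    ``levels`` so the isotonic solver can treat that case exactly.
    """
    b = _as_beta(beta, sample.p)
    e = sample.linear_predictor(b)
    v = grid.knots
    k = v.shape[0]
    if k < 2:
        raise DegenerateGridError("need at least two distinct knots")
    # subject l is at risk (right-open) on knots [index(t_l), index(y_l))
    diff = np.zeros(k + 1)
    np.add.at(diff, np.searchsorted(v, sample.entry), e)
    np.add.at(diff, np.searchsorted(v, sample.time), -e)
    at_risk = np.cumsum(diff[:-1])
    # cancellation noise: an empty risk set must come out exactly zero
    at_risk[at_risk < 1e-9 * e.max()] = 0.0
    w = np.diff(v) * at_risk[:-1]
    d = grid.failures[:-1].astype(float)
    s = np.zeros_like(w)
    np.divide(d, w, out=s, where=w > 0)
    return WeightedLevels(w, s, d, grid, b)


def build_csd(levels: WeightedLevels, n: int) -> CumSumDiagram:
    """Cumulative-sum diagram whose GCM left derivatives give the rates.

    The y-coordinates are built from the failure counts directly, which is
    the identity ``(1/n) sum_{j<=i} w_j s_j = (1/n) * (failures at
    v_1..v_i)`` and stays exact on zero-weight failure intervals (where the
    diagram has a vertical jump).
    """
    x = np.concatenate([[0.0], np.cumsum(levels.weights)]) / n
    y = np.concatenate([[0.0], np.cumsum(levels.failures)]) / n
    return CumSumDiagram(x, y)


def _pava_blocks(d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stack PAVA over (D, W) ratio blocks with value ``D/W``.

    Solves ``max sum_i (d_i log r_i - w_i r_i)`` over nondecreasing ``r``
    (isotonic Poisson regression); adjacent violating blocks are pooled.
    A block with ``W = 0 < D`` has value +inf and therefore always pools
    forward into its successor; a trailing one cannot arise from
    :func:`compute_weights` because the subject observed longest keeps the
    final grid interval's weight positive.
    """

    def value(D, W):
        if W > 0:
            return D / W
        return np.inf if D > 0 else 0.0

    Ds: list = []
    Ws: list = []
    lens: list = []
    for i in range(d.shape[0]):
        D, W, L = float(d[i]), float(w[i]), 1
        while Ds and value(Ds[-1], Ws[-1]) >= value(D, W):
            D += Ds.pop()
            W += Ws.pop()
            L += lens.pop()
        Ds.append(D)
        Ws.append(W)
        lens.append(L)
    out = np.empty(d.shape[0])
    pos = 0
    for D, W, L in zip(Ds, Ws, lens):
        out[pos : pos + L] = value(D, W)
        pos += L
    return out


def isotonic_rates(levels: WeightedLevels) -> np.ndarray:
    """Monotone MLE rates: generalized weighted isotonic fit of the levels.

    Maximizes ``sum_i { d_i log r_i - w_i r_i }`` over nondecreasing rates.
    With all-positive weights this is the weighted isotonic regression of
    ``s = d/w`` on ``w`` (delegated to the linear-time PAVA in scipy) and
    equals the max–min windows formula and the GCM left derivatives of the
    CSD.  In general it matches the max–min formula with zero-total-weight
    windows skipped: intervals with ``w = 0, d = 0`` impose no constraint
    and take the fitted value of the next constraint-bearing interval,
    while intervals with ``w = 0 < d`` pool forward into the next block.
    """
    w = levels.weights
    d = levels.failures
    m = w.shape[0]
    if not np.any(w == 0):
        fit = isotonic_regression(levels.levels, weights=w, increasing=True).x
        return np.maximum(fit, 0.0)
    active = np.flatnonzero((w > 0) | (d > 0))
    rates = np.zeros(m)
    if active.size == 0:
        return rates
    if np.any(w[active] == 0):
        fit = _pava_blocks(d[active], w[active])
    else:
        fit = np.maximum(
            isotonic_regression(
                levels.levels[active], weights=w[active], increasing=True
            ).x,
            0.0,
        )
    # unconstrained (w=0, d=0) intervals take the next active fit value
    nxt = np.minimum(
        np.searchsorted(active, np.arange(m), side="left"), active.size - 1
    )
    rates[:] = fit[nxt]
    return rates


def gcm_left_derivatives(csd: CumSumDiagram) -> np.ndarray:
    """Left-derivative sequence of the greatest convex minorant of the CSD.

    Diagnostic/oracle route: builds the lower convex hull of the diagram's
    points and returns the hull slope immediately left of each ``P_i``,
    i = 1..k-1.  Assumes strictly increasing x (positive weights).
    """
    x, y = csd.x, csd.y
    hull = [0]
    for i in range(1, x.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # drop i1 if it lies above the chord i0 -> i
            if (y[i1] - y[i0]) * (x[i] - x[i0]) >= (y[i] - y[i0]) * (x[i1] - x[i0]):
                hull.pop()
            else:
                break
        hull.append(i)
    slopes = np.empty(x.size - 1)
    for a, b in zip(hull[:-1], hull[1:]):
        slopes[a:b] = (y[b] - y[a]) / (x[b] - x[a])
    return slopes


def maxmin_oracle(levels: WeightedLevels, grid: TimeGrid | None = None) -> np.ndarray:
    """Brute-force max–min rates (O(k^3) window enumeration; test oracle).

    ``lambda_j = max_{r<=j} min_{j<=s<=k-1} (sum_{i=r}^s d_i)/(sum_{i=r}^s w_i)``
    with zero-total-weight windows skipped (they impose no constraint).
    """
    w = levels.weights
    d = levels.failures
    m = w.shape[0]
    rates = np.zeros(m)
    for j in range(m):
        best = -np.inf
        for r in range(j + 1):
            worst = np.inf
            for s in range(j, m):
                W = w[r : s + 1].sum()
                if W <= 0:
                    continue
                worst = min(worst, d[r : s + 1].sum() / W)
            if np.isfinite(worst):
                best = max(best, worst)
        rates[j] = best if np.isfinite(best) else 0.0
    return rates


def monotone_baseline(sample: LTRCSample, beta=None) -> StepHazard:
    """Full pipeline: grid -> weights -> isotonic fit -> step hazard.

    A failure at the very last knot cannot enter any max–min window (the
    sums stop at k-1); the boundary convention extends the hazard at
    ``rates[-1]`` beyond ``v_k`` for both censored and failed largest
    observations.
    """
    grid = build_grid(sample)
    levels = compute_weights(sample, grid, beta)
    return StepHazard(grid, isotonic_rates(levels))


def cumulative_hazard(hazard: StepHazard, y):
    """Integrated baseline hazard ``Lambda_0(y)`` of a step hazard."""
    return hazard.cumulative_hazard(y)


def survival_monotone(hazard: StepHazard, beta=None, z=None, y=0.0):
    """Continuous covariate-specific survival from the monotone hazard."""
    return hazard.survival(y, beta, z)


def tsai_estimator(sample: LTRCSample) -> StepHazard:
    """Tsai's univariate monotone MLE: the proposed fit with empty beta."""
    return monotone_baseline(sample, None)


def lopuhaa_estimator(sample: LTRCSample, beta=None) -> StepHazard:
    """Lopuhaä–Nane monotone estimator: delayed entry deliberately ignored.

    The comparator applies only to right-censored data, so every entry is
    set to 0 before fitting; on truncated data its risk sets are inflated
    supersets of the truncation-aware ones.
    """
    return monotone_baseline(sample.with_zero_entry(), beta)


def conditional_loglik(hazard, sample: LTRCSample, beta=None) -> float:
    """Reduced conditional log-likelihood of a candidate step hazard.

    ``sum_i { s_i log lambda(v_i) - lambda(v_i) } w_i``, evaluated in the
    equivalent general form ``sum_i d_i log lambda(v_i) - w_i lambda(v_i)``
    with ``0 log 0 = 0``; a zero rate where failures occurred yields
    ``-inf`` (returned, not raised).  ``hazard`` may be a
    :class:`StepHazard` on the sample's grid or a raw rate array of
    length k-1.
    """
    grid = build_grid(sample)
    levels = compute_weights(sample, grid, beta)
    lam = hazard.rates if isinstance(hazard, StepHazard) else np.asarray(hazard, float)
    if lam.shape != levels.weights.shape:
        raise ValueError("candidate rates do not match the sample's grid")
    w, d = levels.weights, levels.failures
    if np.any((lam <= 0) & (d > 0)):
        return float("-inf")
    term = -w * lam
    haslog = d > 0
    term[haslog] += d[haslog] * np.log(lam[haslog])
    return float(term.sum())
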