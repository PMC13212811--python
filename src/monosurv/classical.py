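"""Non-monotone comparator estimators for LTRC data.

Three classical tools, each with the risk set modified for delayed entry
(``R(y) = {j : t_j <= y <= y_j}``):

* the truncated product-limit (Kaplan–Meier) survival estimator,
* Cox partial-likelihood estimation of the regression coefficients via
  Newton–Raphson with Breslow's convention for ties,
* the Breslow baseline cumulative-hazard estimator, with the covariate-
  specific survival predictor ``S(y|z) = exp(-Lambda_0(y) exp(beta'z))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LTRCSample, LTRCValidationError, _as_beta

__all__ = [
    "StepSurvival",
    "CoxFit",
    "CumHazardStep",
    "DesignMatrixError",
    "km_truncated",
    "cox_fit",
    "breslow_cumhaz",
    "predict_survival",
]

#: |beta| beyond this triggers the monotone-likelihood diagnostic: e^15-scale
#: relative weights poison downstream risk sums.
MONOTONE_LIKELIHOOD_BOUND = 15.0


class DesignMatrixError(ValueError):
    """Degenerate design (e.g. a constant covariate column)."""


@dataclass(frozen=True)
class StepSurvival:
    """Right-continuous step survival curve with initial value 1."""

    jump_times: np.ndarray
    values: np.ndarray

    def evaluate(self, y):
        """S(y): the value at the last jump time <= y, else 1."""
        y = np.asarray(y, dtype=float)
        idx = np.searchsorted(self.jump_times, y, side="right")
        vals = np.concatenate([[1.0], self.values])
        out = vals[idx]
        return out if out.ndim else float(out)

    __call__ = evaluate


@dataclass(frozen=True)
class CumHazardStep:
    """Step cumulative hazard: jumps of ``increments`` at ``jump_times``."""

    jump_times: np.ndarray
    increments: np.ndarray

    def evaluate(self, y):
        y = np.asarray(y, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        idx = np.searchsorted(self.jump_times, y, side="right")
        out = cum[idx]
        return out if out.ndim else float(out)

    __call__ = evaluate


@dataclass(frozen=True)
class CoxFit:
    """Result of the delayed-entry partial-likelihood fit."""

    beta: np.ndarray
    loglik: float
    score_norm: float
    information: np.ndarray
    converged: bool
    iterations: int
    monotone_likelihood: bool = False


def _event_blocks(sample: LTRCSample):
    """Distinct failure times with counts and per-time covariate sums."""
    ev = sample.status == 1
    t_ev = sample.time[ev]
    z_ev = sample.covariates[ev]
    uy, inv = np.unique(t_ev, return_inverse=True)
    d = np.bincount(inv, minlength=uy.size).astype(float)
    zsum = np.zeros((uy.size, sample.p))
    for j in range(sample.p):
        zsum[:, j] = np.bincount(inv, weights=z_ev[:, j], minlength=uy.size)
    return uy, d, zsum


def _risk_sums(sample: LTRCSample, columns: np.ndarray, times: np.ndarray):
    """Closed-risk-set column sums at each of ``times``.

    For each time y, returns sum over {j : t_j <= y <= y_j} of columns[j].
    Computed as (cumsum over entries <= y) - (cumsum over follow-ups < y).
    """
    order_t = np.argsort(sample.entry, kind="stable")
    order_y = np.argsort(sample.time, kind="stable")
    cum_t = np.vstack([np.zeros(columns.shape[1]), np.cumsum(columns[order_t], axis=0)])
    cum_y = np.vstack([np.zeros(columns.shape[1]), np.cumsum(columns[order_y], axis=0)])
    it = np.searchsorted(sample.entry[order_t], times, side="right")
    iy = np.searchsorted(sample.time[order_y], times, side="left")
    return cum_t[it] - cum_y[iy]


def km_truncated(sample: LTRCSample) -> StepSurvival:
    """Truncated product-limit estimator of the survival function.

    At each distinct failure time ``y_j`` the curve is multiplied by
    ``1 - d(y_j)/n(y_j)`` where ``n(y_j)`` counts subjects with
    ``t_i <= y_j <= y_i``.  With all entries zero this is the standard
    Kaplan–Meier estimator.
    """
    uy, d, _ = _event_blocks(sample)
    if uy.size == 0:
        return StepSurvival(np.empty(0), np.empty(0))
    n_at_risk = _risk_sums(sample, np.ones((sample.n, 1)), uy)[:, 0]
    # the failing subject is itself at risk, so n_at_risk >= d >= 1
    surv = np.cumprod(1.0 - d / n_at_risk)
    return StepSurvival(uy, surv)


def _partial_loglik_parts(sample: LTRCSample, beta: np.ndarray, uy, d, zsum):
    """Breslow-ties partial log-likelihood, score and information at beta."""
    p = sample.p
    e = sample.linear_predictor(beta)
    z = sample.covariates
    # columns: e, e*z (p), e*z_a*z_b upper triangle
    tri = [(a, b) for a in range(p) for b in range(a, p)]
    cols = np.empty((sample.n, 1 + p + len(tri)))
    cols[:, 0] = e
    for j in range(p):
        cols[:, 1 + j] = e * z[:, j]
    for m, (a, b) in enumerate(tri):
        cols[:, 1 + p + m] = e * z[:, a] * z[:, b]
    sums = _risk_sums(sample, cols, uy)
    s0 = sums[:, 0]
    s1 = sums[:, 1 : 1 + p]
    s2 = np.empty((uy.size, p, p))
    for m, (a, b) in enumerate(tri):
        s2[:, a, b] = s2[:, b, a] = sums[:, 1 + p + m]
    if np.any(s0 <= 0):
        raise LTRCValidationError("empty risk set at a failure time")
    ll = float((zsum @ beta).sum() - (d * np.log(s0)).sum())
    zbar = s1 / s0[:, None]
    score = (zsum - d[:, None] * zbar).sum(axis=0)
    info = np.einsum("i,iab->ab", d, s2 / s0[:, None, None]) - np.einsum(
        "i,ia,ib->ab", d, zbar, zbar
    )
    return ll, score, info


def cox_fit(
    sample: LTRCSample, tolerance: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Fit the Cox PH model with delayed-entry risk sets.

    Newton–Raphson from ``beta = 0`` with step-halving (up to 20 halvings
    per step); convergence declared when the max-norm of the score drops
    below ``tolerance``.  Ties share a Breslow denominator.
    """
    if sample.p < 1:
        raise DesignMatrixError("cox_fit requires at least one covariate")
    if sample.n_events < 1:
        raise LTRCValidationError("cox_fit requires at least one failure")
    if np.any(np.ptp(sample.covariates, axis=0) == 0):
        j = int(np.flatnonzero(np.ptp(sample.covariates, axis=0) == 0)[0])
        raise DesignMatrixError(
            f"covariate column {j} is constant: information matrix is singular"
        )
    uy, d, zsum = _event_blocks(sample)
    beta = np.zeros(sample.p)
    ll, score, info = _partial_loglik_parts(sample, beta, uy, d, zsum)
    converged = False
    monotone_flag = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) <= tolerance:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise DesignMatrixError("singular information matrix") from exc
        new_beta, new_ll, new_score, new_info = beta, ll, score, info
        scale = 1.0
        for _ in range(21):
            cand = beta + scale * step
            cll, cscore, cinfo = _partial_loglik_parts(sample, cand, uy, d, zsum)
            if cll > ll or not np.isfinite(ll):
                new_beta, new_ll, new_score, new_info = cand, cll, cscore, cinfo
                break
            scale *= 0.5
        else:
            # no improving step found: stop at the current iterate
            break
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > MONOTONE_LIKELIHOOD_BOUND:
            monotone_flag = True
            break
    if np.max(np.abs(score)) <= tolerance and not monotone_flag:
        converged = True
    return CoxFit(
        beta=beta,
        loglik=ll,
        score_norm=float(np.max(np.abs(score))),
        information=info,
        converged=converged,
        iterations=it,
        monotone_likelihood=monotone_flag,
    )


def breslow_cumhaz(sample: LTRCSample, beta=None) -> CumHazardStep:
    """Breslow baseline cumulative-hazard estimator with delayed entry.

    The increment at each distinct failure time is
    ``d(y_(k)) / sum_{j in R(y_(k))} exp(beta' z_j)`` over the closed risk
    set.  With empty ``beta`` and no truncation this is the Nelson–Aalen
    estimator.
    """
    b = _as_beta(beta, sample.p)
    uy, d, _ = _event_blocks(sample)
    if uy.size == 0:
        return CumHazardStep(np.empty(0), np.empty(0))
    e = sample.linear_predictor(b)
    denom = _risk_sums(sample, e[:, None], uy)[:, 0]
    return CumHazardStep(uy, d / denom)


def predict_survival(cumhaz_at_y, beta=None, z=None):
    """``exp(-Lambda_0(y) * exp(beta'z))`` for a given covariate vector.

    Applies unchanged to the step (Breslow) and the continuous (monotone)
    cumulative hazards.
    """
    H = np.asarray(cumhaz_at_y, dtype=float)
    if np.any(H < 0):
        raise ValueError("cumulative hazard must be nonnegative")
    if beta is None or np.size(beta) == 0 or z is None or np.size(z) == 0:
        lp = 0.0
    else:
        lp = float(np.dot(np.atleast_1d(beta), np.atleast_1d(z)))
    out = np.exp(-H * np.exp(lp))
    return out if out.ndim else float(out)
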