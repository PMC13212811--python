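"""Left-truncated right-censored (LTRC) samples and risk-set primitives.

A subject contributes a delayed-entry (truncation) time ``t``, a follow-up
time ``y = min(event, censoring)``, an event indicator ``delta`` and an
optional covariate vector ``z``.  Observation is conditional on ``t <= y``:
subjects whose event or censoring precedes entry are never seen, which is
the selection bias every estimator downstream has to contend with.

The module also builds the merged time grid ``v_1 < ... < v_k`` pooled from
all entry and follow-up times, with per-knot failure counts, and exposes the
two risk-set weights shared by the estimators:

* closed,      ``R(y)  = {j : t_j <= y <= y_j}`` — Cox / Breslow / product-limit;
* right-open,  ``R(y+) = {l : t_l <= y <  y_l}`` — the monotone estimator's
  interval weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LTRCFormatError",
    "LTRCValidationError",
    "LTRCSample",
    "LatentSample",
    "TimeGrid",
    "load_ltrc",
    "apply_observation_filter",
    "build_grid",
    "risk_weight",
]

REQUIRED_COLUMNS = ("entry", "time", "status")


class LTRCFormatError(ValueError):
    """Input table does not have the required columns/shape."""


class LTRCValidationError(ValueError):
    """A record violates the LTRC data contract."""


def _as_beta(beta, p: int) -> np.ndarray:
    """Coerce ``beta`` to a length-``p`` float vector; empty/None means zeros."""
    if beta is None:
        return np.zeros(p)
    b = np.atleast_1d(np.asarray(beta, dtype=float))
    if b.size == 0:
        return np.zeros(p)
    if b.shape != (p,):
        raise LTRCValidationError(
            f"coefficient vector has length {b.size}, expected {p}"
        )
    return b


@dataclass(frozen=True)
class LTRCSample:
    """An observed LTRC sample stored as parallel arrays.

    Parameters
    ----------
    entry : array of shape (n,)
        Delayed-entry (left-truncation) times ``t_i >= 0``.
    time : array of shape (n,)
        Follow-up times ``y_i = min(x_i, c_i)``; strictly greater than entry.
    status : array of shape (n,)
        Event indicators ``delta_i`` in {0, 1} (1 = observed failure).
    covariates : array of shape (n, p)
        Baseline covariates ``z_i``; ``p = 0`` for univariate analyses.
    """

    entry: np.ndarray
    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        n = entry.shape[0]
        if n < 1:
            raise LTRCValidationError("an LTRC sample requires n >= 1 records")
        if time.shape != (n,) or status.shape != (n,):
            raise LTRCValidationError("entry/time/status must have equal length")
        cov = self.covariates
        if cov is None:
            cov = np.empty((n, 0))
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise LTRCValidationError("covariate rows must match n")
        bad = ~np.isin(status, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise LTRCValidationError(
                f"record {i}: status {status[i]!r} outside {{0, 1}}"
            )
        if (entry < 0).any():
            i = int(np.flatnonzero(entry < 0)[0])
            raise LTRCValidationError(f"record {i}: entry {entry[i]} < 0")
        nonpos = time <= entry
        if nonpos.any():
            i = int(np.flatnonzero(nonpos)[0])
            raise LTRCValidationError(
                f"record {i}: follow-up time {time[i]} <= entry {entry[i]} "
                "(subjects with zero time under observation are rejected)"
            )
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int8))
        object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return self.entry.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, mask) -> "LTRCSample":
        mask = np.asarray(mask)
        return LTRCSample(
            self.entry[mask], self.time[mask], self.status[mask], self.covariates[mask]
        )

    def with_zero_entry(self) -> "LTRCSample":
        """Copy with all entries set to 0 (delayed entry deliberately ignored)."""
        return LTRCSample(
            np.zeros(self.n), self.time, self.status, self.covariates
        )

    def linear_predictor(self, beta) -> np.ndarray:
        """``exp(beta' z_i)`` for every record (all ones when beta is empty)."""
        b = _as_beta(beta, self.p)
        if self.p == 0:
            return np.ones(self.n)
        return np.exp(self.covariates @ b)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"entry": self.entry, "time": self.time, "status": self.status}
        )
        for j in range(self.p):
            df[f"z{j + 1}"] = self.covariates[:, j]
        return df


@dataclass(frozen=True)
class LatentSample:
    """Pre-filter latent records: entry T, event time X, censoring time C."""

    entry: np.ndarray
    event_time: np.ndarray
    censor_time: np.ndarray
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        x = np.asarray(self.event_time, dtype=float)
        c = np.asarray(self.censor_time, dtype=float)
        n = entry.shape[0]
        if x.shape != (n,) or c.shape != (n,):
            raise LTRCValidationError("latent arrays must have equal length")
        if (x <= 0).any() or (c <= 0).any():
            raise LTRCValidationError("latent event/censoring times must be > 0")
        cov = self.covariates
        if cov is None:
            cov = np.empty((n, 0))
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        object.__setattr__(self, "entry", entry)
        object.__setattr__(self, "event_time", x)
        object.__setattr__(self, "censor_time", c)
        object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return self.entry.shape[0]


@dataclass(frozen=True)
class TimeGrid:
    """Merged grid ``v_1 < ... < v_k`` of all entry and follow-up times.

    ``failures[j]`` counts records failing exactly at ``knots[j]``
    (censored records contribute nothing).
    """

    knots: np.ndarray
    failures: np.ndarray

    @property
    def k(self) -> int:
        return self.knots.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.failures.sum())

    def index_of(self, times) -> np.ndarray:
        """Knot indices of ``times``; every sample entry/time maps exactly."""
        idx = np.searchsorted(self.knots, np.asarray(times, dtype=float))
        return idx


def load_ltrc(source: Union[str, "pd.DataFrame"]) -> LTRCSample:
    """Read an LTRC sample from a CSV path (or an in-memory DataFrame).

    The table must carry columns ``entry``, ``time``, ``status``; every
    remaining numeric column is treated as a covariate, in column order.
    Row order is preserved.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        # exact float parsing so written curves re-evaluate identically
        df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LTRCFormatError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise LTRCValidationError("empty table: an LTRC sample requires n >= 1")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    cov = df[extra].to_numpy(dtype=float) if extra else np.empty((len(df), 0))
    status_raw = df["status"].to_numpy()
    return LTRCSample(
        df["entry"].to_numpy(dtype=float),
        df["time"].to_numpy(dtype=float),
        status_raw,
        cov,
    )


def apply_observation_filter(latent: LatentSample):
    """Apply the LTRC observation filter ``T <= Y`` to latent records.

    Each latent record with ``entry <= min(event_time, censor_time)`` becomes
    an observed record with ``time = min(X, C)`` and ``status = 1{X <= C}``;
    the rest are dropped (left truncated).

    Returns
    -------
    (LTRCSample, int)
        The observed sample and the number of dropped records.
    """
    y = np.minimum(latent.event_time, latent.censor_time)
    keep = latent.entry <= y
    dropped = int((~keep).sum())
    status = (latent.event_time <= latent.censor_time).astype(np.int8)
    sample = LTRCSample(
        latent.entry[keep], y[keep], status[keep], latent.covariates[keep]
    )
    return sample, dropped


def build_grid(sample: LTRCSample) -> TimeGrid:
    """Pool entries and follow-up times into the ordered distinct grid."""
    knots = np.unique(np.concatenate([sample.entry, sample.time]))
    failures = np.zeros(knots.shape[0], dtype=np.int64)
    ev = sample.status == 1
    idx = np.searchsorted(knots, sample.time[ev])
    np.add.at(failures, idx, 1)
    return TimeGrid(knots, failures)


def risk_weight(
    sample: LTRCSample, y: float, beta=None, closure: str = "closed"
) -> float:
    """Sum of ``exp(beta' z_j)`` over the risk set at ``y``.

    ``closure='closed'`` uses ``{j : t_j <= y <= y_j}``; ``'right_open'``
    uses ``{l : t_l <= y < y_l}``.  With an empty ``beta`` this is the plain
    risk-set count ``n(y)``.
    """
    if closure not in ("closed", "right_open"):
        raise ValueError(f"unknown closure {closure!r}")
    e = sample.linear_predictor(beta)
    at_risk = sample.entry <= y
    if closure == "closed":
        at_risk &= y <= sample.time
    else:
        at_risk &= y < sample.time
    return float(e[at_risk].sum())
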