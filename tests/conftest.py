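import numpy as np
import pytest

from monosurv import LTRCSample


def random_ltrc(rng: np.random.Generator, n: int, p: int = 0) -> LTRCSample:
    """A small random LTRC sample with nondegenerate follow-up."""
    entry = rng.uniform(0.0, 2.0, n)
    entry[rng.random(n) < 0.4] = 0.0  # a mix of truncated and untruncated
    time = entry + rng.exponential(2.0, n) + 1e-3
    status = (rng.random(n) < 0.6).astype(int)
    cov = rng.normal(0.0, 1.0, (n, p)) if p else np.empty((n, 0))
    return LTRCSample(entry, time, status, cov)


def tsai_brute(sample):
    """Independent univariate monotone-hazard fit: direct enumeration of
    the interval weights plus the brute-force max-min windows formula.

    Kept free of any call into the package's own grid/weight/PAVA code so
    it can serve as an oracle for the covariate-free reduction.
    """
    knots = np.unique(np.concatenate([sample.entry, sample.time]))
    k = knots.size
    w = np.empty(k - 1)
    d = np.empty(k - 1)
    for i in range(k - 1):
        at_risk = sum(
            1 for t, y in zip(sample.entry, sample.time) if t <= knots[i] < y
        )
        w[i] = (knots[i + 1] - knots[i]) * at_risk
        d[i] = sum(
            1
            for y, st in zip(sample.time, sample.status)
            if y == knots[i] and st == 1
        )
    rates = np.zeros(k - 1)
    for j in range(k - 1):
        best = -np.inf
        for r in range(j + 1):
            worst = np.inf
            for s in range(j, k - 1):
                W = w[r : s + 1].sum()
                if W <= 0:
                    continue
                worst = min(worst, d[r : s + 1].sum() / W)
            if np.isfinite(worst):
                best = max(best, worst)
        rates[j] = best if np.isfinite(best) else 0.0
    return knots, rates


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_sample():
    """Three subjects: (entry, time, status) = (0,2,1), (1,3,1), (0,4,0)."""
    return LTRCSample([0, 1, 0], [2, 3, 4], [1, 1, 0])


@pytest.fixture
def two_record_sample():
    """(0,2,1) and (1,3,0): the worked grid/weights example."""
    return LTRCSample([0, 1], [2, 3], [1, 0])
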