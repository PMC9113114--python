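"""Moment-matched truncated-normal sampling.

Cohort characteristics (age, grip strength, clinical scores) and ROI volumes
are calibrated to published cohort tables that report a mean and SD, but every
one of these quantities lives on a bounded support (ages 8-30 years, forces
and volumes positive, severity scores on a fixed scale).  Drawing from a
normal with the printed moments and then truncating would bias the sample
mean away from the printed value -- for a score with mean 29.5 and SD 19.0
truncated at zero the bias exceeds +2 units.  Instead we solve for the parent
normal whose *truncated* distribution has exactly the requested mean and SD.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm


def _truncated_moments(mu: float, sigma: float, low: float, high: float):
    a = (low - mu) / sigma
    b = (high - mu) / sigma
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


@lru_cache(maxsize=512)
def match_truncated_normal(
    mean: float, sd: float, low: float = -np.inf, high: float = np.inf
) -> tuple[float, float]:
    """Parent ``(mu, sigma)`` whose [low, high]-truncation has ``mean``/``sd``.

    Raises ``ValueError`` if the target moments are infeasible on the support
    (the truncated-normal family cannot exceed the uniform SD on an interval).
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if not (low < high):
        raise ValueError(f"empty support [{low}, {high}]")
    if np.isfinite(low) and np.isfinite(high):
        if not (low < mean < high):
            raise ValueError(f"target mean {mean} outside support [{low}, {high}]")
    if sd == 0:
        return float(mean), 0.0
    if np.isneginf(low) and np.isposinf(high):
        return float(mean), float(sd)

    def resid(params):
        mu, log_sigma = params
        m, s = _truncated_moments(mu, np.exp(log_sigma), low, high)
        return [m - mean, s - sd]

    sol = optimize.least_squares(
        resid, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    m, s = _truncated_moments(mu, sigma, low, high)
    if abs(m - mean) > 1e-6 * max(1.0, abs(mean)) or abs(s - sd) > 1e-4 * sd:
        raise ValueError(
            f"cannot match mean={mean}, sd={sd} on [{low}, {high}] "
            f"(best achieved mean={m:.4f}, sd={s:.4f})"
        )
    return float(mu), sigma


def rvs_matched(
    mean: float,
    sd: float,
    low: float,
    high: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``size`` variates whose population mean/SD equal ``mean``/``sd``."""
    if sd == 0:
        return np.full(size, float(mean))
    mu, sigma = match_truncated_normal(mean, sd, low, high)
    a = (low - mu) / sigma
    b = (high - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def ppf_matched(
    u: np.ndarray, mean: float, sd: float, low: float, high: float
) -> np.ndarray:
    """Quantile transform of uniforms; used for Gaussian-copula coupling."""
    if sd == 0:
        return np.full(np.shape(u), float(mean))
    mu, sigma = match_truncated_normal(mean, sd, low, high)
    a = (low - mu) / sigma
    b = (high - mu) / sigma
    return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
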