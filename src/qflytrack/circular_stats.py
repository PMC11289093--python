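"""Directional statistics for flight directions and turning angles.

Implements the first trigonometric moment (mean direction and mean
resultant length R-bar), maximum-likelihood von Mises concentration,
and the uniformity / homogeneity tests used on insect heading data:

* Rayleigh test (series approximation to the p-value),
* Hermans-Rasson test (Monte-Carlo null; high power against
  multimodal departures from uniformity),
* Watson-Williams F test for homogeneity of mean directions,
* chi-squared tests on turning angles grouped into 45-degree
  quadrants and into binary left/right and forward/backward classes.

All angles are radians wrapped to (-pi, pi].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import optimize, special, stats

from .track_io import wrap_angle

__all__ = [
    "CircSample",
    "CircTestResult",
    "mean_direction_and_R",
    "vonmises_kappa",
    "rayleigh_test",
    "hermans_rasson_test",
    "watson_williams_test",
    "quadrant_bias_tests",
]


@dataclass
class CircSample:
    """A sample of circular observations, wrapped to (-pi, pi]."""

    angles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles, dtype=float)
        if a.size < 1:
            raise ValueError("circular sample needs at least one angle")
        self.angles = np.asarray(wrap_angle(a))

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass
class CircTestResult:
    method: str
    statistic: float
    p_value: float
    df: Optional[tuple[int, int]] = None
    mc_reps: Optional[int] = None
    seed: Optional[int] = None
    detail: str = ""
    n_excluded: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["df"] = list(self.df) if self.df is not None else None
        return json.dumps(d)


def _as_sample(sample) -> CircSample:
    return sample if isinstance(sample, CircSample) else CircSample(np.asarray(sample))


def mean_direction_and_R(sample) -> tuple[float, float]:
    """Mean direction and mean resultant length R-bar in [0, 1].

    The mean direction is undefined (returned as ``nan``) when the
    resultant vanishes.
    """
    s = _as_sample(sample)
    C = np.mean(np.cos(s.angles))
    S = np.mean(np.sin(s.angles))
    R = float(np.hypot(C, S))
    if R < 1e-15:
        return float("nan"), 0.0
    return float(np.arctan2(S, C)), R


def _A(kappa: float) -> float:
    """Bessel ratio A(kappa) = I1/I0, computed with exponentially scaled Bessels."""
    return special.i1e(kappa) / special.i0e(kappa)


def vonmises_kappa(sample) -> float:
    """ML von Mises concentration: the root of A(kappa) = R-bar.

    Returns 0 for R-bar = 0 and ``inf`` (with a warning) for R-bar = 1.
    """
    s = _as_sample(sample)
    if s.n < 2:
        raise ValueError("need n >= 2 to estimate concentration")
    _, R = mean_direction_and_R(s)
    if R <= 0:
        return 0.0
    if R >= 1.0 - 1e-12:
        warnings.warn("R-bar = 1: concentration unbounded", RuntimeWarning)
        return float("inf")
    hi = 2.0
    while _A(hi) < R:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            return float("inf")
    return float(optimize.brentq(lambda k: _A(k) - R, 0.0, hi, xtol=1e-12))


def rayleigh_test(sample) -> CircTestResult:
    """Rayleigh test of circular uniformity, Z = n * R-bar^2.

    The p-value uses the standard fourth-order series approximation,
    clamped to [0, 1].
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise ValueError("Rayleigh test needs n >= 3")
    n = s.n
    _, R = mean_direction_and_R(s)
    Z = n * R * R
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return CircTestResult("rayleigh", float(Z), float(np.clip(p, 0.0, 1.0)))


@njit(cache=True)
def _hr_statistic(theta: np.ndarray) -> float:
    n = theta.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            d = theta[i] - theta[j]
            ad = abs(d) % (2.0 * np.pi)
            total += abs(ad - np.pi) - np.pi / 2.0
            total -= 2.895 * (abs(np.sin(d)) - 2.0 / np.pi)
    return total / n


def hermans_rasson_test(sample, mc_reps: int = 9999,
                        seed: Optional[int] = None) -> CircTestResult:
    """Hermans-Rasson test of circular uniformity with a Monte-Carlo null.

    The statistic is the recommended second form
    ``T = (1/n) sum_ij [ |pi - |t_i - t_j|| - pi/2
    - 2.895 (|sin(t_i - t_j)| - 2/pi) ]``; larger T means stronger
    departure from uniformity.  p = (1 + #{T_null >= T_obs}) / (mc_reps + 1).
    """
    s = _as_sample(sample)
    if s.n < 3:
        raise ValueError("Hermans-Rasson test needs n >= 3")
    if mc_reps < 999:
        raise ValueError("mc_reps must be >= 999")
    t_obs = _hr_statistic(s.angles)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(mc_reps):
        null = rng.uniform(-np.pi, np.pi, s.n)
        if _hr_statistic(null) >= t_obs:
            exceed += 1
    p = (1.0 + exceed) / (mc_reps + 1.0)
    return CircTestResult("hermans_rasson", float(t_obs), float(p),
                          mc_reps=mc_reps, seed=seed)


def watson_williams_test(groups: Sequence) -> CircTestResult:
    """Watson-Williams F test for homogeneity of mean directions.

    Classical statistic with the 1 + 3/(8 kappa-hat) correction;
    df = (k - 1, N - k).  A warning is emitted when the pooled
    concentration estimate falls below 1 (the test's assumptions are
    then shaky).
    """
    gs = [_as_sample(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for g in gs:
        if g.n < 2:
            raise ValueError("each group needs n >= 2")
        mu, R = mean_direction_and_R(g)
        if not np.isfinite(mu):
            raise ValueError("a group has undefined mean direction (R = 0)")
    k = len(gs)
    N = sum(g.n for g in gs)
    Ri = np.array([g.n * mean_direction_and_R(g)[1] for g in gs])
    all_angles = np.concatenate([g.angles for g in gs])
    _, Rbar_all = mean_direction_and_R(CircSample(all_angles))
    R_total = N * Rbar_all
    sumRi = float(np.sum(Ri))
    rw = sumRi / N
    # kappa-hat solved from the weighted resultant rw (the classical recipe)
    if 0 < rw < 1 - 1e-12:
        kappa_w = float(optimize.brentq(lambda x: _A(x) - rw, 0.0, 1e6))
    else:
        kappa_w = float("inf")
    if kappa_w < 1:
        warnings.warn(
            "pooled concentration < 1: Watson-Williams assumptions questionable",
            RuntimeWarning,
        )
    K = 1.0 + 3.0 / (8.0 * kappa_w)
    df1, df2 = k - 1, N - k
    denom = N - sumRi
    F = K * (df2 * (sumRi - R_total)) / (df1 * denom)
    p = float(stats.f.sf(F, df1, df2))
    return CircTestResult("watson_williams", float(F), p, df=(df1, df2))


def quadrant_bias_tests(turning) -> list[CircTestResult]:
    """Chi-squared bias tests on turning angles.

    Three goodness-of-fit tests, all against equiprobable classes:

    a. eight 45-degree quadrants (uniformity);
    b. left (theta > 0) vs right (theta < 0) of the previous heading,
       angles of exactly 0 or pi excluded;
    c. forward (|theta| < pi/2) vs backward (|theta| > pi/2), boundary
       angles |theta| = pi/2 excluded.

    Asymptotic chi-squared p-values, no continuity correction.
    """
    s = _as_sample(turning)
    if s.n < 8:
        raise ValueError("quadrant tests need n >= 8")
    a = s.angles
    out = []

    # (a) 8-bin uniformity; bin edges at multiples of pi/4 over (-pi, pi]
    edges = np.linspace(-np.pi, np.pi, 9)
    idx = np.clip(np.searchsorted(edges, a, side="left") - 1, 0, 7)
    counts = np.bincount(idx, minlength=8)
    chi2, p = stats.chisquare(counts)
    out.append(CircTestResult("chisq_quadrant", float(chi2), float(p),
                              df=(7, 0), detail="45deg_8bin"))

    # (b) left vs right
    keep = (a != 0.0) & (np.abs(a) != np.pi)
    left = int(np.sum(a[keep] > 0))
    right = int(np.sum(a[keep] < 0))
    if left + right == 0:
        raise ValueError("all angles lie on the left/right exclusion boundary")
    chi2, p = stats.chisquare([left, right])
    out.append(CircTestResult("chisq_quadrant", float(chi2), float(p), df=(1, 0),
                              detail="left_right", n_excluded=int(s.n - left - right)))

    # (c) forward vs backward
    keep = np.abs(np.abs(a) - np.pi / 2) > 0
    fwd = int(np.sum(np.abs(a[keep]) < np.pi / 2))
    bwd = int(np.sum(np.abs(a[keep]) > np.pi / 2))
    if fwd + bwd == 0:
        raise ValueError("all angles lie on the forward/backward exclusion boundary")
    chi2, p = stats.chisquare([fwd, bwd])
    out.append(CircTestResult("chisq_quadrant", float(chi2), float(p), df=(1, 0),
                              detail="forward_backward", n_excluded=int(s.n - fwd - bwd)))
    return out
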