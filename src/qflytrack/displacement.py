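"""Mean-squared-displacement (MSD) analysis.

Compares the empirical MSD of observed tracks against the predictions
of an uncorrelated random walk, MSD(n) = n * E[L^2], and of a
correlated random walk with symmetric turning (Kareiva-Shigesada):

    MSD(n) = n*m2 + 2*m1^2 * c * (n - (1 - c^n)/(1 - c)) / (1 - c)

where m1 = E[L], m2 = E[L^2] are the step-length moments and
c = E[cos theta] is the mean cosine of the turning angle.  Departures
from the CRW prediction are flagged with a seeded Monte-Carlo envelope
(2.5th/97.5th percentiles of cohorts simulated from the fitted CRW
with the observed path-count/length structure).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .track_io import MovementPath, StepSeries
from .movement_models import CrwModel, simulate_path

__all__ = [
    "empirical_msd",
    "rw_msd",
    "crw_msd",
    "crw_moments",
    "msd_deviation_test",
]


def _positions(obj) -> np.ndarray:
    if isinstance(obj, MovementPath):
        return obj.xy()
    if isinstance(obj, StepSeries):
        return obj.positions()
    return np.asarray(obj, dtype=float)


def empirical_msd(paths: Sequence, n_max: int) -> pd.DataFrame:
    """Observed MSD per step count.

    For each n <= n_max, the mean over paths with at least n steps of
    the squared straight-line distance from the path's first fix to the
    fix after n steps.  Columns: n, msd_obs, n_paths.
    """
    pos = [_positions(p) for p in paths]
    max_len = max(len(p) - 1 for p in pos)
    if n_max > max_len:
        raise ValueError(f"n_max={n_max} exceeds the longest path ({max_len} steps)")
    rows = []
    for n in range(1, n_max + 1):
        d2 = [float(np.sum((p[n] - p[0]) ** 2)) for p in pos if len(p) - 1 >= n]
        if not d2:
            break
        rows.append((n, float(np.mean(d2)), len(d2)))
    return pd.DataFrame(rows, columns=["n", "msd_obs", "n_paths"])


def rw_msd(n, L: float):
    """Random-walk prediction MSD(n) = n * L, L the mean squared step length."""
    if L < 0:
        raise ValueError("L must be >= 0")
    return np.asarray(n, dtype=float) * L


def crw_msd(n, m1: float, m2: float, c: float):
    """Correlated-random-walk MSD with symmetric turning.

    ``c`` is the mean cosine of the turning angle; |c| must be < 1
    (the ballistic limit is undefined).
    """
    if abs(c) >= 1:
        raise ValueError("|c| must be < 1")
    n = np.asarray(n, dtype=float)
    if c == 0:
        return n * m2
    u = 1.0 - c
    if c > 0.5:
        # stable near the ballistic limit: n - (1-c^n)/u = (n*u - (1-c^n))/u
        one_minus_cn = -np.expm1(n * np.log1p(-u))
        bracket = (n * u - one_minus_cn) / u
    else:
        bracket = n - (1.0 - c ** n) / u
    return n * m2 + 2.0 * m1 * m1 * c * bracket / u


def crw_moments(series: Sequence[StepSeries]) -> tuple[float, float, float]:
    """Pooled (m1, m2, c): step-length moments and mean turning cosine."""
    lengths = np.concatenate([s.lengths for s in series if s.n_steps > 0])
    turns = np.concatenate([s.turning_angles for s in series if s.n_steps > 1])
    m1 = float(np.mean(lengths))
    m2 = float(np.mean(lengths ** 2))
    c = float(np.mean(np.cos(turns))) if turns.size else 0.0
    return m1, m2, c


def msd_deviation_test(paths: Sequence, crw: CrwModel, n_max: int,
                       mc_reps: int = 999, seed: Optional[int] = None) -> pd.DataFrame:
    """Monte-Carlo envelope test of observed MSD against a fitted CRW.

    Simulates ``mc_reps`` cohorts matching the observed path-count and
    path-length structure from ``crw``; the envelope is the 2.5th/97.5th
    percentile of cohort MSD at each n.  Returns the MSD table with
    mc_low, mc_high, and an ``outside`` flag per n.
    """
    if mc_reps < 999:
        raise ValueError("mc_reps must be >= 999")
    obs = empirical_msd(paths, n_max)
    n_steps_per_path = [len(_positions(p)) - 1 for p in paths]
    rng = np.random.default_rng(seed)
    coh = np.full((mc_reps, len(obs)), np.nan)
    for r in range(mc_reps):
        sim = [simulate_path(crw, k, seed=rng.integers(2 ** 31))[0]
               for k in n_steps_per_path]
        t = empirical_msd(sim, n_max)
        coh[r, : len(t)] = t["msd_obs"].to_numpy()
    out = obs.copy()
    out["mc_low"] = np.nanpercentile(coh, 2.5, axis=0)
    out["mc_high"] = np.nanpercentile(coh, 97.5, axis=0)
    out["outside"] = (out["msd_obs"] < out["mc_low"]) | (out["msd_obs"] > out["mc_high"])
    return out
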