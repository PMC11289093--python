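"""Scale-dependent fractal dimension of movement paths.

The dividers method measures a path with a "ruler" of span delta: walk
divider endpoints along the polyline (each endpoint is the first point
along the path at chord distance delta from the previous endpoint) and
record stepped length = count * delta + the straight-line remainder.
The fractal dimension at a scale follows from how measured length
shrinks with delta, L(delta) ~ delta^(1-D), estimated locally by
regressing log L on log delta inside a sliding window on the log-scale
axis (D = 1 - slope; 1 = straight, 2 = plane-filling).

A two-phase (threshold) regression of D against log10 scale then asks
whether path tortuosity changes abruptly at some spatial scale: the
maximal likelihood-ratio-type statistic N*log(RSS0/RSS1) is scanned
over candidate thresholds and calibrated by parametric bootstrap from
the single-line null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .track_io import MovementPath, StepSeries

__all__ = [
    "divider_length",
    "fractal_profile",
    "FractalProfile",
    "ChangepointFit",
    "two_phase_fit",
]


def _as_xy(path) -> np.ndarray:
    if isinstance(path, MovementPath):
        return path.xy()
    if isinstance(path, StepSeries):
        return path.positions()
    return np.asarray(path, dtype=float)


def divider_length(path, delta: float) -> tuple[float, int]:
    """Stepped length and divider count of a path at span ``delta``.

    Walks from the path start; each divider endpoint is the first point
    along the polyline at Euclidean (chord) distance ``delta`` from the
    previous endpoint.  Returns ``(count*delta + remainder, count)``
    where the remainder is the straight-line distance from the last
    endpoint to the path end.  Raises if the path's gross length is
    below ``delta`` (not measurable at this scale).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    P = _as_xy(path)
    seg = np.diff(P, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if float(seg_len.sum()) < delta:
        raise ValueError("path gross length below delta: not measurable")

    count = 0
    c = P[0].copy()          # current divider endpoint
    i = 0                    # current segment index
    t = 0.0                  # position parameter on segment i
    n_seg = len(seg)
    while True:
        found = False
        j, u0 = i, t
        while j < n_seg:
            a, d = P[j], seg[j]
            # |a + u d - c|^2 = delta^2 for u in (u0, 1]
            A = float(d @ d)
            if A > 0:
                w = a - c
                B = 2.0 * float(w @ d)
                C = float(w @ w) - delta * delta
                disc = B * B - 4.0 * A * C
                if disc >= 0:
                    r = math.sqrt(disc)
                    for u in ((-B - r) / (2 * A), (-B + r) / (2 * A)):
                        if u0 < u <= 1.0 + 1e-12:
                            u = min(u, 1.0)
                            c = a + u * d
                            i, t = j, u
                            found = True
                            break
            if found:
                break
            j += 1
            u0 = 0.0
        if not found:
            break
        count += 1
    remainder = float(np.hypot(*(P[-1] - c)))
    return count * delta + remainder, count


@dataclass
class FractalProfile:
    """Fractal dimension D per spatial scale, averaged over paths."""

    table: pd.DataFrame          # columns: scale, log10_scale, d_mean, d_se, n_paths
    retained_paths: int = 0
    dropped_paths: int = 0

    @property
    def scales(self) -> np.ndarray:
        return self.table["scale"].to_numpy()


def _path_divider_curve(P: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """log10 stepped length at each grid scale; NaN where not measurable."""
    out = np.full(grid.size, np.nan)
    gross = float(np.sum(np.hypot(*np.diff(P, axis=0).T)))
    for k, d in enumerate(grid):
        if gross < d:
            continue
        L, _ = divider_length(P, float(d))
        out[k] = math.log10(L)
    return out


def fractal_profile(paths: Sequence, scale_min: float = 1.0,
                    scale_max: float = 50.0, n_divisions: int = 100,
                    window: float = 0.35,
                    min_gross_length: Optional[float] = None) -> FractalProfile:
    """Mean fractal dimension as a function of spatial scale.

    ``n_divisions`` divider spans are log-spaced on [scale_min,
    scale_max].  For each path, log10 stepped length is regressed on
    log10 span locally, over all grid scales within +-window/2 (log10
    units) of the focal scale; the path's local D is 1 - slope.  Paths
    with gross length below ``min_gross_length`` are dropped, and only
    scales measurable for every retained path enter the profile.
    """
    if not scale_min < scale_max:
        raise ValueError("scale_min must be < scale_max")
    if n_divisions < 10:
        raise ValueError("n_divisions must be >= 10")
    if window <= 0:
        raise ValueError("window must be > 0")
    grid = np.logspace(math.log10(scale_min), math.log10(scale_max), n_divisions)
    lg = np.log10(grid)

    all_xy = [_as_xy(p) for p in paths]
    if min_gross_length is not None:
        keep = [P for P in all_xy
                if float(np.sum(np.hypot(*np.diff(P, axis=0).T))) >= min_gross_length]
    else:
        keep = all_xy
    dropped = len(all_xy) - len(keep)
    if not keep:
        raise ValueError("no path survives the gross-length exclusion")

    curves = np.array([_path_divider_curve(P, grid) for P in keep])
    measurable = np.all(np.isfinite(curves), axis=0)

    rows = []
    for k in range(grid.size):
        if not measurable[k]:
            continue
        sel = measurable & (np.abs(lg - lg[k]) <= window / 2.0)
        if sel.sum() < 3:
            raise ValueError("fewer than 3 grid points in the local window")
        x = lg[sel]
        ds = []
        for c in curves:
            slope = np.polyfit(x, c[sel], 1)[0]
            ds.append(1.0 - slope)
        ds = np.asarray(ds)
        se = float(np.std(ds, ddof=1) / math.sqrt(len(ds))) if len(ds) > 1 else 0.0
        rows.append((float(grid[k]), float(lg[k]), float(np.mean(ds)), se, len(ds)))
    table = pd.DataFrame(rows, columns=["scale", "log10_scale", "d_mean",
                                        "d_se", "n_paths"])
    return FractalProfile(table, retained_paths=len(keep), dropped_paths=dropped)


@dataclass
class ChangepointFit:
    """Two-phase threshold-regression fit of D against log10 scale."""

    kind: str                      # continuous | discontinuous | single_line
    threshold_log10: Optional[float]
    threshold: Optional[float]     # on the meter scale, 10**threshold_log10
    coefficients: dict
    max_lr: float
    p_value: Optional[float]
    r2_by_phase: list
    boot_reps: Optional[int] = None
    seed: Optional[int] = None


def _rss_line(x, y):
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(resid @ resid), coef


def _fit_at_threshold(x, y, e, kind):
    """RSS and coefficients of the two-phase model with threshold e."""
    lo, hi = x <= e, x > e
    if lo.sum() < 3 or hi.sum() < 3:
        return None
    if kind == "continuous":
        X = np.column_stack([np.ones_like(x), x, np.clip(x - e, 0.0, None)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), {"intercept": float(beta[0]),
                                      "slope_low": float(beta[1]),
                                      "slope_high": float(beta[1] + beta[2])}
    if kind == "discontinuous":
        rss = 0.0
        coefs = {}
        for name, sel in (("low", lo), ("high", hi)):
            r, c = _rss_line(x[sel], y[sel])
            rss += r
            coefs[f"intercept_{name}"] = float(c[1])
            coefs[f"slope_{name}"] = float(c[0])
        return rss, coefs
    raise ValueError(f"unknown kind {kind!r}")


def _scan(x, y, kind):
    """Max LR over candidate thresholds (observed x, 10th-90th pct interior)."""
    n = x.size
    rss0, _ = _rss_line(x, y)
    q10, q90 = np.quantile(x, [0.10, 0.90])
    cands = np.unique(x[(x >= q10) & (x <= q90)])
    best = None
    for e in cands:
        res = _fit_at_threshold(x, y, e, kind)
        if res is None:
            continue
        rss1, coefs = res
        lr = n * math.log(rss0 / rss1) if rss1 > 0 else math.inf
        if best is None or lr > best[0]:
            best = (lr, float(e), coefs)
    if best is None:
        raise ValueError("no valid candidate threshold (phases need >= 3 points)")
    return best, rss0


def two_phase_fit(x, y, kind: str = "discontinuous", boot_reps: int = 999,
                  seed: Optional[int] = None) -> ChangepointFit:
    """Threshold regression of y on x with bootstrap-calibrated p-value.

    ``x`` is typically log10 spatial scale and ``y`` the fractal
    dimension.  ``kind='single_line'`` fits the null model only.  For
    the two-phase kinds, max_lr = N*log(RSS0/RSS1) maximized over
    candidate thresholds; the p-value is the parametric bootstrap
    probability of an equal or larger max_lr under the single-line fit
    with Gaussian residuals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 points")
    if kind == "single_line":
        rss0, coef = _rss_line(x, y)
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss0 / tss if tss > 0 else 0.0
        return ChangepointFit("single_line", None, None,
                              {"intercept": float(coef[1]), "slope": float(coef[0])},
                              0.0, None, [r2])
    if boot_reps < 499:
        raise ValueError("boot_reps must be >= 499")
    (max_lr, e, coefs), rss0 = _scan(x, y, kind)

    # per-phase R^2
    r2s = []
    for sel in (x <= e, x > e):
        yy = y[sel]
        rss, _ = _rss_line(x[sel], yy)
        tss = float(np.sum((yy - yy.mean()) ** 2))
        r2s.append(1.0 - rss / tss if tss > 0 else 1.0)

    # parametric bootstrap from the single-line null
    _, coef0 = _rss_line(x, y)
    yhat0 = np.polyval(coef0, x)
    sigma = math.sqrt(rss0 / (x.size - 2))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(boot_reps):
        yb = yhat0 + rng.normal(0.0, sigma, x.size)
        try:
            (lr_b, _, _), _ = _scan(x, yb, kind)
        except ValueError:
            continue
        if lr_b >= max_lr:
            exceed += 1
    p = (1.0 + exceed) / (boot_reps + 1.0)
    return ChangepointFit(kind, float(e), float(10.0 ** e), coefs,
                          float(max_lr), float(p), r2s,
                          boot_reps=boot_reps, seed=seed)
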