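"""Descriptive step statistics: binned step-frequency power fits,
path-length summaries, and tag-load arithmetic."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .track_io import MovementPath, StepSeries, derive_steps

__all__ = [
    "bin_steps",
    "PowerFit",
    "power_fit",
    "path_summaries",
    "tag_load_ratio",
]


def bin_steps(lengths, width: float = 1.0) -> pd.DataFrame:
    """Histogram step lengths into (k-1, k] * width bins.

    Returns a DataFrame with bin_index (1-based), count, and proportion
    for every bin up to the maximum observed length, empty bins
    included.  Proportions sum to 1.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("no step lengths")
    if np.any(lengths <= 0):
        raise ValueError("step lengths must be positive")
    k = np.ceil(lengths / width).astype(int)
    kmax = int(k.max())
    counts = np.bincount(k, minlength=kmax + 1)[1:]
    return pd.DataFrame({
        "bin_index": np.arange(1, kmax + 1),
        "count": counts,
        "proportion": counts / lengths.size,
    })


@dataclass
class PowerFit:
    """Power-law fit proportion = a * k^b on the log-log scale."""

    a: float
    b: float
    r2: float

    def predict(self, k):
        return self.a * np.asarray(k, dtype=float) ** self.b


def power_fit(binned: pd.DataFrame, abscissa: str = "index") -> PowerFit:
    """OLS of log10(proportion) on log10(bin abscissa) over nonzero bins.

    ``abscissa='index'`` regresses on the integer bin index k (the
    bin's upper edge in meters for unit bins); ``'midpoint'`` uses
    k - 0.5.  This mirrors spreadsheet power-trendline behavior.
    """
    nz = binned[binned["count"] > 0] if "count" in binned else binned[binned["proportion"] > 0]
    if len(nz) < 3:
        raise ValueError("need at least 3 nonzero bins")
    k = nz["bin_index"].to_numpy(dtype=float)
    if abscissa == "midpoint":
        k = k - 0.5
    elif abscissa != "index":
        raise ValueError("abscissa must be 'index' or 'midpoint'")
    x = np.log10(k)
    y = np.log10(nz["proportion"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return PowerFit(a=float(10.0 ** intercept), b=float(slope), r2=r2)


def path_summaries(paths: Sequence[MovementPath], min_step: float = 0.0) -> dict:
    """Cohort summaries of step lengths and per-path total lengths.

    SE is the standard error of the mean (SD / sqrt(n)).
    """
    if not paths:
        raise ValueError("no paths")
    series = [p if isinstance(p, StepSeries) else derive_steps(p, min_step)
              for p in paths]
    steps = np.concatenate([s.lengths for s in series if s.n_steps > 0])
    totals = np.array([float(s.lengths.sum()) for s in series])

    def _stats(x):
        n = x.size
        return {
            "n": int(n),
            "mean": float(np.mean(x)),
            "se": float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "median": float(np.median(x)),
        }

    return {"steps": _stats(steps), "path_totals": _stats(totals)}


def tag_load_ratio(tag_mass_mg: float, fly_mass_mg: float) -> float:
    """Tag-to-fly mass ratio as a percentage, rounded half-up to 1 decimal."""
    if tag_mass_mg <= 0 or fly_mass_mg <= 0:
        raise ValueError("masses must be positive")
    pct = Decimal(100 * tag_mass_mg / fly_mass_mg)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
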