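"""Ensemble dispersal simulation and model comparison.

Simulates cohorts of flies under fitted RW/CRW/HMM movement models and
summarizes how far they spread: the maximum distance any fly reaches
from the release origin, and the radii containing 50% and 95% of all
visited positions (nearest-rank percentiles over step endpoints,
origin excluded).  Replicated summaries are compared across models
with one-way ANOVA and Tukey HSD at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .movement_models import simulate_path

__all__ = [
    "Ensemble",
    "DispersalSummary",
    "run_ensemble",
    "dispersal_summary",
    "compare_dispersal",
]


@dataclass
class Ensemble:
    """Simulated cohort: one position array of shape (n_steps+1, 2) per fly."""

    model_tag: str
    n_flies: int
    n_steps: int
    positions: list
    seed: Optional[int] = None

    def to_frame(self, replicate: int = 0) -> pd.DataFrame:
        rows = []
        for fly, P in enumerate(self.positions):
            for step, (x, y) in enumerate(P):
                rows.append((self.model_tag, replicate, fly, step, x, y))
        return pd.DataFrame(rows, columns=["model", "replicate", "fly",
                                           "step", "x", "y"])


@dataclass
class DispersalSummary:
    max_distance: float
    r95: float
    r50: float
    replicate_id: int = 0


def run_ensemble(model, n_flies: int, n_steps: int, seed=None,
                 model_tag: str = "") -> Ensemble:
    """Simulate ``n_flies`` independent paths of ``n_steps`` from the origin.

    Per-fly sub-seeds are spawned from ``seed``, so the ensemble is
    reproducible given (model, seed).
    """
    if n_flies < 1 or n_steps < 1:
        raise ValueError("n_flies and n_steps must be >= 1")
    tag = model_tag or type(model).__name__.replace("Model", "").lower()
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(n_flies)
    positions = []
    for fly, ss in enumerate(children):
        path, _ = simulate_path(model, n_steps, seed=ss, fly_id=f"{tag}{fly}")
        positions.append(path.xy())
    return Ensemble(tag, n_flies, n_steps, positions, seed=seed)


def _nearest_rank(sorted_d: np.ndarray, p: float) -> float:
    n = sorted_d.size
    k = max(int(np.ceil(p * n)), 1)
    return float(sorted_d[k - 1])


def dispersal_summary(ensemble: Ensemble, replicate_id: int = 0) -> DispersalSummary:
    """Max distance from the origin and nearest-rank 95%/50% radii.

    All visited positions (step endpoints) count as "movements"; the
    origin itself is excluded.
    """
    d = np.concatenate([np.hypot(P[1:, 0], P[1:, 1]) for P in ensemble.positions])
    d.sort()
    return DispersalSummary(
        max_distance=float(d[-1]),
        r95=_nearest_rank(d, 0.95),
        r50=_nearest_rank(d, 0.50),
        replicate_id=replicate_id,
    )


def compare_dispersal(models: dict, n_reps: int, n_flies: int, n_steps: int,
                      seed=None) -> dict:
    """Replicate ensembles per model and compare dispersal summaries.

    ``models`` maps a tag to a model object.  Returns the per-replicate
    summary table plus one-way ANOVA and Tukey HSD results for each of
    max_distance, r95, and r50.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if n_reps < 5:
        raise ValueError("n_reps must be >= 5")
    tags = list(models)
    model_seeds = np.random.SeedSequence(seed).spawn(len(tags))
    rows = []
    for m_i, tag in enumerate(tags):
        reps = model_seeds[m_i].spawn(n_reps)
        for r, ss in enumerate(reps):
            ens = run_ensemble(models[tag], n_flies, n_steps, seed=ss,
                               model_tag=tag)
            s = dispersal_summary(ens, replicate_id=r)
            rows.append((tag, r, s.max_distance, s.r95, s.r50))
    table = pd.DataFrame(rows, columns=["model", "replicate",
                                        "max_distance", "r95", "r50"])

    comparisons = {}
    for metric in ("max_distance", "r95", "r50"):
        groups = [table.loc[table["model"] == t, metric].to_numpy() for t in tags]
        F, p = stats.f_oneway(*groups)
        tk = stats.tukey_hsd(*groups)
        pairs = []
        for i in range(len(tags)):
            for j in range(i + 1, len(tags)):
                pairs.append({
                    "pair": (tags[i], tags[j]),
                    "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p": float(tk.pvalue[i, j]),
                    "significant": bool(tk.pvalue[i, j] < 0.05),
                })
        comparisons[metric] = {"anova_F": float(F), "anova_p": float(p),
                               "tukey": pairs}
    return {"summaries": table, "comparisons": comparisons}
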