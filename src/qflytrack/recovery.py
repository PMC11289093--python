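"""Parameter-recovery experiment for the two-state movement HMM.

Simulates a cohort of tracks from the reference two-state model (short
within-tree steps vs longer forward-persistent between-tree steps),
refits the HMM by multi-start maximum likelihood, and reports the
fitted state parameters with states ordered by ascending step mean.
This is the package's primary self-check: the generating parameters
are known exactly, so the fit must give them back up to sampling
error.
"""

from __future__ import annotations

import numpy as np

from .track_io import derive_steps
from .movement_models import fit_hmm, simulate_path
from .synthetic_data import reference_hmm

__all__ = ["simulate_reference_cohort", "recovery_experiment"]


def simulate_reference_cohort(seed, n_paths: int = 30, n_steps: int = 200):
    """Simulate ``n_paths`` tracks of ``n_steps`` from the reference HMM."""
    model = reference_hmm()
    sim_ss, _ = np.random.SeedSequence(seed).spawn(2)
    series = []
    for ss in sim_ss.spawn(n_paths):
        path, _ = simulate_path(model, n_steps, seed=ss)
        series.append(derive_steps(path, min_step=0.0))
    return series


def recovery_experiment(seed, n_paths: int = 30, n_steps: int = 200,
                        n_starts: int = 25) -> dict:
    """Simulate, refit, and report the fitted state parameters.

    Returns a dict with the fitted short-step ("state1") and long-step
    ("state2") gamma means/SDs, von Mises turn means/concentrations,
    the transition matrix, log-likelihood, and the number of steps used.
    """
    _, fit_ss = np.random.SeedSequence(seed).spawn(2)
    series = simulate_reference_cohort(seed, n_paths, n_steps)
    fit = fit_hmm(series, n_states=2, n_starts=n_starts, seed=fit_ss)
    s1, s2 = fit.model.states
    return {
        "state1_step_mean": s1.step_mean,
        "state1_step_sd": s1.step_sd,
        "state1_turn_mean": s1.turn_mean,
        "state1_turn_kappa": s1.turn_kappa,
        "state2_step_mean": s2.step_mean,
        "state2_step_sd": s2.step_sd,
        "state2_turn_mean": s2.turn_mean,
        "state2_turn_kappa": s2.turn_kappa,
        "transition": fit.model.transition.tolist(),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_steps_total": int(sum(s.n_steps for s in series)),
    }
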