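"""Random-walk, correlated-random-walk, and two-state HMM movement models.

All three models share one likelihood structure so their AICs are
directly comparable:

* step lengths are gamma distributed (parameterized by mean and SD;
  shape = mean^2/sd^2, rate = mean/sd^2),
* turning angles are von Mises (CRW, HMM states) or fixed uniform (RW),
* the first step of each path contributes only its length — its
  heading has no preceding heading, so the turning-angle factor is
  absent (not zero) from every likelihood.

The HMM likelihood is the scaled forward algorithm summed over paths;
each path restarts in the stationary distribution of the shared
transition matrix.  Fitting is direct numerical maximization over
unconstrained transforms (log for means/SDs/concentrations, a
sine/cosine pair for mean angles, softmax logits for transition rows)
with multiple random starts to dodge local maxima.  States are always
reported sorted by ascending step mean, so "state 1" is the
short-step/diffuse-turning behavior and "state 2" the long-step/
forward-persistent one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy import optimize, special, stats

from .track_io import MovementPath, ObservedFix, StepSeries, wrap_angle
from .circular_stats import CircSample, mean_direction_and_R, vonmises_kappa

__all__ = [
    "StateParams",
    "HmmModel",
    "CrwModel",
    "RwModel",
    "FitResult",
    "gamma_from_mean_sd",
    "mean_sd_from_gamma",
    "simulate_path",
    "hmm_loglik",
    "fit_hmm",
    "fit_crw",
    "fit_rw",
    "viterbi_states",
]


# ---------------------------------------------------------------- parameters

def gamma_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(shape, rate) of the gamma distribution with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return mean * mean / (sd * sd), mean / (sd * sd)


def mean_sd_from_gamma(shape: float, rate: float) -> tuple[float, float]:
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    return shape / rate, math.sqrt(shape) / rate


@dataclass
class StateParams:
    """Emission parameters of one behavioral state."""

    step_mean: float
    step_sd: float
    turn_mean: float = 0.0
    turn_kappa: float = 0.0

    def __post_init__(self):
        if self.step_mean <= 0 or self.step_sd <= 0:
            raise ValueError("step_mean and step_sd must be positive")
        if self.turn_kappa < 0:
            raise ValueError("turn_kappa must be >= 0")
        self.turn_mean = float(wrap_angle(self.turn_mean))

    def gamma_params(self) -> tuple[float, float]:
        return gamma_from_mean_sd(self.step_mean, self.step_sd)


@dataclass
class HmmModel:
    """Two (or more) state hidden Markov movement model."""

    states: list[StateParams]
    transition: np.ndarray
    initial: Optional[np.ndarray] = None  # None -> stationary distribution

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        S = len(self.states)
        if self.transition.shape != (S, S):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if self.initial is not None:
            self.initial = np.asarray(self.initial, dtype=float)
            if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-10):
                raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        S = self.n_states
        A = np.vstack([self.transition.T - np.eye(S), np.ones(S)])
        b = np.zeros(S + 1)
        b[-1] = 1.0
        d, *_ = np.linalg.lstsq(A, b, rcond=None)
        d = np.clip(d, 0.0, None)
        return d / d.sum()

    def start_distribution(self) -> np.ndarray:
        return self.initial if self.initial is not None else self.stationary()

    def to_dict(self) -> dict:
        return {
            "type": "hmm",
            "states": [asdict(s) for s in self.states],
            "transition": self.transition.tolist(),
            "initial": None if self.initial is None else self.initial.tolist(),
        }


@dataclass
class CrwModel:
    """Correlated random walk: gamma steps, von Mises turning angles."""

    step_mean: float
    step_sd: float
    turn_mean: float = 0.0
    turn_kappa: float = 0.0

    def __post_init__(self):
        if self.step_mean <= 0 or self.step_sd <= 0:
            raise ValueError("step_mean and step_sd must be positive")
        if self.turn_kappa < 0:
            raise ValueError("turn_kappa must be >= 0")
        self.turn_mean = float(wrap_angle(self.turn_mean))

    def to_dict(self) -> dict:
        return {"type": "crw", **asdict(self)}


@dataclass
class RwModel:
    """Simple (Brownian-like) random walk: gamma steps, uniform turning."""

    step_mean: float
    step_sd: float

    def __post_init__(self):
        if self.step_mean <= 0 or self.step_sd <= 0:
            raise ValueError("step_mean and step_sd must be positive")

    def to_dict(self) -> dict:
        return {"type": "rw", **asdict(self)}


def model_from_dict(d: dict):
    t = d.get("type")
    if t == "hmm":
        return HmmModel(
            [StateParams(**s) for s in d["states"]],
            np.asarray(d["transition"], dtype=float),
            None if d.get("initial") is None else np.asarray(d["initial"], dtype=float),
        )
    if t == "crw":
        return CrwModel(d["step_mean"], d["step_sd"], d["turn_mean"], d["turn_kappa"])
    if t == "rw":
        return RwModel(d["step_mean"], d["step_sd"])
    raise ValueError(f"unknown model type {t!r}")


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood model fit."""

    model: object
    model_type: str
    loglik: float
    n_params: int
    n_starts: int
    converged: bool
    state_order: str = "ascending_step_mean"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


# ---------------------------------------------------------------- densities

_LOG_2PI = math.log(2.0 * math.pi)


def _gamma_logpdf(x: np.ndarray, shape: float, rate: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return ((shape - 1.0) * np.log(x) - rate * x
            + shape * math.log(rate) - special.gammaln(shape))


def _vonmises_logpdf(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    return kappa * np.cos(theta - mu) - _LOG_2PI - np.log(special.i0e(kappa)) - kappa


# ---------------------------------------------------------------- simulation

def _draw_gamma(rng, mean, sd, size=None):
    shape, rate = gamma_from_mean_sd(mean, sd)
    return rng.gamma(shape, 1.0 / rate, size=size)


def _draw_turn(rng, mu: float, kappa: float) -> float:
    if math.isinf(kappa):
        return mu  # degenerate limit: deterministic turning
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi)
    return rng.vonmises(mu, kappa)


def simulate_path(model, n_steps: int, origin=(0.0, 0.0), seed=None,
                  fly_id: str = "sim", dt_h: float = 0.1):
    """Simulate one movement path.

    The initial heading is uniform on the circle; each subsequent
    heading is the previous one plus a turning angle drawn from the
    model (uniform for RW, von Mises otherwise; for the HMM the state
    first evolves along its Markov chain).  Step lengths are gamma.

    Returns ``(MovementPath, states)``, where ``states`` is the
    generating state sequence for an HMM and ``None`` otherwise.
    ``dt_h`` is the elapsed time per step, in hours.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    heading = rng.uniform(-np.pi, np.pi)
    x, y = float(origin[0]), float(origin[1])
    fixes = [ObservedFix(fly_id, 0, 0.0, x, y)]
    states = None

    if isinstance(model, HmmModel):
        delta = model.start_distribution()
        S = model.n_states
        states = np.empty(n_steps, dtype=np.int64)
        state = rng.choice(S, p=delta)
        for t in range(n_steps):
            if t > 0:
                state = rng.choice(S, p=model.transition[state])
                sp = model.states[state]
                heading = wrap_angle(heading + _draw_turn(rng, sp.turn_mean,
                                                          sp.turn_kappa))
            states[t] = state
            sp = model.states[state]
            L = _draw_gamma(rng, sp.step_mean, sp.step_sd)
            x += L * math.cos(heading)
            y += L * math.sin(heading)
            fixes.append(ObservedFix(fly_id, t + 1, (t + 1) * dt_h, x, y))
    else:
        for t in range(n_steps):
            if t > 0:
                if isinstance(model, RwModel):
                    turn = rng.uniform(-np.pi, np.pi)
                else:
                    turn = _draw_turn(rng, model.turn_mean, model.turn_kappa)
                heading = wrap_angle(heading + turn)
            L = _draw_gamma(rng, model.step_mean, model.step_sd)
            x += L * math.cos(heading)
            y += L * math.sin(heading)
            fixes.append(ObservedFix(fly_id, t + 1, (t + 1) * dt_h, x, y))

    return MovementPath(fly_id, fixes), states


# ---------------------------------------------------------------- likelihood

@njit(cache=True)
def _forward_ll(logB, offsets, Gamma, delta):
    """Scaled forward log-likelihood over concatenated paths."""
    S = logB.shape[1]
    ll = 0.0
    alpha = np.empty(S)
    tmp = np.empty(S)
    for p in range(offsets.shape[0] - 1):
        s, e = offsets[p], offsets[p + 1]
        if e <= s:
            continue
        m = logB[s, 0]
        for k in range(1, S):
            if logB[s, k] > m:
                m = logB[s, k]
        c = 0.0
        for k in range(S):
            alpha[k] = delta[k] * math.exp(logB[s, k] - m)
            c += alpha[k]
        if c <= 0.0 or not math.isfinite(c):
            return -np.inf
        ll += m + math.log(c)
        for k in range(S):
            alpha[k] /= c
        for t in range(s + 1, e):
            m = logB[t, 0]
            for k in range(1, S):
                if logB[t, k] > m:
                    m = logB[t, k]
            c = 0.0
            for k in range(S):
                acc = 0.0
                for j in range(S):
                    acc += alpha[j] * Gamma[j, k]
                tmp[k] = acc * math.exp(logB[t, k] - m)
                c += tmp[k]
            if c <= 0.0 or not math.isfinite(c):
                return -np.inf
            ll += m + math.log(c)
            for k in range(S):
                alpha[k] = tmp[k] / c
    return ll


def _concat_series(series: Sequence[StepSeries]):
    """Concatenate step series into flat arrays; NaN marks absent turnings."""
    lengths, turns, offsets = [], [], [0]
    for s in series:
        n = s.n_steps
        if n == 0:
            offsets.append(offsets[-1])
            continue
        if np.any(s.lengths <= 0):
            raise ValueError(
                "zero-length step in series: filter with derive_steps(min_step=...)"
            )
        lengths.append(s.lengths)
        t = np.full(n, np.nan)
        t[1:] = s.turning_angles
        turns.append(t)
        offsets.append(offsets[-1] + n)
    if not lengths:
        raise ValueError("no steps in any series")
    return (np.concatenate(lengths), np.concatenate(turns),
            np.asarray(offsets, dtype=np.int64))


def _log_emissions(lengths, turns, states: Sequence[StateParams]) -> np.ndarray:
    T = lengths.shape[0]
    S = len(states)
    logB = np.empty((T, S))
    has_turn = ~np.isnan(turns)
    for k, sp in enumerate(states):
        shape, rate = sp.gamma_params()
        logB[:, k] = _gamma_logpdf(lengths, shape, rate)
        logB[has_turn, k] += _vonmises_logpdf(turns[has_turn], sp.turn_mean,
                                              sp.turn_kappa)
    return logB


def hmm_loglik(model: HmmModel, series: Sequence[StepSeries]) -> float:
    """Forward-algorithm log-likelihood of the step series under the HMM.

    Per step the emission density is gamma(length) x von Mises(turning);
    the turning factor is omitted for each path's first step.  Each path
    is initialized at the model's start distribution.
    """
    lengths, turns, offsets = _concat_series(series)
    logB = _log_emissions(lengths, turns, model.states)
    if not np.all(np.isfinite(logB)):
        raise ValueError(
            "non-finite emission density (zero step length with shape < 1?); "
            "filter steps with derive_steps(min_step=...)"
        )
    delta = model.start_distribution()
    return float(_forward_ll(logB, offsets, model.transition, delta))


# ---------------------------------------------------------------- HMM fitting

def _pack_dim(S: int) -> int:
    return 5 * S + S * (S - 1)


def _unpack(x: np.ndarray, S: int):
    """Unconstrained vector -> (states, Gamma)."""
    states = []
    for k in range(S):
        lm, ls, lk, ts, tc = x[5 * k: 5 * k + 5]
        states.append(StateParams(
            step_mean=math.exp(lm), step_sd=math.exp(ls),
            turn_mean=math.atan2(ts, tc), turn_kappa=math.exp(lk),
        ))
    Gamma = np.empty((S, S))
    z = x[5 * S:]
    pos = 0
    for i in range(S):
        logits = np.zeros(S)
        for j in range(S):
            if j != i:
                logits[j] = z[pos]
                pos += 1
        e = np.exp(logits - logits.max())
        Gamma[i] = e / e.sum()
    return states, Gamma


def _pack(states: Sequence[StateParams], Gamma: np.ndarray) -> np.ndarray:
    S = len(states)
    x = np.empty(_pack_dim(S))
    for k, sp in enumerate(states):
        kap = max(sp.turn_kappa, 1e-6)
        x[5 * k: 5 * k + 5] = (
            math.log(sp.step_mean), math.log(sp.step_sd), math.log(kap),
            math.sin(sp.turn_mean), math.cos(sp.turn_mean),
        )
    z = []
    for i in range(S):
        di = max(Gamma[i, i], 1e-6)
        for j in range(S):
            if j != i:
                z.append(math.log(max(Gamma[i, j], 1e-6) / di))
    x[5 * S:] = z
    return x


def _stationary_of(Gamma: np.ndarray) -> np.ndarray:
    S = Gamma.shape[0]
    A = np.vstack([Gamma.T - np.eye(S), np.ones(S)])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    d, *_ = np.linalg.lstsq(A, b, rcond=None)
    d = np.clip(d, 0.0, None)
    return d / d.sum()


def _moment_start(lengths, turns, S):
    """Split pooled step lengths at quantiles to seed state moments."""
    qs = np.quantile(lengths, np.linspace(0, 1, S + 1))
    states = []
    t_ok = turns[~np.isnan(turns)]
    if t_ok.size >= 2:
        mu_t, _ = mean_direction_and_R(CircSample(t_ok))
        kap_t = vonmises_kappa(CircSample(t_ok))
        if not np.isfinite(mu_t):
            mu_t = 0.0
    else:
        mu_t, kap_t = 0.0, 0.5
    kap_t = min(max(kap_t, 0.05), 10.0)
    for k in range(S):
        sel = (lengths >= qs[k]) & (lengths <= qs[k + 1])
        xs = lengths[sel]
        m = float(np.mean(xs)) if xs.size else float(np.mean(lengths))
        sd = float(np.std(xs)) if xs.size > 1 else m
        states.append(StateParams(max(m, 1e-3), max(sd, 1e-3), mu_t, kap_t))
    Gamma = np.full((S, S), 0.2 / max(S - 1, 1))
    np.fill_diagonal(Gamma, 0.8)
    return states, Gamma


def fit_hmm(series: Sequence[StepSeries], n_states: int = 2,
            n_starts: int = 25, seed=None, tol: float = 1e-8,
            max_iter: int = 500, init: Optional[HmmModel] = None) -> FitResult:
    """Fit an HMM by direct maximization of the forward log-likelihood.

    ``n_starts`` initializations are drawn by perturbing data-moment
    seeds (the first start is unperturbed); the best converged
    likelihood is kept.  ``init`` replaces the unperturbed first start
    with a user-supplied model.  States are reported sorted by ascending
    step mean and the initial distribution is set to the stationary
    distribution of the fitted transition matrix.
    """
    lengths, turns, offsets = _concat_series(series)
    S = int(n_states)
    n_params = 4 * S + S * (S - 1)
    if lengths.size < 10 * n_params:
        warnings.warn(
            f"only {lengths.size} steps for {n_params} parameters; "
            "estimates may be unstable", RuntimeWarning)
    rng = np.random.default_rng(seed)

    def neg_ll(x):
        try:
            states, Gamma = _unpack(x, S)
        except ValueError:
            return np.inf
        logB = _log_emissions(lengths, turns, states)
        if not np.all(np.isfinite(logB)):
            return np.inf
        ll = _forward_ll(logB, offsets, Gamma, _stationary_of(Gamma))
        return np.inf if not np.isfinite(ll) else -ll

    if init is not None:
        base_states, base_Gamma = init.states, init.transition
    else:
        base_states, base_Gamma = _moment_start(lengths, turns, S)
    x_base = _pack(base_states, base_Gamma)
    bounds = ([(-8, 8)] * (5 * S)) + ([(-12, 12)] * (S * (S - 1)))

    best = None
    any_converged = False
    for i in range(max(n_starts, 1)):
        x0 = x_base.copy()
        if i > 0:
            x0[: 5 * S] += rng.normal(0.0, 0.6, 5 * S)
            x0[5 * S:] += rng.normal(0.0, 1.0, S * (S - 1))
        res = optimize.minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol * 1e-2, "gtol": 1e-7, "maxiter": max_iter},
        )
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all HMM starts failed to produce a finite likelihood")
    if not any_converged:
        raise RuntimeError("no HMM start converged; try more starts or more data")

    states, Gamma = _unpack(best.x, S)
    order = np.argsort([sp.step_mean for sp in states])
    states = [states[k] for k in order]
    Gamma = Gamma[np.ix_(order, order)]
    model = HmmModel(states, Gamma, initial=None)
    return FitResult(model=model, model_type="hmm", loglik=float(-best.fun),
                     n_params=n_params, n_starts=n_starts, converged=True)


# ------------------------------------------------------- RW / CRW fitting

def _pooled_lengths_turns(series):
    lengths, turns, _ = _concat_series(series)
    return lengths, turns[~np.isnan(turns)]


def _fit_gamma_ml(lengths: np.ndarray) -> tuple[float, float]:
    if np.var(lengths) <= 0:
        raise ValueError("degenerate gamma ML: all step lengths equal")
    shape, _, scale = stats.gamma.fit(lengths, floc=0)
    return float(shape), float(1.0 / scale)


def fit_crw(series: Sequence[StepSeries]) -> FitResult:
    """ML correlated-random-walk fit on pooled lengths and turning angles."""
    lengths, turns = _pooled_lengths_turns(series)
    if lengths.size < 2:
        raise ValueError("need at least 2 steps")
    shape, rate = _fit_gamma_ml(lengths)
    mean, sd = mean_sd_from_gamma(shape, rate)
    if turns.size >= 2:
        mu, _ = mean_direction_and_R(CircSample(turns))
        kappa = vonmises_kappa(CircSample(turns))
        if not np.isfinite(mu):
            mu = 0.0
    else:
        mu, kappa = 0.0, 0.0
    model = CrwModel(mean, sd, mu, kappa)
    ll = float(np.sum(_gamma_logpdf(lengths, shape, rate))
               + np.sum(_vonmises_logpdf(turns, mu, kappa)))
    return FitResult(model=model, model_type="crw", loglik=ll,
                     n_params=4, n_starts=1, converged=True)


def fit_rw(series: Sequence[StepSeries]) -> FitResult:
    """ML simple-random-walk fit; turning angles fixed uniform (not estimated)."""
    lengths, turns = _pooled_lengths_turns(series)
    if lengths.size < 2:
        raise ValueError("need at least 2 steps")
    shape, rate = _fit_gamma_ml(lengths)
    mean, sd = mean_sd_from_gamma(shape, rate)
    model = RwModel(mean, sd)
    ll = float(np.sum(_gamma_logpdf(lengths, shape, rate))
               - turns.size * _LOG_2PI)
    return FitResult(model=model, model_type="rw", loglik=ll,
                     n_params=2, n_starts=1, converged=True)


# ---------------------------------------------------------------- decoding

def viterbi_states(model: HmmModel, series: StepSeries) -> np.ndarray:
    """Most probable state sequence; ties resolved toward the lower index."""
    if series.n_steps == 0:
        raise ValueError("empty step series")
    lengths, turns, _ = _concat_series([series])
    logB = _log_emissions(lengths, turns, model.states)
    S = model.n_states
    T = lengths.size
    logG = np.log(np.clip(model.transition, 1e-300, None))
    delta = np.log(np.clip(model.start_distribution(), 1e-300, None)) + logB[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logG
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(S)] + logB[t]
    out = np.empty(T, dtype=np.int64)
    out[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        out[t - 1] = back[t, out[t]]
    return out
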