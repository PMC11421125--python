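"""Two-state hidden Markov model for step length and turning angle.

Step lengths follow a zero-inflated gamma: an atom of probability
``zero_mass`` at exactly 0 m (GPS fixes at the same position) mixed with a
gamma density for positive lengths. Turning angles follow a von Mises
distribution. The two latent states are the classic ungulate movement modes:
*restricted* (short, tortuous steps — foraging/ruminating) and *exploratory*
(long, directed steps — relocation). The model is fitted by direct numerical
maximization of the scaled forward log-likelihood, pooled over all contiguous
track segments, and decoded with the Viterbi algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, i0e, logit, expit

__all__ = [
    "StateParameters",
    "HMMFit",
    "steplen_density",
    "turn_density",
    "forward_loglik",
    "fit_hmm",
    "viterbi",
    "stationary_distribution",
    "DEFAULT_INITIAL_STATES",
]

STATE_NAMES = ("restricted", "exploratory")


def wrap_angle(phi):
    """Wrap angle(s) to (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2 * np.pi)
    return -(out - np.pi)


@dataclass
class StateParameters:
    """Emission parameters of one behavioral state.

    mean, sd
        Mean and standard deviation of the gamma step-length distribution, m.
    zero_mass
        Probability of a step of exactly 0 m.
    vm_mean, vm_conc
        Mean (radians, in (-pi, pi]) and concentration of the von Mises
        turning-angle distribution.
    """

    mean: float
    sd: float
    zero_mass: float = 0.0
    vm_mean: float = 0.0
    vm_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("gamma mean and sd must be positive")
        if not 0 <= self.zero_mass < 1:
            raise ValueError("zero_mass must be in [0, 1)")
        if self.vm_conc < 0:
            raise ValueError("vm_conc must be >= 0")
        self.vm_mean = wrap_angle(self.vm_mean)

    @property
    def shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def scale(self) -> float:
        return self.sd**2 / self.mean

    def to_dict(self) -> dict:
        return {
            "mean": float(self.mean),
            "sd": float(self.sd),
            "zero_mass": float(self.zero_mass),
            "vm_mean": float(self.vm_mean),
            "vm_conc": float(self.vm_conc),
        }


# Initial values for the two-state fit: restricted state centered at a
# 100 m mean step with near-uniform turning angles around pi (reversals),
# exploratory state at 450 m with concentrated forward persistence.
DEFAULT_INITIAL_STATES = (
    StateParameters(mean=100.0, sd=100.0, zero_mass=0.001, vm_mean=np.pi, vm_conc=0.001),
    StateParameters(mean=450.0, sd=450.0, zero_mass=0.001, vm_mean=0.1, vm_conc=0.99),
)
DEFAULT_INITIAL_GAMMA = np.array([[0.9, 0.1], [0.1, 0.9]])


@dataclass
class HMMFit:
    states: tuple[StateParameters, StateParameters]
    Gamma: np.ndarray  # 2x2 transition probabilities
    delta: np.ndarray  # initial (stationary) distribution
    loglik: float
    converged: bool
    decoded: np.ndarray | None = None
    n_steps: int = 0
    message: str = ""
    state_names: tuple[str, str] = field(default=STATE_NAMES)

    def to_dict(self) -> dict:
        return {
            "states": {
                name: sp.to_dict() for name, sp in zip(self.state_names, self.states)
            },
            "transition_matrix": np.asarray(self.Gamma).tolist(),
            "delta": np.asarray(self.delta).tolist(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_steps": int(self.n_steps),
            "message": self.message,
        }


def steplen_density(l, state: StateParameters):
    """Zero-inflated gamma step-length density/mass.

    Returns ``zero_mass`` at l == 0 (a probability mass, not a density) and
    ``(1 - zero_mass) * gamma_pdf(l)`` for l > 0.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("step lengths must be >= 0")
    return np.exp(log_steplen_density(l, state))


def log_steplen_density(l, state: StateParameters):
    l = np.asarray(l, dtype=float)
    a, s = state.shape, state.scale
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = (a - 1) * np.log(l) - l / s - a * np.log(s) - gammaln(a)
        logpdf = logpdf + np.log1p(-state.zero_mass)
    if state.zero_mass > 0:
        logpdf = np.where(l == 0, np.log(state.zero_mass), logpdf)
    else:
        logpdf = np.where(l == 0, -np.inf, logpdf)
    return logpdf


def turn_density(phi, state: StateParameters):
    """von Mises turning-angle density exp(k cos(phi - mu)) / (2 pi I0(k))."""
    return np.exp(log_turn_density(phi, state))


def log_turn_density(phi, state: StateParameters):
    phi = np.asarray(phi, dtype=float)
    kappa = state.vm_conc
    # i0e(k) = I0(k) exp(-k) keeps this stable for large concentrations
    return kappa * (np.cos(phi - state.vm_mean) - 1.0) - np.log(2 * np.pi * i0e(kappa))


def _log_emissions(l, phi, states) -> np.ndarray:
    """(T, 2) log emission matrix; undefined angles contribute length only."""
    l = np.asarray(l, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty((l.size, len(states)))
    defined = np.isfinite(phi)
    for j, sp in enumerate(states):
        out[:, j] = log_steplen_density(l, sp)
        out[defined, j] += log_turn_density(phi[defined], sp)
    return out


def _check_gamma(Gamma) -> np.ndarray:
    Gamma = np.asarray(Gamma, dtype=float)
    if Gamma.shape != (2, 2) or np.any(Gamma < 0):
        raise ValueError("Gamma must be a non-negative 2x2 matrix")
    if not np.allclose(Gamma.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition-matrix rows must sum to 1")
    return Gamma


def stationary_distribution(Gamma) -> np.ndarray:
    """Stationary distribution of a 2x2 stochastic matrix."""
    Gamma = _check_gamma(Gamma)
    g12, g21 = Gamma[0, 1], Gamma[1, 0]
    if g12 + g21 == 0:  # identity chain: uniform by convention
        return np.array([0.5, 0.5])
    return np.array([g21, g12]) / (g12 + g21)


def forward_loglik(l, phi, states, Gamma, delta) -> float:
    """Scaled forward-recursion log-likelihood of one contiguous track."""
    Gamma = _check_gamma(Gamma)
    delta = np.asarray(delta, dtype=float)
    logB = _log_emissions(l, phi, states)
    # scale each column of emissions to avoid under/overflow
    c = logB.max(axis=1)
    c = np.where(np.isfinite(c), c, 0.0)
    B = np.exp(logB - c[:, None])
    alpha = delta * B[0]
    ll = c[0]
    norm = alpha.sum()
    if norm <= 0:
        return -np.inf
    ll += np.log(norm)
    alpha /= norm
    for t in range(1, logB.shape[0]):
        alpha = (alpha @ Gamma) * B[t]
        norm = alpha.sum()
        if norm <= 0:
            return -np.inf
        ll += np.log(norm) + c[t]
        alpha /= norm
    return float(ll)


def _pooled_loglik(segments, states, Gamma, delta) -> float:
    return sum(forward_loglik(l, phi, states, Gamma, delta) for l, phi in segments)


# -- working-scale parameter vector --------------------------------------
# per state: [log mean, log sd, logit zero_mass, vm_mean, log vm_conc]
# then: [logit g12, logit g21]


def _pack(states, Gamma) -> np.ndarray:
    theta = []
    for sp in states:
        theta += [
            np.log(sp.mean),
            np.log(sp.sd),
            logit(np.clip(sp.zero_mass, 1e-12, 1 - 1e-12)),
            sp.vm_mean,
            np.log(max(sp.vm_conc, 1e-10)),
        ]
    theta += [logit(Gamma[0, 1]), logit(Gamma[1, 0])]
    return np.asarray(theta, dtype=float)


def _unpack(theta):
    states = []
    for j in range(2):
        m, s, z, mu, k = theta[5 * j : 5 * j + 5]
        states.append(
            StateParameters(
                mean=np.exp(m),
                sd=np.exp(s),
                zero_mass=float(expit(z)),
                vm_mean=float(wrap_angle(mu)),
                vm_conc=float(np.exp(k)),
            )
        )
    g12, g21 = expit(theta[10]), expit(theta[11])
    Gamma = np.array([[1 - g12, g12], [g21, 1 - g21]])
    return tuple(states), Gamma


def _segments_from_steps(steps: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    if "seg_id" in steps.columns:
        groups = [g for _, g in steps.groupby("seg_id", sort=False)]
    else:
        groups = [steps]
    return [
        (g["l"].to_numpy(dtype=float), g["phi"].to_numpy(dtype=float)) for g in groups
    ]


def fit_hmm(
    steps: pd.DataFrame,
    initial_states=DEFAULT_INITIAL_STATES,
    initial_gamma=DEFAULT_INITIAL_GAMMA,
    max_iter: int = 500,
    tol: float = 1e-8,
    decode: bool = True,
) -> HMMFit:
    """Fit the two-state HMM by maximizing the pooled forward log-likelihood.

    `steps` needs columns ``l`` (meters) and ``phi`` (radians, NaN where the
    turning angle is undefined), plus optionally ``seg_id`` marking contiguous
    track segments that each restart the forward recursion. All segments share
    one parameter set. The initial state distribution is tied to the
    stationary distribution of the transition matrix. After fitting, states
    are relabeled in ascending order of gamma mean so that index 0 is the
    restricted state.
    """
    segments = _segments_from_steps(steps)
    n_steps = sum(len(l) for l, _ in segments)
    if n_steps < 10:
        raise ValueError("too few steps to fit an HMM")

    theta0 = _pack(initial_states, np.asarray(initial_gamma, dtype=float))

    def nll(theta):
        try:
            states, Gamma = _unpack(theta)
        except (ValueError, FloatingPointError):
            return 1e12
        delta = stationary_distribution(Gamma)
        ll = _pooled_loglik(segments, states, Gamma, delta)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    ll0 = -nll(theta0)
    res = minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "maxfun": 20000},
    )
    states, Gamma = _unpack(res.x)
    # relabel by ascending gamma mean: index 0 = restricted
    order = np.argsort([sp.mean for sp in states])
    states = tuple(states[j] for j in order)
    Gamma = Gamma[np.ix_(order, order)]
    delta = stationary_distribution(Gamma)
    loglik = _pooled_loglik(segments, states, Gamma, delta)
    if loglik < ll0 - 1e-6:
        warnings.warn("optimizer did not improve on the initial values")
    if abs(states[0].mean - states[1].mean) < 0.01 * states[1].mean:
        warnings.warn("degenerate fit: the two state means collapsed")

    fit = HMMFit(
        states=states,
        Gamma=Gamma,
        delta=delta,
        loglik=float(loglik),
        converged=bool(res.success),
        n_steps=n_steps,
        message=str(res.message),
    )
    if decode:
        fit.decoded = viterbi(steps, fit)
    return fit


def _viterbi_one(l, phi, states, Gamma, delta) -> np.ndarray:
    logB = _log_emissions(l, phi, states)
    with np.errstate(divide="ignore"):
        logG = np.log(np.asarray(Gamma, dtype=float))
        logd = np.log(np.asarray(delta, dtype=float))
    T = logB.shape[0]
    v = logd + logB[0]
    back = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        cand = v[:, None] + logG  # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)  # ties -> lower (restricted) index
        v = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(v))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi(steps: pd.DataFrame, fit: HMMFit) -> np.ndarray:
    """Most probable state sequence (0 = restricted, 1 = exploratory).

    Decodes each contiguous segment independently; ties in the dynamic
    program break toward the restricted state.
    """
    segments = _segments_from_steps(steps)
    paths = [
        _viterbi_one(l, phi, fit.states, fit.Gamma, fit.delta) for l, phi in segments
    ]
    return np.concatenate(paths) if paths else np.empty(0, dtype=int)
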