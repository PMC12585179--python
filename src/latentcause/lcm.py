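"""The latent cause model: generative assumptions and trial-by-trial inference.

An agent experiencing a sequence of trials assumes each observation — a
stimulus vector ``x`` (tone/CS and context salience) together with a shock
outcome ``r`` — is generated by one of a growing set of latent causes.  The
prior over causes follows a Chinese restaurant process whose seating counts
are discounted by a power-law temporal kernel ``(Δτ)^-g``; the concentration
parameter ``α`` governs how readily a new cause is inferred.  Each cause k
carries Gaussian stimulus likelihoods (empirical per-dimension means, fixed
variance ``σx²``), and predicts the shock linearly through an associative
weight vector ``w_k`` (fixed outcome variance ``σr²``).

Within a trial the agent alternates a Bayesian E-step (posterior over causes
given the prior and likelihoods) with a posterior-weighted Rescorla–Wagner
M-step on the weights, a fixed number of times.  The conditioned response is
the probability that a Gaussian centred on the expected shock (variance λ)
exceeds a threshold θ.  Everything here is deterministic: simulating the
same schedule under the same parameters is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .paradigm import CRTrace, TrialSchedule

__all__ = [
    "PARAM_NAMES",
    "INTEGER_PARAMS",
    "ParamSet",
    "ModelState",
    "SimulationResult",
    "temporal_kernel",
    "cause_prior",
    "feature_likelihood",
    "outcome_likelihood",
    "e_step",
    "predict_outcome",
    "m_step",
    "emit_cr",
    "simulate_trial",
    "simulate_paradigm",
]

#: Canonical parameter order used throughout (vectors, CSV columns, sampling).
PARAM_NAMES = (
    "alpha",
    "g",
    "eta",
    "max_em_iter",
    "w0",
    "sigma_r2",
    "sigma_x2",
    "theta",
    "lam",
    "K",
)

#: Names of the integer-valued parameters (continuously relaxed during MCMC).
INTEGER_PARAMS = ("max_em_iter", "K")

_D = 2  # stimulus dimensionality: (CS, context)


@dataclass(frozen=True)
class ParamSet:
    """The ten latent-cause-model parameters of one agent.

    alpha : CRP concentration (> 0); higher values favour new causes.
    g : temporal scaling of the power-law kernel (>= 0); 0 disables decay.
    eta : Rescorla–Wagner learning rate in (0, 1].
    max_em_iter : number of E/M iterations per trial (positive integer).
    w0 : initial associative weight of a freshly inferred cause.
    sigma_r2 : outcome (shock) variance (> 0).
    sigma_x2 : stimulus variance (> 0).
    theta : response threshold on the expected shock.
    lam : response variance of the CR emission Gaussian (> 0).
    K : maximum number of latent causes (positive integer).
    """

    alpha: float
    g: float
    eta: float
    max_em_iter: int
    w0: float
    sigma_r2: float
    sigma_x2: float
    theta: float
    lam: float
    K: int

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must lie in (0, 1]")
        if int(self.max_em_iter) != self.max_em_iter or self.max_em_iter < 1:
            raise ValueError("max_em_iter must be a positive integer")
        if not self.sigma_r2 > 0 or not self.sigma_x2 > 0:
            raise ValueError("sigma_r2 and sigma_x2 must be positive")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if int(self.K) != self.K or self.K < 1:
            raise ValueError("K must be a positive integer")
        object.__setattr__(self, "max_em_iter", int(self.max_em_iter))
        object.__setattr__(self, "K", int(self.K))

    def to_vector(self) -> np.ndarray:
        """Parameters as a float vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "ParamSet":
        """Build from a vector in :data:`PARAM_NAMES` order.

        Integer parameters are rounded toward infinity (ceiling), matching
        how the continuous MCMC relaxation is mapped back to integers.
        """
        kw = dict(zip(PARAM_NAMES, map(float, vec)))
        for name in INTEGER_PARAMS:
            kw[name] = int(math.ceil(kw[name] - 1e-12))
        return cls(**kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        return cls(**{n: d[n] for n in PARAM_NAMES})


@dataclass
class ModelState:
    """Mutable inference state of one agent while folding over trials.

    Cause indices are 0-based internally; the paper's z_1 is cause 0.
    """

    K: int
    n_active: int = 0
    assignments: list = field(default_factory=list)  # MAP cause per past trial
    assign_times: list = field(default_factory=list)  # τ of past trials
    feature_sums: np.ndarray = None  # (K, 2) per-cause stimulus sums
    feature_counts: np.ndarray = None  # (K,) trials assigned per cause
    weights: np.ndarray = None  # (K, 2) associative weights

    def __post_init__(self) -> None:
        if self.feature_sums is None:
            self.feature_sums = np.zeros((self.K, _D))
        if self.feature_counts is None:
            self.feature_counts = np.zeros(self.K, dtype=int)
        if self.weights is None:
            self.weights = np.zeros((self.K, _D))


def temporal_kernel(delta: float, g: float):
    """Power-law temporal kernel (Δτ)^-g.

    Down-weights the CRP seating count of a past trial by the elapsed model
    time; with g = 0 every past trial counts fully (classic CRP).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("time difference must be positive")
    if g < 0:
        raise ValueError("g must be non-negative")
    out = delta ** (-g)
    return float(out) if out.ndim == 0 else out


def cause_prior(state: ModelState, t_now: float, params: ParamSet) -> np.ndarray:
    """Time-sensitive CRP prior over causes at time ``t_now``.

    Existing cause k receives the kernel-weighted count of past trials
    assigned to it; a new-cause slot with mass α is appended while fewer
    than K causes exist.  Returned vector is normalized to sum 1.
    """
    if state.assign_times and t_now <= max(state.assign_times):
        raise ValueError("t_now must exceed all past trial times")
    has_new = state.n_active < params.K
    mass = np.zeros(state.n_active + (1 if has_new else 0))
    for z, tau in zip(state.assignments, state.assign_times):
        mass[z] += temporal_kernel(t_now - tau, params.g)
    if has_new:
        mass[-1] = params.alpha
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate prior: no mass on any cause")
    return mass / total


def feature_likelihood(
    x: np.ndarray, state: ModelState, params: ParamSet, include_new: bool | None = None
) -> np.ndarray:
    """Gaussian stimulus likelihood of ``x`` under each cause.

    For cause k the per-dimension mean is the empirical mean of the stimuli
    of trials assigned to it; the variance σx² is fixed a priori.  The
    new-cause slot (appended while fewer than K causes exist) uses mean 0
    in every dimension, as no observation has been generated by it yet.
    """
    x = np.asarray(x, dtype=float)
    if include_new is None:
        include_new = state.n_active < params.K
    n = state.n_active + (1 if include_new else 0)
    means = np.zeros((n, _D))
    if state.n_active:
        counts = state.feature_counts[: state.n_active, None]
        with np.errstate(invalid="ignore"):
            means[: state.n_active] = np.where(
                counts > 0, state.feature_sums[: state.n_active] / counts, 0.0
            )
    var = params.sigma_x2
    dens = np.exp(-((x[None, :] - means) ** 2) / (2 * var)) / math.sqrt(
        2 * math.pi * var
    )
    return dens.prod(axis=1)


def outcome_likelihood(r: float, x: np.ndarray, w, params: ParamSet):
    """Gaussian outcome likelihood N(r; w_k·x, σr²) per cause."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    mu = w @ np.asarray(x, dtype=float)
    dens = np.exp(-((r - mu) ** 2) / (2 * params.sigma_r2)) / math.sqrt(
        2 * math.pi * params.sigma_r2
    )
    return dens if dens.size > 1 else float(dens[0])


def e_step(prior: np.ndarray, feat_lik: np.ndarray, out_lik=None) -> np.ndarray:
    """Bayes rule: posterior ∝ prior × stimulus likelihood [× outcome likelihood].

    The outcome likelihood is omitted when the response is emitted before
    the outcome of the trial has been observed.
    """
    mass = np.asarray(prior, dtype=float) * np.asarray(feat_lik, dtype=float)
    if out_lik is not None:
        mass = mass * np.asarray(out_lik, dtype=float)
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate posterior: all unnormalized masses are zero")
    return mass / total


def predict_outcome(posterior: np.ndarray, weights, x: np.ndarray) -> float:
    """Expected shock: Σ_k posterior_k (w_k · x)."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    return float(np.asarray(posterior) @ (w @ np.asarray(x, dtype=float)))


def m_step(
    posterior: np.ndarray, x: np.ndarray, r: float, weights, params: ParamSet
) -> np.ndarray:
    """Posterior-weighted Rescorla–Wagner update of every weight vector.

    w_k ← w_k + η · posterior_k · (r − w_k·x) · x
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float)).copy()
    x = np.asarray(x, dtype=float)
    err = r - w @ x
    w += params.eta * np.asarray(posterior)[:, None] * err[:, None] * x[None, :]
    return w


def emit_cr(expected_r: float, params: ParamSet) -> float:
    """Conditioned response: P(N(expected_r, λ) > θ) = 1 − Φ((θ−E[r])/√λ)."""
    return float(ndtr((expected_r - params.theta) / math.sqrt(params.lam)))


def simulate_trial(
    state: ModelState, t_now: float, x: np.ndarray, r: float, params: ParamSet
):
    """Run one trial: emit the CR, then learn from the observed outcome.

    The CR is anticipatory: it is computed from the stimulus-only posterior
    and the pre-update weights, before the outcome enters inference.  The
    absence of a shock is itself an observation (r = 0), so the EM loop runs
    with the outcome likelihood on every trial.  Mutates ``state``.

    Returns
    -------
    cr : float
    info : dict with keys ``posterior_stim``, ``posterior``, ``map_cause``
        (0-based), ``instantiated`` (bool).
    """
    x = np.asarray(x, dtype=float)
    prior = cause_prior(state, t_now, params)
    has_new = state.n_active < params.K
    feat = feature_likelihood(x, state, params, include_new=has_new)
    post_stim = e_step(prior, feat)

    w_aligned = state.weights[: state.n_active].copy()
    if has_new:
        w_aligned = np.vstack([w_aligned, np.full((1, _D), params.w0)])

    cr = emit_cr(predict_outcome(post_stim, w_aligned, x), params)

    # EM loop: the prior and stimulus likelihood are fixed; weights (hence the
    # outcome likelihood) evolve.  The prospective new cause starts at w0 and
    # learns like any other, so a cause inferred on a shock trial already
    # carries that trial's association.
    post = post_stim
    for _ in range(params.max_em_iter):
        out = outcome_likelihood(r, x, w_aligned, params)
        post = e_step(prior, feat, out)
        w_aligned = m_step(post, x, r, w_aligned, params)

    map_cause = int(np.argmax(post))  # ties break toward the lowest index
    instantiated = False
    if has_new and map_cause == state.n_active:
        state.n_active += 1
        instantiated = True
    state.weights[: state.n_active] = w_aligned[: state.n_active]
    state.feature_sums[map_cause] += x
    state.feature_counts[map_cause] += 1
    state.assignments.append(map_cause)
    state.assign_times.append(float(t_now))

    return cr, {
        "posterior_stim": post_stim,
        "posterior": post,
        "map_cause": map_cause,
        "instantiated": instantiated,
    }


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of one deterministic simulation over a trial schedule.

    Posterior arrays have one column per cause eventually instantiated plus
    a final column holding any probability mass on a prospective new cause
    that was not instantiated on that trial.  Rows sum to 1.

    ``posterior_stim`` is the stimulus-only posterior used for response
    emission; ``posterior`` the final post-EM posterior that also saw the
    outcome.  ``weights`` holds post-trial weight vectors (NaN before a
    cause exists).  ``map_assignment`` is 0-based; trials are row 0 = trial 1.
    """

    cr: CRTrace
    posterior_stim: np.ndarray  # (n_trials, n_causes + 1)
    posterior: np.ndarray  # (n_trials, n_causes + 1)
    weights: np.ndarray  # (n_trials, n_causes, 2)
    map_assignment: np.ndarray  # (n_trials,)
    first_inferred_trial: np.ndarray  # (n_causes,) 1-based trial of instantiation
    params: ParamSet
    schedule: TrialSchedule

    @property
    def n_causes(self) -> int:
        return int(self.first_inferred_trial.shape[0])

    def to_frame(self) -> pd.DataFrame:
        """Per-trial CSV-ready table: cr, MAP cause (1-based), posteriors, weights."""
        n, c = self.posterior.shape
        data = {
            "trial": np.arange(1, n + 1),
            "cr": self.cr.values,
            "map_cause": self.map_assignment + 1,
        }
        for k in range(c - 1):
            data[f"posterior_{k + 1}"] = self.posterior[:, k]
        data["posterior_new"] = self.posterior[:, -1]
        for k in range(self.n_causes):
            data[f"w_cs_{k + 1}"] = self.weights[:, k, 0]
            data[f"w_context_{k + 1}"] = self.weights[:, k, 1]
        return pd.DataFrame(data)


def simulate_paradigm(params: ParamSet, schedule: TrialSchedule) -> SimulationResult:
    """Fold :func:`simulate_trial` over every trial of the schedule."""
    n = schedule.n_trials
    state = ModelState(K=params.K)
    cr = np.empty(n)
    raw_stim, raw_post, maps, inst = [], [], [], []
    weights_hist = []
    for t in range(n):
        cr[t], info = simulate_trial(
            state, schedule.times[t], schedule.stimuli[t], float(schedule.us[t]), params
        )
        raw_stim.append(info["posterior_stim"])
        raw_post.append(info["posterior"])
        maps.append(info["map_cause"])
        inst.append(info["instantiated"])
        weights_hist.append((state.n_active, state.weights[: state.n_active].copy()))

    n_causes = state.n_active
    post_stim = np.zeros((n, n_causes + 1))
    post_final = np.zeros((n, n_causes + 1))
    weights = np.full((n, n_causes, _D), np.nan)
    first_inferred = np.zeros(n_causes, dtype=int)
    n_before = 0
    for t in range(n):
        vec_s, vec_p = raw_stim[t], raw_post[t]
        k_here = len(vec_p)  # active causes at trial t (+ new slot if present)
        had_new = k_here > n_before
        n_existing = n_before
        post_stim[t, :n_existing] = vec_s[:n_existing]
        post_final[t, :n_existing] = vec_p[:n_existing]
        if had_new:
            if inst[t]:
                post_stim[t, n_existing] = vec_s[-1]
                post_final[t, n_existing] = vec_p[-1]
            else:
                post_stim[t, -1] = vec_s[-1]
                post_final[t, -1] = vec_p[-1]
        if inst[t]:
            first_inferred[maps[t]] = t + 1
            n_before += 1
        na, w = weights_hist[t]
        weights[t, :na] = w
    return SimulationResult(
        cr=CRTrace(values=np.clip(cr, 0.0, 1.0)),
        posterior_stim=post_stim,
        posterior=post_final,
        weights=weights,
        map_assignment=np.array(maps, dtype=int),
        first_inferred_trial=first_inferred,
        params=params,
        schedule=schedule,
    )
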