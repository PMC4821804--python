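"""Two-stage maximum-likelihood estimation of the learning model.

Stage 1 estimates the shared initial signal/noise weights (w0_signal,
w0_noise) on pooled data, profiling out per-subject nuisance parameters by
alternating optimization.  Stage 2 fixes those initial weights and estimates
the five free parameters (alpha_w, alpha_c, beta, lambda, sigma_c) per
subject.  Both stages maximize the joint likelihood of choices (softmax) and
confidence reports (censored Gaussian).

Optimization is derivative-free Nelder-Mead in a transformed space (log for
the positive parameters, logit for alpha_c) with Latin-hypercube multistart.
The per-trial likelihood recursion is sequential (weights evolve trial by
trial), so the inner loop is JIT-compiled.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from .model import CW, ModelParams, TrialRecord

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_PENALTY = 1e12


@njit(cache=True)
def _norm_logcdf(z: float) -> float:
    # log Phi(z) via erfc for numerical safety in the lower tail
    return math.log(max(0.5 * math.erfc(-z / math.sqrt(2.0)), 1e-300))


@njit(cache=True)
def _nll_core(
    alpha_w: float,
    alpha_c: float,
    beta: float,
    lambda_: float,
    sigma_c: float,
    w0_signal: float,
    w0_noise: float,
    c_bar0: float,
    e_ccw: np.ndarray,
    e_cw: np.ndarray,
    choice_is_cw: np.ndarray,
    conf: np.ndarray,
) -> float:
    """Joint negative log likelihood of one subject's conditioned session."""
    w_ccw_ccw = w0_signal
    w_cw_cw = w0_signal
    w_ccw_cw = w0_noise
    w_cw_ccw = w0_noise
    c_bar = c_bar0
    nll = 0.0
    for t in range(e_ccw.shape[0]):
        a_ccw = e_ccw[t] * w_ccw_ccw + e_cw[t] * w_cw_ccw
        a_cw = e_cw[t] * w_cw_cw + e_ccw[t] * w_ccw_cw
        dv = a_cw - a_ccw
        # softmax choice term
        z = beta * dv if choice_is_cw[t] else -beta * dv
        if z > 0:
            nll += math.log1p(math.exp(-z))
        else:
            nll += -z + math.log1p(math.exp(z))
        # censored-Gaussian confidence term
        c_prime = lambda_ * abs(dv)
        c = conf[t]
        if c <= 0.0:
            nll -= _norm_logcdf((0.0 - c_prime) / sigma_c)
        elif c >= 1.0:
            nll -= _norm_logcdf((c_prime - 1.0) / sigma_c)
        else:
            zc = (c - c_prime) / sigma_c
            nll += 0.5 * zc * zc + math.log(sigma_c) + _LOG_SQRT_2PI
        # learning: CPE against pre-update expected confidence
        delta = c - c_bar
        a_choice = a_cw if choice_is_cw[t] else a_ccw
        upd = alpha_w * delta * a_choice
        if choice_is_cw[t]:
            w_cw_cw += upd * e_cw[t]
            w_ccw_cw += upd * e_ccw[t]
        else:
            w_cw_ccw += upd * e_cw[t]
            w_ccw_ccw += upd * e_ccw[t]
        c_bar += alpha_c * delta
    return nll


@dataclass
class SubjectData:
    """Arrays a fit needs: normalized energies, choices, confidences."""

    e_ccw: np.ndarray
    e_cw: np.ndarray
    choice_is_cw: np.ndarray
    confidence: np.ndarray

    @classmethod
    def from_trials(cls, trials: list[TrialRecord]) -> "SubjectData":
        return cls(
            e_ccw=np.array([t.energies.E_ccw for t in trials]),
            e_cw=np.array([t.energies.E_cw for t in trials]),
            choice_is_cw=np.array([t.choice == CW for t in trials]),
            confidence=np.array([t.confidence for t in trials]),
        )

    def __post_init__(self) -> None:
        n = len(self.e_ccw)
        if not (len(self.e_cw) == len(self.choice_is_cw) == len(self.confidence) == n):
            raise ValueError("subject data arrays must have equal length")
        self.e_ccw = np.ascontiguousarray(self.e_ccw, dtype=np.float64)
        self.e_cw = np.ascontiguousarray(self.e_cw, dtype=np.float64)
        self.choice_is_cw = np.ascontiguousarray(self.choice_is_cw, dtype=np.bool_)
        self.confidence = np.ascontiguousarray(self.confidence, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.e_ccw)


def negative_log_likelihood(
    params: ModelParams, data: SubjectData | list[TrialRecord], c_bar0: float = 0.5
) -> float:
    """-sum_t [log p(d_t) + log p(c_t)] for a conditioned run of the model."""
    if isinstance(data, list):
        data = SubjectData.from_trials(data)
    nll = _nll_core(
        params.alpha_w,
        params.alpha_c,
        params.beta,
        params.lambda_,
        params.sigma_c,
        params.w0_signal,
        params.w0_noise,
        c_bar0,
        data.e_ccw,
        data.e_cw,
        data.choice_is_cw,
        data.confidence,
    )
    if not math.isfinite(nll):
        import warnings

        warnings.warn("non-finite likelihood; returning large penalty", stacklevel=2)
        return _PENALTY
    return float(nll)


@dataclass
class FitResult:
    params: ModelParams
    neg_log_lik: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    seed: int


@dataclass
class GroupFitResult:
    w0_signal: float
    w0_noise: float
    pooled_neg_log_lik: float
    per_subject_nuisance: list = field(default_factory=list)


# --- parameter transforms ---------------------------------------------------
# theta = (log alpha_w, logit alpha_c, log beta, log lambda, log sigma_c)

_THETA_LO = np.array([-12.0, -6.0, -4.0, -4.0, -4.0])
_THETA_HI = np.array([0.0, 6.0, 4.0, 3.0, 0.5])


def _sexp(x: float) -> float:
    """exp with the argument clamped so simplex excursions cannot overflow."""
    return math.exp(min(max(x, -745.0), 50.0))


def _expit(x: float) -> float:
    x = min(max(x, -50.0), 50.0)
    return 1.0 / (1.0 + math.exp(-x))


def _theta_to_params(theta: np.ndarray, w0: tuple[float, float]) -> ModelParams:
    return ModelParams(
        alpha_w=_sexp(theta[0]),
        alpha_c=_expit(theta[1]),
        beta=_sexp(theta[2]),
        lambda_=_sexp(theta[3]),
        sigma_c=_sexp(theta[4]),
        w0_signal=w0[0],
        w0_noise=w0[1],
    )


def _params_to_theta(p: ModelParams) -> np.ndarray:
    eps = 1e-12
    ac = min(max(p.alpha_c, eps), 1 - eps)
    return np.array(
        [
            math.log(max(p.alpha_w, eps)),
            math.log(ac / (1 - ac)),
            math.log(max(p.beta, eps)),
            math.log(max(p.lambda_, eps)),
            math.log(p.sigma_c),
        ]
    )


def fit_subject(
    data: SubjectData | list[TrialRecord],
    w0: tuple[float, float],
    n_restarts: int = 10,
    seed: int = 0,
    c_bar0: float = 0.5,
    xtol: float = 1e-6,
    max_iter: int = 2000,
) -> FitResult:
    """Stage-2 fit: the five free parameters with initial weights fixed.

    Multistart Nelder-Mead from Latin-hypercube draws in transformed space;
    returns the best restart.
    """
    if isinstance(data, list):
        data = SubjectData.from_trials(data)

    def objective(theta: np.ndarray) -> float:
        nll = _nll_core(
            _sexp(theta[0]),
            _expit(theta[1]),
            _sexp(theta[2]),
            _sexp(theta[3]),
            _sexp(theta[4]),
            w0[0],
            w0[1],
            c_bar0,
            data.e_ccw,
            data.e_cw,
            data.choice_is_cw,
            data.confidence,
        )
        return nll if math.isfinite(nll) else _PENALTY

    sampler = qmc.LatinHypercube(d=5, seed=seed)
    starts = qmc.scale(sampler.random(n_restarts), _THETA_LO, _THETA_HI)
    best = None
    any_converged = False
    for theta0 in starts:
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={"fatol": xtol, "xatol": 1e-6, "maxiter": max_iter, "maxfev": 4000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(any_converged and best.fun < _PENALTY)
    return FitResult(
        params=_theta_to_params(best.x, w0),
        neg_log_lik=float(best.fun),
        n_trials=len(data),
        converged=converged,
        n_restarts_used=n_restarts,
        seed=seed,
    )


def fit_group_initial_weights(
    subjects: list[SubjectData],
    n_sweeps: int = 2,
    n_restarts: int = 4,
    seed: int = 0,
    w0_init: tuple[float, float] = (0.5, 0.1),
    c_bar0: float = 0.5,
) -> GroupFitResult:
    """Stage-1 fit: shared initial weights on pooled data.

    Per-subject nuisance parameters (the five free parameters) are profiled
    out by alternating optimization: fit each subject at the current w0, then
    optimize w0 by Nelder-Mead with the nuisance parameters fixed, for
    `n_sweeps` rounds.  A single subject degenerates to a joint 7-parameter
    fit of that subject.
    """
    if not subjects:
        raise ValueError("no subjects")
    for s in subjects:
        if len(s) == 0 or (s.choice_is_cw.all() or (~s.choice_is_cw).all()) and len(subjects) > 1:
            raise ValueError("degenerate subject data (no choice variability)")
    w0 = (float(w0_init[0]), float(w0_init[1]))
    # restart seeds derive from the data, not the subject position, so the
    # pooled estimate is invariant to subject ordering
    subject_seeds = [
        seed + zlib.crc32(s.confidence.tobytes()) % 100_000 for s in subjects
    ]
    fits: list[FitResult] = []
    pooled = math.inf
    for sweep in range(n_sweeps):
        fits = [
            fit_subject(s, w0, n_restarts=n_restarts, seed=s_seed, c_bar0=c_bar0)
            for s, s_seed in zip(subjects, subject_seeds)
        ]

        def pooled_nll(w: np.ndarray) -> float:
            total = 0.0
            for s, f in zip(subjects, fits):
                p = f.params
                total += _nll_core(
                    p.alpha_w, p.alpha_c, p.beta, p.lambda_, p.sigma_c,
                    w[0], w[1], c_bar0,
                    s.e_ccw, s.e_cw, s.choice_is_cw, s.confidence,
                )
            return total if math.isfinite(total) else _PENALTY

        res = minimize(
            pooled_nll,
            np.array(w0),
            method="Nelder-Mead",
            options={"fatol": 1e-6, "xatol": 1e-6, "maxiter": 1000},
        )
        w0 = (float(res.x[0]), float(res.x[1]))
        pooled = float(res.fun)
    return GroupFitResult(
        w0_signal=w0[0],
        w0_noise=w0[1],
        pooled_neg_log_lik=pooled,
        per_subject_nuisance=fits,
    )


def two_stage_fit(
    subjects: list[SubjectData],
    seed: int = 0,
    n_restarts_stage2: int = 10,
    **group_kwargs,
) -> tuple[GroupFitResult, list[FitResult]]:
    """Full procedure: pooled initial-weight estimation, then per-subject fits."""
    group = fit_group_initial_weights(subjects, seed=seed, **group_kwargs)
    w0 = (group.w0_signal, group.w0_noise)
    fits = [
        fit_subject(s, w0, n_restarts=n_restarts_stage2, seed=seed + 31 * i)
        for i, s in enumerate(subjects)
    ]
    return group, fits
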