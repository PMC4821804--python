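"""Confidence-guided associative reinforcement-learning model.

The observer reads out two normalized orientation energies (E_ccw, E_cw)
through a 2x2 weight matrix into decision units A_ccw, A_cw.  *Signal
weights* connect each energy detector to the decision unit of the same
orientation; *noise weights* connect it to the opposing unit:

    A_ccw = E_ccw * w_ccw,ccw + E_cw * w_cw,ccw
    A_cw  = E_cw  * w_cw,cw   + E_ccw * w_ccw,cw

The decision value DV = A_cw - A_ccw drives a softmax choice
p(cw) = 1 / (1 + exp(-beta * DV)) and a decisional certainty
c' = lambda * |DV|, reported as confidence through censored Gaussian noise.

Without external feedback, learning is driven by a *confidence prediction
error* delta = c - c_bar, the mismatch between the trial's confidence and a
running (Rescorla-Wagner) estimate of expected confidence.  Weights into the
chosen unit update by a three-factor rule — presynaptic energy x postsynaptic
activity x delta:

    w_i,choice <- w_i,choice + alpha_w * delta * E_i * A_choice,  i in {ccw, cw}

so connections that contributed more to the choice change more, and the sign
of delta decides strengthening versus weakening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
from scipy.stats import norm

from .energy import EnergyObservation

CW, CCW = "cw", "ccw"


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the learning model.

    alpha_w : weight learning rate (>= 0)
    alpha_c : expected-confidence learning rate (in [0, 1])
    beta    : softmax inverse temperature (>= 0)
    lambda_ : certainty scaling, confidence units per DV unit (>= 0)
    sigma_c : SD of the censored Gaussian confidence report noise (> 0)
    w0_signal, w0_noise : initial values of the signal and noise weights
    """

    alpha_w: float
    alpha_c: float
    beta: float
    lambda_: float
    sigma_c: float
    w0_signal: float = 0.0
    w0_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_w < 0:
            raise ValueError("alpha_w must be >= 0")
        if not 0.0 <= self.alpha_c <= 1.0:
            raise ValueError("alpha_c must be in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be > 0")


@dataclass
class ModelState:
    """Evolving state: the four readout weights plus expected confidence."""

    w_ccw_ccw: float  # signal weight, ccw detector -> ccw unit
    w_cw_cw: float    # signal weight, cw detector -> cw unit
    w_ccw_cw: float   # noise weight, ccw detector -> cw unit
    w_cw_ccw: float   # noise weight, cw detector -> ccw unit
    c_bar: float = 0.5

    @classmethod
    def from_params(cls, params: ModelParams, c_bar0: float = 0.5) -> "ModelState":
        return cls(
            w_ccw_ccw=params.w0_signal,
            w_cw_cw=params.w0_signal,
            w_ccw_cw=params.w0_noise,
            w_cw_ccw=params.w0_noise,
            c_bar=c_bar0,
        )

    @property
    def signal_mean(self) -> float:
        return 0.5 * (self.w_ccw_ccw + self.w_cw_cw)

    @property
    def noise_mean(self) -> float:
        return 0.5 * (self.w_ccw_cw + self.w_cw_ccw)


@dataclass
class TrialRecord:
    """One trial of a session, with model internals logged."""

    run_index: int
    trial_index: int
    condition: str            # 'staircase' | 'constant'
    true_orientation: str     # 'cw' | 'ccw'
    contrast_cp: float
    energies: EnergyObservation
    choice: str
    confidence: float
    correct: bool
    dv: float
    certainty: float
    cpe: float
    c_bar_pre: float
    t_trial_onset: float = float("nan")
    t_stimulus_onset: float = float("nan")
    w_signal: float = float("nan")   # post-update means, for trajectory analyses
    w_noise: float = float("nan")


# --- elementary operations --------------------------------------------------

def decision_activities(E: EnergyObservation, state: ModelState) -> tuple[float, float]:
    """(A_ccw, A_cw): weighted sums of the normalized energies."""
    a_ccw = E.E_ccw * state.w_ccw_ccw + E.E_cw * state.w_cw_ccw
    a_cw = E.E_cw * state.w_cw_cw + E.E_ccw * state.w_ccw_cw
    return a_ccw, a_cw


def decision_value(a_ccw: float, a_cw: float) -> float:
    """DV = A_cw - A_ccw; positive favors the clockwise choice."""
    return a_cw - a_ccw


def choice_probability(dv: float, beta: float) -> float:
    """Softmax (logistic) probability of a clockwise choice, overflow-safe."""
    z = -beta * dv
    if z >= 0:
        ez = math.exp(-z) if z < 700 else 0.0
        return ez / (1.0 + ez)
    return 1.0 / (1.0 + math.exp(z))


def decisional_certainty(dv: float, lambda_: float) -> float:
    """c' = lambda * |DV|: the model's internal confidence readout."""
    return lambda_ * abs(dv)


def confidence_prediction_error(c: float, c_bar: float) -> float:
    """delta = c - c_bar, the internal teaching signal."""
    if not 0.0 <= c <= 1.0 or not 0.0 <= c_bar <= 1.0:
        raise ValueError("confidence values must lie in [0, 1]")
    return c - c_bar


def update_expected_confidence(c_bar: float, delta: float, alpha_c: float) -> float:
    """Rescorla-Wagner update: c_bar <- c_bar + alpha_c * delta."""
    return c_bar + alpha_c * delta


def update_weights(
    state: ModelState,
    delta: float,
    E: EnergyObservation,
    a_choice: float,
    choice: str,
    alpha_w: float,
) -> ModelState:
    """Three-factor update of the two connections into the chosen unit only."""
    d_cw = alpha_w * delta * E.E_cw * a_choice
    d_ccw = alpha_w * delta * E.E_ccw * a_choice
    if choice == CW:
        return replace(state, w_cw_cw=state.w_cw_cw + d_cw, w_ccw_cw=state.w_ccw_cw + d_ccw)
    if choice == CCW:
        return replace(
            state, w_cw_ccw=state.w_cw_ccw + d_cw, w_ccw_ccw=state.w_ccw_ccw + d_ccw
        )
    raise ValueError(f"choice must be 'cw' or 'ccw', got {choice!r}")


def confidence_log_density(c: float, c_prime: float, sigma_c: float) -> float:
    """Censored-Gaussian log likelihood of a confidence report on [0, 1].

    Interior reports use the Normal(c', sigma_c) density; reports exactly at
    0 or 1 use the probability mass of the tail beyond the boundary, so the
    mixed density/mass distribution integrates to one.
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be > 0")
    if not 0.0 <= c <= 1.0:
        raise ValueError("confidence must lie in [0, 1]")
    if c == 0.0:
        return norm.logcdf((0.0 - c_prime) / sigma_c)
    if c == 1.0:
        return norm.logsf((1.0 - c_prime) / sigma_c)
    return norm.logpdf(c, loc=c_prime, scale=sigma_c)


# --- session runner ---------------------------------------------------------

@dataclass
class SessionResult:
    trials: list[TrialRecord]
    final_state: ModelState
    log_likelihood: float  # conditioned mode: sum of log p(d) + log p(c)
    state_trajectory: list[ModelState] = field(default_factory=list)


def run_session(
    params: ModelParams,
    energies: list[EnergyObservation],
    mode: str = "generative",
    true_orientations: list[str] | None = None,
    contrasts: list[float] | None = None,
    observed_choices: list[str] | None = None,
    observed_confidences: list[float] | None = None,
    state: ModelState | None = None,
    rng: np.random.Generator | None = None,
    run_index: int = 0,
    condition: str = "constant",
    learning: bool = True,
) -> SessionResult:
    """Run the model through a stream of energy observations, trial by trial.

    Per trial: activities -> DV -> choice and confidence (sampled in
    generative mode, taken from the data in conditioned mode) -> CPE against
    the pre-update expected confidence -> weight update -> expected-confidence
    update.  Conditioned mode also accumulates the joint log likelihood of the
    observed choices and confidences.
    """
    if mode not in ("generative", "conditioned"):
        raise ValueError(f"mode must be 'generative' or 'conditioned', got {mode!r}")
    if mode == "conditioned":
        if observed_choices is None or observed_confidences is None:
            raise ValueError("conditioned mode requires observed choices and confidences")
        if len(observed_choices) != len(energies) or len(observed_confidences) != len(energies):
            raise ValueError("observed streams must match the energy stream length")
    if mode == "generative" and rng is None:
        rng = np.random.default_rng(0)
    if state is None:
        state = ModelState.from_params(params)
    n = len(energies)
    truths = true_orientations if true_orientations is not None else [CW] * n
    if len(truths) != n:
        raise ValueError("true_orientations must match the energy stream length")
    cps = contrasts if contrasts is not None else [float("nan")] * n

    trials: list[TrialRecord] = []
    trajectory: list[ModelState] = []
    loglik = 0.0
    for t, E in enumerate(energies):
        a_ccw, a_cw = decision_activities(E, state)
        dv = decision_value(a_ccw, a_cw)
        p_cw = choice_probability(dv, params.beta)
        c_prime = decisional_certainty(dv, params.lambda_)
        if mode == "generative":
            choice = CW if rng.random() < p_cw else CCW
            confidence = float(
                np.clip(rng.normal(c_prime, params.sigma_c), 0.0, 1.0)
            )
        else:
            choice = observed_choices[t]
            confidence = float(observed_confidences[t])
            p_choice = p_cw if choice == CW else 1.0 - p_cw
            loglik += math.log(max(p_choice, 1e-300))
            loglik += confidence_log_density(confidence, c_prime, params.sigma_c)
        c_bar_pre = state.c_bar
        delta = confidence_prediction_error(confidence, c_bar_pre)
        if learning:
            a_choice = a_cw if choice == CW else a_ccw
            state = update_weights(state, delta, E, a_choice, choice, params.alpha_w)
            state = replace(
                state,
                c_bar=update_expected_confidence(state.c_bar, delta, params.alpha_c),
            )
        trials.append(
            TrialRecord(
                run_index=run_index,
                trial_index=t,
                condition=condition,
                true_orientation=truths[t],
                contrast_cp=float(cps[t]),
                energies=E,
                choice=choice,
                confidence=confidence,
                correct=choice == truths[t],
                dv=dv,
                certainty=c_prime,
                cpe=delta,
                c_bar_pre=c_bar_pre,
                w_signal=state.signal_mean,
                w_noise=state.noise_mean,
            )
        )
        trajectory.append(replace(state))
    return SessionResult(
        trials=trials,
        final_state=state,
        log_likelihood=loglik,
        state_trajectory=trajectory,
    )
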