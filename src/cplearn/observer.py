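"""Synthetic observers: a statistical stand-in for human participants.

Instead of rendering images and filtering them on every trial, the observer
carries a rectified-Gaussian surrogate for the orientation-energy front end:
the energy at the stimulus' designated orientation is Normal(floor +
gain * contrast, sd) clipped at zero, the opposite-orientation energy is
Normal(floor, sd) clipped at zero, independently across trials.  Choices and
confidence are then generated by the confidence-guided learning model itself,
so correct/incorrect trials inherit the energy asymmetry through the decision
rule alone (higher designated energy -> larger |DV| toward the truth ->
more likely correct), not by construction.

`simulate_experiment` assembles the full study protocol: a pre-test with
staircases on both reference axes, an adjustment run, nine 48-trial training
runs (staircase-controlled trials targeting 80.35% correct interleaved with
constant-contrast trials), and a post-test, with the model's weights and
expected confidence carried through continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy import EnergyObservation, normalize_energies
from .model import CW, CCW, ModelParams, ModelState, TrialRecord, run_session
from .staircase import (
    COARSE,
    StaircaseConfig,
    StaircaseState,
    run_staircase_session,
    staircase_update,
)

#: Default generative parameters: learning rates at the study's reported
#: medians; softmax, certainty-scaling and report-noise values chosen so the
#: calibrated observer performs near threshold with mid-scale confidence.
DEFAULT_TRUE_PARAMS = ModelParams(
    alpha_w=0.0018,
    alpha_c=0.533,
    beta=7.0,
    lambda_=2.0,
    sigma_c=0.18,
    w0_signal=0.5,
    w0_noise=0.1,
)

#: Frozen output of `calibrate_gain()` for the default observer: the
#: designated-energy slope per contrast percent at which the default model
#: scores ~80.35% correct at 8% contrast.
DEFAULT_ENERGY_GAIN = 0.1016


@dataclass(frozen=True)
class ObserverSpec:
    """Generative description of one synthetic participant."""

    true_params: ModelParams = DEFAULT_TRUE_PARAMS
    energy_gain: float = DEFAULT_ENERGY_GAIN   # raw energy units per contrast %
    energy_floor: float = 0.3                  # baseline raw energy mean
    energy_noise_sd: float = 0.15              # trial-to-trial raw SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.energy_gain < 0:
            raise ValueError("energy_gain must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Protocol constants of the study analogue."""

    n_training_runs: int = 9
    trials_per_run: int = 48
    constant_condition_fraction: float = 0.5
    trained_axis: str = "vertical"
    untrained_axis: str = "horizontal"
    test_block_size: int = 16
    fixation_mean_s: float = 2.0     # fixation 2000 +/- 1000 ms
    fixation_jitter_s: float = 1.0
    post_stim_mean_s: float = 2.0
    post_stim_jitter_s: float = 1.0
    stimulus_duration_s: float = 0.1
    response_screen_s: float = 3.0
    staircase: StaircaseConfig = StaircaseConfig()
    learning_during_tests: bool = True


def generate_energy_stream(
    contrasts,
    true_orientations,
    spec: ObserverSpec,
    rng: np.random.Generator | None = None,
) -> list[EnergyObservation]:
    """Raw surrogate energies for a sequence of trials.

    Designated-orientation energy ~ max(0, Normal(floor + gain * c_p, sd));
    opposite-orientation energy ~ max(0, Normal(floor, sd)); at zero contrast
    both are identically distributed.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    obs = []
    for c, truth in zip(contrasts, true_orientations):
        designated = max(
            0.0, rng.normal(spec.energy_floor + spec.energy_gain * c, spec.energy_noise_sd)
        )
        opposite = max(0.0, rng.normal(spec.energy_floor, spec.energy_noise_sd))
        if truth == CW:
            obs.append(EnergyObservation(E_ccw_raw=opposite, E_cw_raw=designated))
        elif truth == CCW:
            obs.append(EnergyObservation(E_ccw_raw=designated, E_cw_raw=opposite))
        else:
            raise ValueError(f"true orientation must be 'cw' or 'ccw', got {truth!r}")
    return obs


def calibration_constant(
    spec: ObserverSpec, reference_contrast: float = 8.0, n_burn_in: int = 200
) -> float:
    """Fixed energy-normalization constant for generative simulation.

    The session-maximum normalization used in fitting is acausal online, so
    generative runs divide raw energies by the maximum raw energy of a
    200-stimulus burn-in set at a reference contrast, drawn from a dedicated
    seed stream.
    """
    rng = np.random.default_rng(
        int(np.random.SeedSequence((spec.seed, 0xCA1B)).generate_state(1)[0]) % 2**31
    )
    truths = [CW if rng.random() < 0.5 else CCW for _ in range(n_burn_in)]
    burn = generate_energy_stream([reference_contrast] * n_burn_in, truths, spec, rng)
    return max(max(o.E_ccw_raw, o.E_cw_raw) for o in burn)


def simulate_trials(
    spec: ObserverSpec,
    contrasts,
    rng: np.random.Generator,
    state: ModelState | None = None,
    norm_k: float | None = None,
    run_index: int = 0,
    condition: str = "constant",
    learning: bool = True,
    true_orientations=None,
):
    """Simulate a block of trials at given contrasts; returns (trials, state)."""
    n = len(contrasts)
    if true_orientations is None:
        true_orientations = [CW if rng.random() < 0.5 else CCW for _ in range(n)]
    raw = generate_energy_stream(contrasts, true_orientations, spec, rng)
    k = norm_k if norm_k is not None else calibration_constant(spec)
    energies = normalize_energies(raw, mode="fixed", k=k)
    result = run_session(
        spec.true_params,
        energies,
        mode="generative",
        true_orientations=true_orientations,
        contrasts=contrasts,
        state=state,
        rng=rng,
        run_index=run_index,
        condition=condition,
        learning=learning,
    )
    return result.trials, result.final_state


def simulated_accuracy(
    spec: ObserverSpec, contrast: float, n_trials: int = 5000, seed: int = 1234,
    learning: bool = False,
) -> float:
    """Proportion correct of the observer at a fixed contrast (learning off)."""
    rng = np.random.default_rng(seed)
    trials, _ = simulate_trials(
        spec, [contrast] * n_trials, rng, learning=learning,
        norm_k=calibration_constant(spec),
    )
    return float(np.mean([t.correct for t in trials]))


def calibrate_gain(
    spec: ObserverSpec,
    target_accuracy: float = 0.8035,
    contrast: float = 8.0,
    n_trials: int = 5000,
    seed: int = 1234,
    tol: float = 0.002,
    max_iter: int = 40,
) -> float:
    """Bisection on energy_gain so the observer hits a target accuracy.

    Calibrates the surrogate front end to the study's operating point:
    ~80.35% correct at the mean training contrast of 8%.
    """
    lo, hi = 0.0, 1.0
    gain = spec.energy_gain
    for _ in range(max_iter):
        gain = 0.5 * (lo + hi)
        acc = simulated_accuracy(replace(spec, energy_gain=gain), contrast, n_trials, seed)
        if abs(acc - target_accuracy) < tol:
            break
        if acc < target_accuracy:
            lo = gain
        else:
            hi = gain
    return gain


@dataclass
class ExperimentDataset:
    """Everything one synthetic participant produces."""

    trials: pd.DataFrame               # training trials (9 runs x 48)
    pretest_thresholds: dict
    posttest_thresholds: dict
    adjustment_contrast: float
    test_logs: dict = field(default_factory=dict)
    state_trajectory: list = field(default_factory=list)
    spec: ObserverSpec | None = None
    design: ExperimentDesign | None = None
    seed: int = 0


def _trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_index": [t.run_index for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "condition": [t.condition for t in trials],
            "true_orientation": [t.true_orientation for t in trials],
            "contrast_cp": [t.contrast_cp for t in trials],
            "E_ccw_raw": [t.energies.E_ccw_raw for t in trials],
            "E_cw_raw": [t.energies.E_cw_raw for t in trials],
            "E_ccw": [t.energies.E_ccw for t in trials],
            "E_cw": [t.energies.E_cw for t in trials],
            "choice": [t.choice for t in trials],
            "confidence": [t.confidence for t in trials],
            "correct": [t.correct for t in trials],
            "dv": [t.dv for t in trials],
            "certainty": [t.certainty for t in trials],
            "cpe": [t.cpe for t in trials],
            "c_bar_pre": [t.c_bar_pre for t in trials],
            "w_signal": [t.w_signal for t in trials],
            "w_noise": [t.w_noise for t in trials],
            "t_trial_onset": [t.t_trial_onset for t in trials],
            "t_stimulus_onset": [t.t_stimulus_onset for t in trials],
        }
    )


def _assign_event_times(
    trials: list[TrialRecord], design: ExperimentDesign, rng: np.random.Generator
) -> None:
    """Fill per-run trial/stimulus onset times (uniform jitter around means)."""
    t = 0.0
    for tr in trials:
        fixation = rng.uniform(
            design.fixation_mean_s - design.fixation_jitter_s,
            design.fixation_mean_s + design.fixation_jitter_s,
        )
        post = rng.uniform(
            design.post_stim_mean_s - design.post_stim_jitter_s,
            design.post_stim_mean_s + design.post_stim_jitter_s,
        )
        tr.t_trial_onset = t
        tr.t_stimulus_onset = t + fixation
        t = (
            tr.t_stimulus_onset
            + design.stimulus_duration_s
            + post
            + design.response_screen_s
        )


def _run_test_session(
    spec, design, rng, state_box: dict, norm_k: float
) -> dict:
    """Pre/post test: staircases on both axes, model as the observer."""

    def observer(contrast: float, axis: str) -> bool:
        trials, new_state = simulate_trials(
            spec,
            [contrast],
            rng,
            state=state_box["state"],
            norm_k=norm_k,
            condition="test",
            learning=design.learning_during_tests,
        )
        state_box["state"] = new_state
        return trials[0].correct

    return run_staircase_session(
        observer,
        design.staircase,
        rng,
        block_size=design.test_block_size,
        axes=(design.trained_axis, design.untrained_axis),
    )


def simulate_experiment(
    spec: ObserverSpec, design: ExperimentDesign = ExperimentDesign(), seed: int | None = None
) -> ExperimentDataset:
    """Run the complete study analogue for one synthetic participant.

    The model state (weights, expected confidence) is carried continuously
    through pre-test, adjustment, training and post-test; staircase-condition
    training trials track the 80.35%-correct contrast while the interleaved
    constant-condition half stays at the adjustment-run endpoint contrast.
    Bit-exact reproducible from (spec, design, seed).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    norm_k = calibration_constant(spec)
    state_box = {"state": ModelState.from_params(spec.true_params)}

    pre = _run_test_session(spec, design, rng, state_box, norm_k)

    # adjustment run: weighted staircase from the pre-test trained-axis threshold
    adj_state = StaircaseState.from_config(design.staircase)
    adj_state.phase = "weighted"
    adj_state.contrast = pre["thresholds"][design.trained_axis]
    free_cfg = replace(design.staircase, terminate_at_reversal=10**9)
    for _ in range(design.trials_per_run):
        trials, state_box["state"] = simulate_trials(
            spec, [adj_state.contrast], rng, state=state_box["state"],
            norm_k=norm_k, condition="adjustment",
        )
        staircase_update(adj_state, trials[0].correct, free_cfg)
    constant_contrast = adj_state.contrast

    # nine training runs: staircase-controlled and constant halves interleaved
    training: list[TrialRecord] = []
    for run in range(design.n_training_runs):
        n = design.trials_per_run
        n_const = int(round(design.constant_condition_fraction * n))
        tags = np.array(["staircase"] * (n - n_const) + ["constant"] * n_const)
        rng.shuffle(tags)
        for i, tag in enumerate(tags):
            if tag == "staircase":
                contrast = adj_state.contrast
            else:
                contrast = constant_contrast
            trials, state_box["state"] = simulate_trials(
                spec, [contrast], rng, state=state_box["state"], norm_k=norm_k,
                run_index=run, condition=tag,
            )
            trials[0].trial_index = i
            if tag == "staircase":
                staircase_update(adj_state, trials[0].correct, free_cfg)
            training.extend(trials)

    post = _run_test_session(spec, design, rng, state_box, norm_k)

    _assign_event_times(training, design, rng)
    return ExperimentDataset(
        trials=_trials_to_frame(training),
        pretest_thresholds=pre["thresholds"],
        posttest_thresholds=post["thresholds"],
        adjustment_contrast=constant_contrast,
        test_logs={"pre": pre["log"], "post": post["log"]},
        spec=spec,
        design=design,
        seed=seed,
    )


def simulate_cohort(
    n_subjects: int, master_seed: int = 0, spec: ObserverSpec | None = None,
    design: ExperimentDesign = ExperimentDesign(),
) -> list[ExperimentDataset]:
    """Independent synthetic participants from a master seed fan-out."""
    base = spec if spec is not None else ObserverSpec()
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects) % 2**31
    return [
        simulate_experiment(replace(base, seed=int(s)), design, seed=int(s))
        for s in seeds
    ]
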