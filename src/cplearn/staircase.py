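"""Two-phase adaptive contrast staircase and its equilibrium analysis.

The procedure starts with a coarse one-up-one-down staircase using
multiplicative 0.05 log-unit steps to approach the threshold range, then
switches (after a fixed number of reversals) to a weighted one-up-two-down
staircase: contrast drops by `down_step` after two consecutive correct
responses and rises by `down_step / down_up_ratio` after any error.  With a
down/up step ratio of 0.5488 the weighted phase converges where
p^2 * step_down = (1 - p^2) * step_up, i.e. at 80.35% correct.  The staircase
terminates at a fixed reversal count and the threshold is estimated as the
mean of the weighted-phase reversal contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

COARSE, WEIGHTED = "coarse", "weighted"


class StaircaseTerminated(RuntimeError):
    pass


class StaircaseNotTerminating(RuntimeError):
    def __init__(self, message: str, partial_log=None):
        super().__init__(message)
        self.partial_log = partial_log


@dataclass(frozen=True)
class StaircaseConfig:
    start_contrast: float = 20.0          # percent
    phase1_logstep: float = 0.05          # log10 units, multiplicative phase
    switch_after_reversals: int = 3
    down_step: float = 0.33               # contrast percentage points
    down_up_ratio: float = 0.5488         # step_down / step_up
    terminate_at_reversal: int = 9
    contrast_bounds: tuple[float, float] = (0.1, 100.0)
    reset_reversals_on_switch: bool = False

    def __post_init__(self) -> None:
        if self.down_up_ratio <= 0:
            raise ValueError("down_up_ratio must be > 0")

    @property
    def up_step(self) -> float:
        return self.down_step / self.down_up_ratio


@dataclass
class StaircaseState:
    phase: str = COARSE
    contrast: float = 20.0
    consecutive_correct: int = 0
    reversal_contrasts: list = field(default_factory=list)
    weighted_reversal_contrasts: list = field(default_factory=list)
    last_direction: str = "none"          # 'up' | 'down' | 'none'
    terminated: bool = False
    n_trials: int = 0

    @classmethod
    def from_config(cls, cfg: StaircaseConfig) -> "StaircaseState":
        return cls(contrast=cfg.start_contrast)


def staircase_update(state: StaircaseState, correct: bool, cfg: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one trial outcome (state is mutated and returned).

    A reversal is recorded at the pre-step contrast whenever the direction of
    adjustment changes; reversals drive both the coarse->weighted phase switch
    and termination.
    """
    if state.terminated:
        raise StaircaseTerminated("staircase_update called after termination")
    state.n_trials += 1
    direction = None
    if state.phase == COARSE:
        if correct:
            new_contrast = state.contrast * 10.0 ** (-cfg.phase1_logstep)
            direction = "down"
        else:
            new_contrast = state.contrast * 10.0 ** (cfg.phase1_logstep)
            direction = "up"
    else:
        if correct:
            state.consecutive_correct += 1
            if state.consecutive_correct >= 2:
                new_contrast = state.contrast - cfg.down_step
                direction = "down"
                state.consecutive_correct = 0
            else:
                new_contrast = state.contrast
        else:
            state.consecutive_correct = 0
            new_contrast = state.contrast + cfg.up_step
            direction = "up"

    if direction is not None:
        if state.last_direction != "none" and direction != state.last_direction:
            state.reversal_contrasts.append(state.contrast)
            if state.phase == WEIGHTED:
                state.weighted_reversal_contrasts.append(state.contrast)
            n_rev = len(state.reversal_contrasts)
            if state.phase == COARSE and n_rev >= cfg.switch_after_reversals:
                state.phase = WEIGHTED
                state.consecutive_correct = 0
                if cfg.reset_reversals_on_switch:
                    state.reversal_contrasts = []
            elif len(state.reversal_contrasts) >= cfg.terminate_at_reversal:
                state.terminated = True
        state.last_direction = direction
        lo, hi = cfg.contrast_bounds
        state.contrast = float(np.clip(new_contrast, lo, hi))
    return state


def equilibrium_performance(down_up_ratio: float, n_down: int = 2) -> float:
    """Asymptotic proportion correct of a weighted 1-up-n-down staircase.

    Solves p^n * step_down = (1 - p^n) * step_up for p:
    p = (1 / (1 + ratio))^(1/n).
    """
    if down_up_ratio <= 0 or n_down < 1:
        raise ValueError("require down_up_ratio > 0 and n_down >= 1")
    return (1.0 / (1.0 + down_up_ratio)) ** (1.0 / n_down)


def equilibrium_ratio(p: float, n_down: int = 2) -> float:
    """Inverse of equilibrium_performance: the down/up step ratio converging at p."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return (1.0 - p**n_down) / p**n_down


def threshold_estimate(state: StaircaseState) -> float:
    """Mean of the reversal contrasts recorded during the weighted phase."""
    if not state.weighted_reversal_contrasts:
        raise ValueError("no weighted-phase reversals to estimate a threshold from")
    return float(np.mean(state.weighted_reversal_contrasts))


def run_weighted_phase(
    p_correct: Callable[[float], float],
    n_trials: int,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
    start_contrast: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Free-run the weighted phase (no termination) against a stochastic observer.

    Returns (contrasts, corrects) over n_trials; used for convergence studies
    and for staircase-controlled training runs.
    """
    state = StaircaseState.from_config(cfg)
    state.phase = WEIGHTED
    if start_contrast is not None:
        state.contrast = start_contrast
    free_cfg = StaircaseConfig(
        start_contrast=cfg.start_contrast,
        phase1_logstep=cfg.phase1_logstep,
        switch_after_reversals=cfg.switch_after_reversals,
        down_step=cfg.down_step,
        down_up_ratio=cfg.down_up_ratio,
        terminate_at_reversal=10**9,
        contrast_bounds=cfg.contrast_bounds,
    )
    contrasts = np.empty(n_trials)
    corrects = np.empty(n_trials, dtype=bool)
    for t in range(n_trials):
        contrasts[t] = state.contrast
        correct = rng.random() < p_correct(state.contrast)
        corrects[t] = correct
        staircase_update(state, correct, free_cfg)
    return contrasts, corrects


def run_staircase_session(
    observer: Callable[[float, str], bool],
    cfg: StaircaseConfig,
    rng: np.random.Generator,
    block_size: int = 16,
    axes: tuple[str, str] = ("vertical", "horizontal"),
    max_trials_per_axis: int = 2000,
) -> dict:
    """Run independent staircases per reference axis in alternating blocks.

    observer(contrast, axis) -> bool (correct).  Blocks of `block_size`
    trials alternate between axes until each axis' staircase terminates;
    returns per-axis threshold estimates and a tidy trial log.
    """
    states = {axis: StaircaseState.from_config(cfg) for axis in axes}
    log: list[dict] = []
    block = 0
    while not all(s.terminated for s in states.values()):
        axis = axes[block % len(axes)]
        block += 1
        state = states[axis]
        if state.terminated:
            continue
        for _ in range(block_size):
            if state.terminated:
                break
            contrast = state.contrast
            phase = state.phase
            n_rev_before = len(state.reversal_contrasts)
            correct = bool(observer(contrast, axis))
            staircase_update(state, correct, cfg)
            log.append(
                {
                    "axis": axis,
                    "trial": state.n_trials,
                    "block": block,
                    "contrast": contrast,
                    "correct": correct,
                    "phase": phase,
                    "reversal": len(state.reversal_contrasts) > n_rev_before,
                }
            )
        if state.n_trials > max_trials_per_axis:
            raise StaircaseNotTerminating(
                f"staircase on axis {axis!r} did not terminate within "
                f"{max_trials_per_axis} trials",
                partial_log=log,
            )
    return {
        "thresholds": {axis: threshold_estimate(states[axis]) for axis in axes},
        "states": states,
        "log": log,
    }
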