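import numpy as np
import pytest

from cplearn.model import ModelParams, ModelState
from cplearn.observer import ObserverSpec, calibration_constant, simulate_trials
from cplearn.stimulus import StimulusSpec


@pytest.fixture
def default_spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams(
        alpha_w=0.0018, alpha_c=0.533, beta=7.0, lambda_=2.0, sigma_c=0.18,
        w0_signal=0.5, w0_noise=0.1,
    )


def simulate_training_session(
    spec: ObserverSpec,
    n_runs: int = 9,
    trials_per_run: int = 48,
    contrast: float = 8.0,
    seed: int | None = None,
):
    """Fixed-contrast training-session analogue: 9 runs of 48 trials with the
    model's learning on; returns the flat trial list."""
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    k = calibration_constant(spec)
    state = ModelState.from_params(spec.true_params)
    trials = []
    for run in range(n_runs):
        run_trials, state = simulate_trials(
            spec, [contrast] * trials_per_run, rng, state=state, norm_k=k, run_index=run
        )
        trials.extend(run_trials)
    return trials
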