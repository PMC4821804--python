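"""Desk-scale behavioral and model-based analyses.

Covers the study-analogue summaries: the sliding-window confidence/
performance calibration curve, the perceptual learning index (threshold
improvement with baseline regressed out), run-wise slopes of thresholds and
model weights, Fisher-z group summaries of per-subject correlations, and the
hemodynamic side: canonical double-gamma HRF, simulated BOLD time courses for
anticipation/prediction-error scenarios, and model-derived parametric
regressors for a GLM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# --- behavioral summaries ---------------------------------------------------

@dataclass
class CalibrationCurve:
    """Sliding-window proportion correct over sorted confidence values."""

    confidence_centers: np.ndarray
    proportion_correct: np.ndarray
    window_size: int
    window_fraction: float


def confidence_performance_curve(
    confidence, correct, window_fraction: float = 0.05
) -> CalibrationCurve:
    """Sort trials by confidence and slide a window of ceil(fraction * n)
    trials with step 1, emitting mean correctness per window."""
    confidence = np.asarray(confidence, dtype=float)
    correct = np.asarray(correct, dtype=float)
    n = len(confidence)
    window = int(np.ceil(window_fraction * n))
    if window < 1 or n < 1.0 / window_fraction:
        raise ValueError(f"need at least {int(np.ceil(1 / window_fraction))} trials, got {n}")
    order = np.argsort(confidence, kind="stable")
    conf_sorted = confidence[order]
    corr_sorted = correct[order]
    kernel = np.ones(window) / window
    centers = np.convolve(conf_sorted, kernel, mode="valid")
    proportions = np.convolve(corr_sorted, kernel, mode="valid")
    return CalibrationCurve(
        confidence_centers=centers,
        proportion_correct=proportions,
        window_size=window,
        window_fraction=window_fraction,
    )


@dataclass
class LearningIndex:
    """Per-subject threshold improvement, baseline regressed out.

    Values are the negated OLS residuals of (post - pre) on pre, so larger
    values mean more learning; they sum to zero and are uncorrelated with the
    pre-test thresholds by construction.
    """

    values: np.ndarray
    improvement: np.ndarray
    slope: float
    intercept: float


def perceptual_learning_index(pre_thresholds, post_thresholds) -> LearningIndex:
    pre = np.asarray(pre_thresholds, dtype=float)
    post = np.asarray(post_thresholds, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 3:
        raise ValueError("need paired per-subject thresholds, n >= 3")
    if np.ptp(pre) == 0:
        raise ValueError("pre-test thresholds have zero variance")
    improvement = post - pre
    slope, intercept = np.polyfit(pre, improvement, 1)
    residuals = improvement - (intercept + slope * pre)
    return LearningIndex(
        values=-residuals,
        improvement=improvement,
        slope=float(slope),
        intercept=float(intercept),
    )


def slope_per_run(values, run_index) -> tuple[float, pd.Series]:
    """Least-squares slope of per-run means against the run index."""
    series = pd.Series(np.asarray(values, dtype=float), index=np.asarray(run_index))
    run_means = series.groupby(level=0).mean()
    if len(run_means) < 2:
        raise ValueError("need at least 2 runs")
    slope = np.polyfit(run_means.index.to_numpy(dtype=float), run_means.to_numpy(), 1)[0]
    return float(slope), run_means


@dataclass
class FisherZResult:
    mean_z: float
    t_statistic: float
    p_value: float
    n: int


def fisher_z_group_test(correlations) -> FisherZResult:
    """One-sample t-test of Fisher z-transformed correlations against 0."""
    r = np.asarray(correlations, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 correlation coefficients")
    if np.any(np.abs(r) >= 1):
        raise ValueError("correlations must satisfy |r| < 1")
    z = np.arctanh(r)
    if np.ptp(z) == 0:
        # degenerate sample: all z identical; t is 0 at the null, infinite off it
        t = 0.0 if z[0] == 0 else math.copysign(math.inf, z[0])
        p = 1.0 if z[0] == 0 else 0.0
    else:
        t, p = stats.ttest_1samp(z, 0.0)
    return FisherZResult(mean_z=float(z.mean()), t_statistic=float(t), p_value=float(p), n=len(r))


# --- hemodynamics -----------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6),
    scaled to unit peak."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0


def _double_gamma_raw(t: np.ndarray, p: HrfParams) -> np.ndarray:
    peak = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - under / p.undershoot_ratio
    h[t < 0] = 0.0
    return h


def double_gamma_hrf(t, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sample the canonical HRF at times t (seconds); zero for t < 0.

    Scaled to unit peak, with the peak located on a dense internal grid so
    the scale does not depend on the caller's sampling grid.
    """
    t = np.asarray(t, dtype=float)
    scale = np.max(np.abs(_double_gamma_raw(np.arange(0.0, 32.0, 0.01), params)))
    return _double_gamma_raw(t, params) / scale


BOLD_SAMPLING_HZ = 10.0
BOLD_N_SAMPLES = 240
BOLD_T_START = -4.0   # seconds relative to stimulus onset
TRIAL_ONSET_T = -2.0


@dataclass
class BoldTimeCourse:
    """Simulated BOLD response, 240 samples at 10 Hz from -4 s to +20 s."""

    samples: np.ndarray
    time: np.ndarray
    scenario: str

    def __post_init__(self) -> None:
        if len(self.samples) != BOLD_N_SAMPLES:
            raise ValueError("BOLD time course must hold exactly 240 samples")


_SCENARIO_STIM_WEIGHT = {"positive_pe": 1.0, "absent_pe": 0.0, "negative_pe": -1.0}


def simulate_bold(scenario: str, hrf_params: HrfParams = HrfParams()) -> BoldTimeCourse:
    """Anticipation + prediction-error BOLD scenario.

    The neural vector covers -4 s to +20 s around stimulus onset at 10 Hz
    (240 samples), with a +1 impulse at trial onset (-2 s) and a
    {+1, 0, -1} impulse at stimulus onset (0 s) according to the
    prediction-error sign; it is convolved with the canonical double-gamma
    HRF and truncated to 240 samples.
    """
    if scenario not in _SCENARIO_STIM_WEIGHT:
        raise ValueError(f"unknown scenario {scenario!r}")
    dt = 1.0 / BOLD_SAMPLING_HZ
    time = BOLD_T_START + dt * np.arange(BOLD_N_SAMPLES)
    neural = np.zeros(BOLD_N_SAMPLES)
    neural[int(round((TRIAL_ONSET_T - BOLD_T_START) * BOLD_SAMPLING_HZ))] = 1.0
    neural[int(round((0.0 - BOLD_T_START) * BOLD_SAMPLING_HZ))] = _SCENARIO_STIM_WEIGHT[
        scenario
    ]
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt), hrf_params)
    bold = np.convolve(neural, hrf)[:BOLD_N_SAMPLES]
    return BoldTimeCourse(samples=bold, time=time, scenario=scenario)


def build_parametric_regressors(
    onsets,
    weights,
    tr: float = 2.0,
    duration: float | None = None,
    mean_center: bool = True,
    hrf_params: HrfParams = HrfParams(),
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved parametric impulse train, sampled at the scanner TR.

    Weighted (mean-centered by default) delta functions at the event onsets
    are convolved with the canonical HRF on a fine grid and sampled every
    `tr` seconds.  Returns (scan_times, regressor).  A constant weight vector
    mean-centers to an identically zero regressor; a single unit-weight event
    reproduces the sampled HRF.
    """
    onsets = np.asarray(onsets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if onsets.shape != weights.shape:
        raise ValueError("onsets and weights must align")
    if duration is None:
        duration = float(onsets.max()) + 32.0
    if np.any(onsets < 0) or np.any(onsets >= duration):
        raise ValueError("event onsets must lie within [0, duration)")
    w = weights - weights.mean() if mean_center else weights
    n_fine = int(np.ceil(duration / dt)) + 1
    train = np.zeros(n_fine)
    np.add.at(train, np.round(onsets / dt).astype(int), w)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt), hrf_params)
    fine = np.convolve(train, hrf)[:n_fine]
    scan_times = np.arange(0.0, duration, tr)
    regressor = fine[np.round(scan_times / dt).astype(int)]
    return scan_times, regressor


def model_glm_regressors(
    trials: pd.DataFrame, tr: float = 2.0, duration: float | None = None
) -> pd.DataFrame:
    """The model-based GLM pair: expected confidence modulating trial onsets
    and the confidence prediction error modulating stimulus onsets."""
    if duration is None:
        duration = float(trials["t_stimulus_onset"].max()) + 32.0
    t, ec = build_parametric_regressors(
        trials["t_trial_onset"].to_numpy(), trials["c_bar_pre"].to_numpy(), tr, duration
    )
    _, pe = build_parametric_regressors(
        trials["t_stimulus_onset"].to_numpy(), trials["cpe"].to_numpy(), tr, duration
    )
    return pd.DataFrame({"time_s": t, "expected_confidence": ec, "cpe": pe})
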