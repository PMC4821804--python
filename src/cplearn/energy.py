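"""Orientation-energy extraction: a quadrature filter-bank front end.

Stands in for the representational subsystem of early visual cortex: raw
luminance images go in, one location-tolerant, unnormalized energy scalar per
(orientation, spatial frequency) channel comes out.  Each channel is a
quadrature pair of zero-mean Gabor kernels; their squared responses are summed
pointwise into a phase-invariant energy map which is then pooled over space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .stimulus import LuminanceImage, StimulusSpec

#: Orientation channels used throughout the study: +/-20 deg around the
#: vertical (0 deg) and horizontal (90 deg) reference axes.
DEFAULT_ORIENTATIONS = (-20.0, 20.0, 70.0, 110.0)
DEFAULT_FREQS = (1.25,)


def gabor_sigma_for_bandwidth(freq: float, bandwidth_octaves: float) -> float:
    """Envelope SD (degrees) giving a half-amplitude bandwidth in octaves."""
    b = 2.0**bandwidth_octaves
    return (1.0 / (np.pi * freq)) * np.sqrt(np.log(2.0) / 2.0) * (b + 1.0) / (b - 1.0)


@dataclass
class FilterBank:
    """Quadrature Gabor kernels per (orientation, frequency) channel.

    kernels maps (theta_deg, freq_cpd) -> (even, odd) arrays; both kernels
    are DC-free so a uniform image produces exactly zero energy.
    """

    orientations: tuple[float, ...]
    spatial_freqs: tuple[float, ...]
    kernels: dict = field(repr=False, default_factory=dict)
    pooling: str = "sum"
    degrees_per_pixel: float = 5.3 / 300


def _quadrature_pair(
    theta_deg: float, freq: float, sigma: float, extent_deg: float, dpp: float
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(extent_deg / dpp))
    n += 1 - n % 2  # odd size so the kernel has a central sample
    half = (n - 1) / 2.0
    coords = (np.arange(n) - half) * dpp
    x, y = np.meshgrid(coords, coords)
    theta = np.deg2rad(theta_deg)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    arg = 2.0 * np.pi * freq * (x * np.cos(theta) + y * np.sin(theta))
    even = envelope * np.cos(arg)
    odd = envelope * np.sin(arg)
    even -= even.mean()  # remove DC; odd is DC-free by symmetry but guard anyway
    odd -= odd.mean()
    return even, odd


def build_filter_bank(
    orientations=DEFAULT_ORIENTATIONS,
    spatial_freqs=DEFAULT_FREQS,
    bandwidth_octaves: float = 1.0,
    kernel_extent_deg: float | None = None,
    pooling: str = "sum",
    degrees_per_pixel: float = 5.3 / 300,
) -> FilterBank:
    """Construct the quadrature filter bank.

    kernel_extent_deg defaults to 6 envelope SDs and must hold at least one
    carrier cycle.
    """
    if pooling not in ("sum", "max"):
        raise ValueError(f"pooling must be 'sum' or 'max', got {pooling!r}")
    bank = FilterBank(
        orientations=tuple(float(o) for o in orientations),
        spatial_freqs=tuple(float(f) for f in spatial_freqs),
        pooling=pooling,
        degrees_per_pixel=degrees_per_pixel,
    )
    for f in bank.spatial_freqs:
        sigma = gabor_sigma_for_bandwidth(f, bandwidth_octaves)
        extent = kernel_extent_deg if kernel_extent_deg is not None else 6.0 * sigma
        if extent < 1.0 / f:
            raise ValueError(
                f"kernel extent {extent:.3f} deg cannot hold one cycle of {f} c/deg"
            )
        for theta in bank.orientations:
            bank.kernels[(theta, f)] = _quadrature_pair(
                theta, f, sigma, extent, degrees_per_pixel
            )
    return bank


def orientation_energy(
    img: LuminanceImage, bank: FilterBank, theta: float, freq: float,
    background_L0: float | None = None,
) -> float:
    """Pooled quadrature energy of one channel; a nonnegative scalar.

    The image is contrast-normalized internally, (L - L0)/L0, with L0 taken
    from the image mean unless given explicitly; a uniform image therefore
    yields exactly zero.
    """
    key = (float(theta), float(freq))
    if key not in bank.kernels:
        raise KeyError(f"channel {key} not in filter bank")
    values = img.values if isinstance(img, LuminanceImage) else np.asarray(img)
    l0 = background_L0 if background_L0 is not None else float(values.mean())
    contrast = (values - l0) / l0 if l0 != 0 else values.astype(float)
    even, odd = bank.kernels[key]
    r_even = fftconvolve(contrast, even, mode="same")
    r_odd = fftconvolve(contrast, odd, mode="same")
    energy_map = r_even**2 + r_odd**2
    if bank.pooling == "sum":
        return float(energy_map.sum())
    return float(energy_map.max())


@dataclass
class EnergyObservation:
    """Clockwise/counterclockwise orientation energies for one trial.

    Raw energies are in arbitrary filter-output units; normalized energies
    are raw divided by a session maximum (fitting mode) or a fixed
    calibration constant (generative mode) and feed the decision model.
    """

    E_ccw_raw: float
    E_cw_raw: float
    E_ccw: float = float("nan")
    E_cw: float = float("nan")

    def __post_init__(self) -> None:
        if self.E_ccw_raw < 0 or self.E_cw_raw < 0:
            raise ValueError("raw energies must be nonnegative")


def stimulus_energies(
    img: LuminanceImage,
    bank: FilterBank,
    theta_ccw: float,
    theta_cw: float,
    freq: float = 1.25,
    background_L0: float | None = None,
) -> EnergyObservation:
    """Raw ccw/cw channel energies of one stimulus image."""
    return EnergyObservation(
        E_ccw_raw=orientation_energy(img, bank, theta_ccw, freq, background_L0),
        E_cw_raw=orientation_energy(img, bank, theta_cw, freq, background_L0),
    )


def normalize_energies(
    observations: list[EnergyObservation], mode: str = "session_max", k: float | None = None
) -> list[EnergyObservation]:
    """Fill normalized energies by a common divisor.

    mode='session_max' divides by the maximum raw energy over the stream (the
    maximum normalized energy is then exactly 1); mode='fixed' divides by the
    calibration constant k > 0.  Ratios between energies are unchanged.
    """
    if not observations:
        raise ValueError("empty energy stream")
    if mode == "session_max":
        divisor = max(max(o.E_ccw_raw, o.E_cw_raw) for o in observations)
        if divisor == 0:
            raise ValueError("all-zero energy stream cannot be max-normalized")
    elif mode == "fixed":
        if k is None or k <= 0:
            raise ValueError("fixed mode requires k > 0")
        divisor = float(k)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return [
        EnergyObservation(
            E_ccw_raw=o.E_ccw_raw,
            E_cw_raw=o.E_cw_raw,
            E_ccw=o.E_ccw_raw / divisor,
            E_cw=o.E_cw_raw / divisor,
        )
        for o in observations
    ]
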