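"""Gabor-in-noise stimulus synthesis.

A stimulus is an additive luminance mixture of an oriented Gabor patch and a
phase-randomized, band-pass filtered noise field,

    L(x, y) = (1 + c_p/100 * G(x, y) + c_n/100 * N(x, y)) * L0,

rendered on a square pixel grid spanning a fixed field of view in degrees of
visual angle, then faded to background luminance through a circular
Butterworth-profile aperture.  All quantities carry physical units: contrasts
in percent, space in degrees, luminance in cd/m^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image


class InvalidSpecError(ValueError):
    """Raised when a stimulus specification violates its invariants."""


@dataclass(frozen=True)
class StimulusSpec:
    """Physical parameters of one Gabor-in-noise stimulus.

    Parameters
    ----------
    peak_contrast_cp : float
        Peak Michelson contrast of the Gabor term, percent in [0, 100].
    noise_contrast_cn : float
        Peak contrast of the noise term, percent (15 throughout the study).
    orientation_theta : float
        Carrier orientation in degrees; +/-20 deg offsets from a reference
        axis at 0 deg (vertical) or 90 deg (horizontal).
    phase_psi : float
        Carrier phase in cycles; the sine argument uses phi = 2*pi*phase_psi.
    spatial_freq_f : float
        Carrier spatial frequency, cycles/degree.
    envelope_sigma : float
        Gaussian envelope SD, degrees.
    background_L0 : float
        Background luminance, cd/m^2.
    n_pixels, extent_deg : int, float
        Square grid size and its span in degrees (300 px over 5.3 deg).
    aperture_radius : float
        Hard crop radius, degrees; pixels beyond it are exactly L0.
    aperture_cutoff, aperture_order : float, int
        Radial Butterworth fade profile of the aperture.
    trim_level : float
        Gabor values with |G| below this are zeroed.
    noise_peak_normalized : bool
        If True (default) the noise field is standardized to unit maximum
        absolute value, making c_n a peak contrast like c_p.
    """

    peak_contrast_cp: float = 100.0
    noise_contrast_cn: float = 15.0
    orientation_theta: float = 20.0
    phase_psi: float = 0.25
    spatial_freq_f: float = 1.25
    envelope_sigma: float = 0.6
    background_L0: float = 51.9
    n_pixels: int = 300
    extent_deg: float = 5.3
    aperture_radius: float = 2.5
    aperture_cutoff: float = 0.275
    aperture_order: int = 7
    trim_level: float = 0.005
    noise_peak_normalized: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_contrast_cp <= 100.0:
            raise InvalidSpecError(
                f"peak_contrast_cp must be in [0, 100], got {self.peak_contrast_cp}"
            )
        if self.envelope_sigma <= 0 or self.spatial_freq_f <= 0:
            raise InvalidSpecError("envelope_sigma and spatial_freq_f must be > 0")
        if self.n_pixels < 2 or self.extent_deg <= 0:
            raise InvalidSpecError("grid must have >=2 pixels and positive extent")

    @property
    def degrees_per_pixel(self) -> float:
        return self.extent_deg / self.n_pixels


@dataclass
class LuminanceImage:
    """A grayscale stimulus in physical luminance units (cd/m^2)."""

    values: np.ndarray
    degrees_per_pixel: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class NoiseField:
    """Zero-mean, band-pass, phase-randomized noise on the stimulus grid."""

    values: np.ndarray
    seed: int


def grid_coordinates(spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in degrees; image center is (0, 0).

    x increases rightward (columns), y downward (rows); with an even number
    of pixels the exact origin falls between the four central pixels.
    """
    dpp = spec.degrees_per_pixel
    coords = (np.arange(spec.n_pixels) + 0.5) * dpp - spec.extent_deg / 2.0
    x, y = np.meshgrid(coords, coords)
    return x, y


def gabor_value(x, y, spec: StimulusSpec) -> np.ndarray:
    """Evaluate the (untrimmed) Gabor function at coordinates in degrees.

    G(x, y) = exp(-(x^2 + y^2) / (2 sigma^2))
              * sin(2 pi f (x cos(theta) + y sin(theta)) + phi)

    with phi = 2 pi * phase_psi, so the default quarter-cycle phase gives
    G(0, 0) = 1 (cosine phase at the envelope peak).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.deg2rad(spec.orientation_theta)
    phi = 2.0 * np.pi * spec.phase_psi
    envelope = np.exp(-(x**2 + y**2) / (2.0 * spec.envelope_sigma**2))
    carrier = np.sin(
        2.0 * np.pi * spec.spatial_freq_f * (x * np.cos(theta) + y * np.sin(theta))
        + phi
    )
    return envelope * carrier


def make_gabor(spec: StimulusSpec) -> np.ndarray:
    """Sample the Gabor term on the stimulus grid and trim small values.

    Values with |G| < spec.trim_level are set to zero.  Note the envelope-only
    trim radius solving exp(-r^2 / (2 sigma^2)) = trim_level is
    sigma * sqrt(2 ln(1/trim_level)), about 1.953 deg for the defaults.
    """
    x, y = grid_coordinates(spec)
    g = gabor_value(x, y, spec)
    g[np.abs(g) < spec.trim_level] = 0.0
    return g


def trim_radius(spec: StimulusSpec) -> float:
    """Radius where the Gaussian envelope alone falls to trim_level, degrees."""
    return spec.envelope_sigma * np.sqrt(2.0 * np.log(1.0 / spec.trim_level))


def _butterworth_lowpass(freq_radius: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    return 1.0 / (1.0 + (freq_radius / cutoff) ** (2 * order))


def noise_band_cutoffs(spec: StimulusSpec) -> tuple[float, float]:
    """Band edges one octave below/above the carrier frequency, cycles/degree."""
    return spec.spatial_freq_f / 2.0, spec.spatial_freq_f * 2.0


def make_noise_field(spec: StimulusSpec) -> NoiseField:
    """Phase-randomized band-pass noise, reproducible from the spec seed.

    The power spectrum is the difference of two order-3 radial Butterworth
    low-pass profiles with cutoffs one octave below and one octave above the
    Gabor carrier frequency; phases are i.i.d. uniform on [0, 2 pi).  The
    field is the real part of the inverse FFT, its DC coefficient is zeroed
    (spatial mean exactly 0) and, by default, it is standardized to unit
    maximum absolute value so that c_n acts as a peak contrast.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_pixels
    freqs = np.fft.fftfreq(n, d=spec.degrees_per_pixel)
    fx, fy = np.meshgrid(freqs, freqs)
    fr = np.hypot(fx, fy)
    lo, hi = noise_band_cutoffs(spec)
    power = _butterworth_lowpass(fr, hi, 3) - _butterworth_lowpass(fr, lo, 3)
    power = np.clip(power, 0.0, None)
    amplitude = np.sqrt(power)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[0, 0] = 0.0
    noise = np.fft.ifft2(spectrum).real
    noise -= noise.mean()  # guard against floating-point residue of the DC zeroing
    if spec.noise_peak_normalized:
        peak = np.max(np.abs(noise))
        if peak > 0:
            noise = noise / peak
    return NoiseField(values=noise, seed=spec.rng_seed)


def aperture_window(r, spec: StimulusSpec) -> np.ndarray:
    """Radial fade profile W(r) = 1 / (1 + (2 f_c r)^(2 n)).

    W(0) = 1 and the half-amplitude radius is 1 / (2 * aperture_cutoff)
    (~1.82 deg for the defaults, inside the 2.5 deg crop).
    """
    r = np.asarray(r, dtype=float)
    return 1.0 / (1.0 + (2.0 * spec.aperture_cutoff * r) ** (2 * spec.aperture_order))


def apply_circular_aperture(img: LuminanceImage, spec: StimulusSpec) -> LuminanceImage:
    """Fade deviations from background through the radial Butterworth window,
    then hard-set pixels beyond aperture_radius to background luminance."""
    x, y = grid_coordinates(spec)
    r = np.hypot(x, y)
    window = aperture_window(r, spec)
    out = spec.background_L0 + (img.values - spec.background_L0) * window
    out[r > spec.aperture_radius] = spec.background_L0
    return LuminanceImage(values=out, degrees_per_pixel=img.degrees_per_pixel)


def compose_stimulus(
    gabor: np.ndarray, noise: NoiseField | np.ndarray, spec: StimulusSpec
) -> LuminanceImage:
    """Mix Gabor and noise into a luminance image and apply the aperture.

    Negative luminances (possible for extreme contrast mixtures) are clipped
    to zero with a warning.
    """
    n_values = noise.values if isinstance(noise, NoiseField) else np.asarray(noise)
    if gabor.shape != n_values.shape:
        raise InvalidSpecError("Gabor and noise grids must match")
    lum = (
        1.0
        + spec.peak_contrast_cp / 100.0 * gabor
        + spec.noise_contrast_cn / 100.0 * n_values
    ) * spec.background_L0
    if np.any(lum < 0):
        warnings.warn("luminance mixture fell below 0 cd/m^2; clipping", stacklevel=2)
        lum = np.clip(lum, 0.0, None)
    img = LuminanceImage(values=lum, degrees_per_pixel=spec.degrees_per_pixel)
    return apply_circular_aperture(img, spec)


def make_stimulus(spec: StimulusSpec) -> LuminanceImage:
    """Full pipeline: Gabor + seeded noise + mixture + aperture."""
    return compose_stimulus(make_gabor(spec), make_noise_field(spec), spec)


# --- PNG + JSON sidecar I/O ------------------------------------------------

_PNG_MAX = 65535


def write_stimulus_png(img: LuminanceImage, spec: StimulusSpec, path: str | Path) -> None:
    """Write a 16-bit grayscale PNG plus a JSON sidecar with spec and scale."""
    path = Path(path)
    peak = float(img.values.max())
    scale = peak / _PNG_MAX if peak > 0 else 1.0
    data = np.round(img.values / scale).astype(np.uint16)
    Image.fromarray(data).save(path)
    sidecar = {
        "luminance_per_level": scale,
        "degrees_per_pixel": img.degrees_per_pixel,
        "spec": asdict(spec),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stimulus_png(path: str | Path) -> tuple[LuminanceImage, StimulusSpec]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    data = np.asarray(Image.open(path), dtype=float) * sidecar["luminance_per_level"]
    spec = StimulusSpec(**sidecar["spec"])
    return LuminanceImage(values=data, degrees_per_pixel=sidecar["degrees_per_pixel"]), spec
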