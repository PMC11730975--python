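"""Stimulus synthesis and synthetic ground truth.

Generates every stimulus class the analysis operates on:

* vertical sinusoidal gratings (and a high-contrast stripe-texture surrogate
  for op-art, clearly a surrogate and not a reproduction of any artwork);
* band-pass "bump" noise -- white Gaussian noise shaped in the frequency
  domain by a raised radial cosine centred, in log2 spatial frequency, at a
  chosen frequency f0 (T = 0.9, beta = 0.5);
* random-phase 1/f^k noise standing in for natural photographs (natural
  images have k near -1);
* a Gaussian-edged circular window (flat radius 150 px, sigma 10 px) and a
  5 Hz raised-sinusoid temporal contrast envelope;
* synthetic 1-7 discomfort ratings from a linear mixed model with observer
  random intercepts, and synthetic SSVEP EEG (5 Hz fundamental + 10 Hz
  harmonic on posterior channels over 1/f background noise).

Luminance is dimensionless in [0, 1] with 0.5 mid-gray; every generator is
bit-reproducible given its spec and seed.

Bump-filter convention: the raised radial cosine is a standard raised-cosine
window in nu = log2(f/f0): gain 1 for |nu| <= (1-beta)/(2T), cosine roll-off
to 0 at |nu| = (1+beta)/(2T).  With T = 0.9, beta = 0.5 the passband is flat
over +/-0.28 octaves and reaches zero at +/-0.83 octaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_PPD
from .ssvep import EEGRecording, POSTERIOR_CHANNELS

CATEGORIES = ("grating", "bump", "onef_noise", "stripe_texture", "external")

#: compact synthetic montage: the nine posterior channels of interest,
#: linked-mastoid references, and a handful of midline/frontal sites
DEFAULT_MONTAGE = POSTERIOR_CHANNELS + ("Pz", "Cz", "Fz", "F3", "F4", "M1", "M2")


class CalibrationError(ValueError):
    """Raised when a requested spatial frequency exceeds the Nyquist limit."""


@dataclass
class ImageStimulus:
    """Calibrated grayscale image: luminance in [0, 1], 0.5 = mid-gray."""

    pixels: np.ndarray
    ppd: float
    category: str = "external"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixel values outside [0, 1]: [{lo}, {hi}]")
        if self.ppd <= 0:
            raise CalibrationError("pixels-per-degree must be positive")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def nyquist_cpd(self) -> float:
        return self.ppd / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GratingSpec:
    frequency: float          # c/deg
    orientation: float = 0.0  # deg; 0 = vertical grating (horizontal modulation)
    contrast: float = 1.0     # Michelson
    size: int = 512
    phase: float = 0.0        # radians

    def validate(self, ppd: float) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.frequency >= ppd / 2.0:
            raise CalibrationError(
                f"{self.frequency} c/deg is at or above Nyquist ({ppd / 2} c/deg)"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.size < 2:
            raise ValueError("size must be at least 2 pixels")


@dataclass(frozen=True)
class BumpSpec:
    f0: float                # centre frequency, c/deg
    T: float = 0.9
    beta: float = 0.5
    size: int = 512
    seed: int = 0

    def validate(self, ppd: float) -> None:
        if self.f0 <= 0:
            raise ValueError("centre frequency must be positive")
        if self.f0 >= ppd / 2.0:
            raise CalibrationError(
                f"f0={self.f0} c/deg is at or above Nyquist ({ppd / 2} c/deg)"
            )
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.T <= 0:
            raise ValueError("T must be positive")


@dataclass
class SyntheticGroundTruth:
    """Generative parameters behind the synthetic ratings and EEG."""

    rating_coefficients: dict[str, float]
    observer_sd: float = 0.5
    residual_sd: float = 1.0
    ssvep_amplitude_map: dict = field(default_factory=dict)  # condition -> uV
    intercept: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observer_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def _pixel_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return x - c, y - c


def make_grating(spec: GratingSpec, ppd: float = DEFAULT_PPD) -> ImageStimulus:
    """Sinusoid around 0.5 with Michelson contrast ``spec.contrast``."""
    spec.validate(ppd)
    x, y = _pixel_grid(spec.size)
    th = np.radians(spec.orientation)
    coord = x * np.cos(th) + y * np.sin(th)
    f_cpp = spec.frequency / ppd  # cycles per pixel
    pixels = 0.5 + 0.5 * spec.contrast * np.cos(2 * np.pi * f_cpp * coord + spec.phase)
    return ImageStimulus(pixels, ppd, "grating")


def make_stripe_texture(
    frequency: float,
    ppd: float = DEFAULT_PPD,
    size: int = 512,
    contrast: float = 1.0,
    wiggle_amp_px: float = 0.0,
    wiggle_period_px: float = 64.0,
    phase: float = 0.0,
) -> ImageStimulus:
    """High-contrast square-wave stripes; op-art surrogate.

    ``wiggle_amp_px`` bends the stripes sinusoidally along their length for
    an op-art-like appearance.  This is a labelled surrogate for striped
    artworks, not a reproduction of any artwork.
    """
    if frequency >= ppd / 2.0:
        raise CalibrationError(f"{frequency} c/deg at/above Nyquist ({ppd / 2})")
    x, y = _pixel_grid(size)
    coord = x + wiggle_amp_px * np.sin(2 * np.pi * y / wiggle_period_px)
    carrier = np.cos(2 * np.pi * frequency / ppd * coord + phase)
    pixels = 0.5 + 0.5 * contrast * np.sign(carrier)
    return ImageStimulus(pixels, ppd, "stripe_texture")


def raised_cosine_gain(
    f: np.ndarray, f0: float, T: float = 0.9, beta: float = 0.5
) -> np.ndarray:
    """Raised-cosine amplitude gain in log2 spatial frequency.

    Gain is 1 for |log2(f/f0)| <= (1-beta)/(2T), rolls off as a half cosine,
    and is 0 beyond |log2(f/f0)| = (1+beta)/(2T).  Zero at f = 0.
    """
    f = np.asarray(f, dtype=float)
    gain = np.zeros_like(f)
    pos = f > 0
    nu = np.abs(np.log2(f[pos] / f0))
    flat = (1 - beta) / (2 * T)
    edge = (1 + beta) / (2 * T)
    g = np.zeros_like(nu)
    g[nu <= flat] = 1.0
    roll = (nu > flat) & (nu < edge)
    g[roll] = 0.5 * (1 + np.cos(np.pi * T / beta * (nu[roll] - flat)))
    gain[pos] = g
    return gain


def _freq_grid_cpd(size: int, ppd: float) -> np.ndarray:
    fx = np.fft.fftfreq(size)[None, :] * ppd
    fy = np.fft.fftfreq(size)[:, None] * ppd
    return np.hypot(fx, fy)


def _rescale_midgray(field_: np.ndarray) -> np.ndarray:
    """Linear rescale of a zero-mean field into [0, 1] about 0.5.

    Max-|deviation| normalisation preserves the spectral shape (no clipping);
    only the DC term is touched.
    """
    dev = field_ - field_.mean()
    m = np.abs(dev).max()
    if m == 0:
        return np.full_like(field_, 0.5)
    return 0.5 + 0.5 * dev / m


def make_bump_noise(spec: BumpSpec, ppd: float = DEFAULT_PPD) -> ImageStimulus:
    """Band-pass noise: white noise filtered by the raised radial cosine."""
    spec.validate(ppd)
    upper_edge = spec.f0 * 2 ** ((1 + spec.beta) / (2 * spec.T))
    if upper_edge > ppd / 2.0:
        warnings.warn(
            f"bump roll-off (to {upper_edge:.2f} c/deg) extends past Nyquist "
            f"({ppd / 2:.2f} c/deg); filter truncated",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.size, spec.size))
    f = _freq_grid_cpd(spec.size, ppd)
    gain = raised_cosine_gain(f, spec.f0, spec.T, spec.beta)
    shaped = np.fft.ifft2(np.fft.fft2(noise) * gain).real
    return ImageStimulus(_rescale_midgray(shaped), ppd, "bump")


def make_onef_noise(
    k: float, size: int = 512, seed: int = 0, ppd: float = DEFAULT_PPD
) -> ImageStimulus:
    """Random-phase noise with amplitude spectrum exactly proportional to f^k.

    The amplitudes are set deterministically to f^k (DC to zero before the
    mid-gray rescale); only the phases are random, so the construction is its
    own oracle for the spectral-slope estimator.
    """
    if not -3.0 <= k <= 1.0:
        raise ValueError("exponent k must lie in [-3, 1]")
    if size < 8:
        raise ValueError("size must be at least 8 pixels")
    rng = np.random.default_rng(seed)
    phases = np.angle(np.fft.fft2(rng.standard_normal((size, size))))
    f = _freq_grid_cpd(size, ppd)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** k
    field_ = np.fft.ifft2(amp * np.exp(1j * phases)).real
    return ImageStimulus(_rescale_midgray(field_), ppd, "onef_noise")


def apply_gaussian_window(
    img: ImageStimulus, flat_radius_px: int = 150, sigma_px: float = 10.0
) -> ImageStimulus:
    """Gaussian-edged circular window: contrast intact inside the flat radius,
    attenuated by a Gaussian of the radial overshoot outside, 0.5 far field."""
    h, w = img.shape
    if 2 * flat_radius_px > min(h, w):
        raise ValueError(
            f"flat radius {flat_radius_px} px does not fit a {h}x{w} image"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - (w - 1) / 2.0, yy - (h - 1) / 2.0)
    over = np.maximum(r - flat_radius_px, 0.0)
    env = np.exp(-(over**2) / (2 * sigma_px**2))
    pixels = 0.5 + (img.pixels - 0.5) * env
    return ImageStimulus(pixels, img.ppd, img.category)


def temporal_contrast_envelope(
    rate_hz: float = 5.0, duration_s: float = 20.0, frame_rate_hz: float = 60.0
) -> np.ndarray:
    """Raised-sinusoid contrast multiplier in [0, 1] at ``rate_hz``.

    The stimulus fades in and out of mid-gray so the space-average luminance
    is constant over time; the envelope starts at zero contrast.
    """
    if frame_rate_hz <= 2 * rate_hz:
        raise ValueError("frame rate must exceed twice the modulation rate")
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    return 0.5 * (1 - np.cos(2 * np.pi * rate_hz * t))


def standardize_columns(
    table: pd.DataFrame, columns: list[str], suffix: str = "_z"
) -> pd.DataFrame:
    """Return a copy with z-scored versions of ``columns`` appended."""
    out = table.copy()
    for col in columns:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col + suffix] = (v - v.mean()) / sd
    return out


def generate_synthetic_ratings(
    stats_table: pd.DataFrame,
    truth: SyntheticGroundTruth,
    n_observers: int = 11,
    predictors: list[str] | None = None,
    discretize: bool = False,
) -> pd.DataFrame:
    """Simulate discomfort ratings from a linear mixed model.

    rating = intercept + X @ beta + observer intercept + residual noise,
    clipped to the 1-7 scale (``discretize=True`` additionally rounds to the
    integer Likert points).  Predictor columns are used as-is and should be
    standardized by the caller.  Deterministic given ``truth.seed``.
    """
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    predictors = predictors or list(truth.rating_coefficients)
    X = stats_table[predictors].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors contain non-finite values")
    beta = np.array([truth.rating_coefficients[p] for p in predictors])
    mu_fixed = truth.intercept + X @ beta

    rng = np.random.default_rng(truth.seed)
    image_ids = (
        stats_table["image_id"].tolist()
        if "image_id" in stats_table.columns
        else list(stats_table.index)
    )
    frames = []
    for o in range(n_observers):
        b_o = rng.normal(0.0, truth.observer_sd) if truth.observer_sd > 0 else 0.0
        eps = (
            rng.normal(0.0, truth.residual_sd, size=len(X))
            if truth.residual_sd > 0
            else np.zeros(len(X))
        )
        rating = np.clip(mu_fixed + b_o + eps, 1.0, 7.0)
        if discretize:
            rating = np.clip(np.rint(rating), 1, 7)
        block = stats_table.copy()
        block.insert(0, "observer", f"obs{o:02d}")
        block["image_id"] = image_ids
        block["rating"] = rating
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def _pink_noise(
    n_samples: int, fs: float, rms_uv: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f-power background noise (amplitude ~ f^-0.5, flattened below 0.5 Hz)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.maximum(f, 0.5) ** -0.5
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n_samples)
    sd = x.std()
    return x * (rms_uv / sd) if sd > 0 else x


def generate_synthetic_eeg(
    conditions: list,
    truth: SyntheticGroundTruth,
    labels: tuple[str, ...] = DEFAULT_MONTAGE,
    fs_hz: float = 256.0,
    epoch_s: float = 20.0,
    pre_s: float = 2.0,
    noise_rms_uv: float = 1.0,
    harmonic_ratio: float = 0.25,
    artifacts: list[tuple[object, int]] = (),
    artifact_uv: float = 600.0,
    seed: int | None = None,
) -> EEGRecording:
    """Synthesize an SSVEP recording: one 20 s trial per condition.

    Posterior channels carry a 5 Hz sinusoid at the condition's amplitude
    (from ``truth.ssvep_amplitude_map``) plus a 10 Hz harmonic at
    ``harmonic_ratio`` of it; all channels carry independent 1/f background
    noise.  ``artifacts`` is a list of (condition, sub_epoch_index) pairs
    (sub-epoch 0 = the first 2 s of the trial); each receives a 1 s
    ``artifact_uv`` pulse centred in the sub-epoch so that exactly those
    sub-epochs exceed a +/-500 uV rejection threshold downstream.
    """
    if fs_hz < 256:
        raise ValueError("sampling rate must be at least 256 Hz")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    labels = tuple(labels)
    n_ch = len(labels)
    trial_len = int(round((pre_s + epoch_s) * fs_hz))
    total = trial_len * len(conditions) + int(round(fs_hz))
    data = np.zeros((n_ch, total))
    if noise_rms_uv > 0:
        for ch in range(n_ch):
            data[ch] += _pink_noise(total, fs_hz, noise_rms_uv, rng)

    posterior_idx = [labels.index(c) for c in POSTERIOR_CHANNELS if c in labels]
    events: list[tuple[int, object]] = []
    n_epoch = int(round(epoch_s * fs_hz))
    t = np.arange(n_epoch) / fs_hz
    for ci, cond in enumerate(conditions):
        onset = ci * trial_len + int(round(pre_s * fs_hz))
        events.append((onset, cond))
        a = float(truth.ssvep_amplitude_map.get(cond, 0.0))
        sig = a * np.sin(2 * np.pi * 5.0 * t) + harmonic_ratio * a * np.sin(
            2 * np.pi * 10.0 * t
        )
        for ch in posterior_idx:
            data[ch, onset : onset + n_epoch] += sig

    # artifacts are injected everywhere except the mastoid references so
    # they survive linked-mastoid re-referencing (a common-mode pulse would
    # be subtracted out)
    scalp_idx = [i for i, lab in enumerate(labels) if lab not in ("M1", "M2")]
    n_burst = int(round(fs_hz))
    burst = artifact_uv * np.sin(2 * np.pi * 10.0 * np.arange(n_burst) / fs_hz)
    for cond, sub_idx in artifacts:
        ci = conditions.index(cond)
        onset = ci * trial_len + int(round(pre_s * fs_hz))
        s0 = onset + int(round((sub_idx * 2.0 + 0.5) * fs_hz))
        # in-band (10 Hz) burst centred in the sub-epoch: passes the
        # 0.1-40 Hz filter at unity gain, so exactly the targeted
        # sub-epochs exceed the rejection threshold
        data[np.ix_(scalp_idx, range(s0, s0 + n_burst))] += burst[None, :]

    return EEGRecording(data, fs_hz, labels, events)
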