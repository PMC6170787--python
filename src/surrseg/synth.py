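"""Synthetic multichannel signal generators.

Generates signals with the structure the downstream analysis assumes: a
dominant cyclic component (a sinusoid with random phase, default 10 Hz)
superimposed on 1/f^beta background noise, with optional linear
cross-channel mixing and optional genuine nonlinearity (quadratic phase
coupling or a Henon-map component) used as a positive control.

All generators are deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .recording import MultichannelRecording

__all__ = [
    "SynthConfig",
    "generate_linear_cyclic",
    "generate_nonlinear",
    "spectral_peak_frequency",
    "colored_noise",
    "henon_series",
]

NONLINEARITY_KINDS = ("none", "quadratic_phase_coupling", "henon_component")

HENON_A = 1.4
HENON_B = 0.3


@dataclass
class SynthConfig:
    """Configuration for the synthetic generators.

    ``alpha_rel_power`` is the fraction of each pre-mixing column's unit
    variance contributed by the cyclic component; it may be a scalar
    (shared by all channels) or one value per channel.
    """

    duration_s: float
    sampling_rate_hz: float = 1000.0
    alpha_freq_hz: float = 10.0
    alpha_rel_power: float | Sequence[float] = 0.5
    noise_exponent: float = 1.0
    channel_labels: Sequence[str] = ("ch0",)
    cross_channel_mixing: np.ndarray | None = None
    nonlinearity: str = "none"
    nonlinearity_strength: float = 0.0
    qpc_freqs_hz: tuple[float, float] = (10.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.alpha_freq_hz <= 0:
            raise ValueError("alpha_freq_hz must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if self.nonlinearity not in NONLINEARITY_KINDS:
            raise ValueError(
                f"nonlinearity must be one of {NONLINEARITY_KINDS}"
            )
        if self.nonlinearity_strength < 0:
            raise ValueError("nonlinearity_strength must be >= 0")
        self.channel_labels = [str(c) for c in self.channel_labels]
        powers = np.atleast_1d(np.asarray(self.alpha_rel_power, dtype=float))
        if powers.size == 1:
            powers = np.full(len(self.channel_labels), powers[0])
        if powers.size != len(self.channel_labels):
            raise ValueError("alpha_rel_power length must match channel count")
        if np.any(powers < 0) or np.any(powers > 1):
            raise ValueError("alpha_rel_power must lie in [0, 1]")
        self.alpha_rel_power = powers
        if self.cross_channel_mixing is not None:
            mix = np.asarray(self.cross_channel_mixing, dtype=float)
            n = len(self.channel_labels)
            if mix.shape != (n, n):
                raise ValueError(
                    f"mixing matrix shape {mix.shape} does not match "
                    f"{n} channels"
                )
            self.cross_channel_mixing = mix

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def implied_covariance(self) -> np.ndarray:
        """Channel covariance implied by the mixing matrix (M @ M.T)."""
        if self.cross_channel_mixing is None:
            return np.eye(self.n_channels)
        m = self.cross_channel_mixing
        return m @ m.T


def colored_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance, zero-mean 1/f^exponent noise by spectral shaping.

    White Gaussian noise is transformed to the frequency domain, each
    positive-frequency bin is scaled by ``f**(-exponent/2)`` (DC set to
    zero) and the result transformed back, so the target slope is exact
    in expectation and the series is stationary by construction.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    white = rng.standard_normal(n)
    if exponent == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** (-exponent / 2.0)
        out = np.fft.irfft(spec * scale, n=n)
    out = out - out.mean()
    sd = out.std()
    if sd == 0:
        raise ValueError("degenerate noise draw")
    return out / sd


def henon_series(
    n: int,
    a: float = HENON_A,
    b: float = HENON_B,
    x0: float = 0.0,
    y0: float = 0.0,
    discard: int = 1000,
) -> np.ndarray:
    """x-coordinate of the Henon map, transients discarded, standardized."""
    total = n + discard
    xs = np.empty(total)
    x, y = x0, y0
    for i in range(total):
        x, y = 1.0 - a * x * x + y, b * x
        if not np.isfinite(x):
            raise ValueError("Henon iteration diverged; bad initial condition")
        xs[i] = x
    out = xs[discard:]
    out = out - out.mean()
    return out / out.std()


def _sinusoid(n: int, rate: float, freq: float, phase: float) -> np.ndarray:
    """Unit-variance sinusoid (amplitude sqrt(2))."""
    t = np.arange(n) / rate
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * freq * t + phase)


def _linear_columns(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent pre-mixing columns: cyclic component + colored noise."""
    n = config.n_samples
    cols = np.empty((n, config.n_channels))
    for c in range(config.n_channels):
        p = float(config.alpha_rel_power[c])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        cyc = _sinusoid(n, config.sampling_rate_hz, config.alpha_freq_hz, phase)
        noise = colored_noise(n, config.noise_exponent, rng)
        cols[:, c] = np.sqrt(p) * cyc + np.sqrt(1.0 - p) * noise
    return cols


def _mix(config: SynthConfig, cols: np.ndarray) -> MultichannelRecording:
    if config.cross_channel_mixing is not None:
        cols = cols @ config.cross_channel_mixing.T
    return MultichannelRecording(
        samples=cols,
        sampling_rate_hz=config.sampling_rate_hz,
        channel_labels=list(config.channel_labels),
    )


def generate_linear_cyclic(config: SynthConfig) -> MultichannelRecording:
    """Generate a linear-by-construction cyclic recording.

    Each pre-mixing column is ``sqrt(p) * sinusoid + sqrt(1-p) * noise``
    with unit variance; columns are then combined by the mixing matrix.
    Under this process the phase-randomization null hypothesis is true up
    to the deterministic cyclic component.
    """
    if config.nonlinearity != "none":
        raise ValueError("generate_linear_cyclic requires nonlinearity='none'")
    if config.n_samples < 2 * config.sampling_rate_hz / config.alpha_freq_hz:
        raise ValueError("duration must cover at least two cyclic periods")
    rng = np.random.default_rng(config.seed)
    return _mix(config, _linear_columns(config, rng))


def _nonlinear_columns(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    cols = np.empty((n, config.n_channels))
    t = np.arange(n) / config.sampling_rate_hz
    for c in range(config.n_channels):
        if config.nonlinearity == "henon_component":
            x0 = rng.uniform(-0.1, 0.1)
            y0 = rng.uniform(-0.1, 0.1)
            comp = henon_series(n, x0=x0, y0=y0)
        else:  # quadratic_phase_coupling
            f1, f2 = config.qpc_freqs_hz
            p1 = rng.uniform(0.0, 2.0 * np.pi)
            p2 = rng.uniform(0.0, 2.0 * np.pi)
            raw = (
                np.sin(2 * np.pi * f1 * t + p1)
                + np.sin(2 * np.pi * f2 * t + p2)
                + np.sin(2 * np.pi * (f1 + f2) * t + p1 + p2)
            )
            raw = raw - raw.mean()
            comp = raw / raw.std()
        cols[:, c] = comp
    return cols


def generate_nonlinear(config: SynthConfig) -> MultichannelRecording:
    """Generate a recording with a genuinely nonlinear component.

    The output column is ``sqrt(1-s) * linear + sqrt(s) * component``
    where ``s = nonlinearity_strength`` and the component (Henon series
    or quadratically phase-coupled triplet) is standardized, so ``s`` is
    a variance fraction.  At ``s = 0`` the output is bitwise identical to
    :func:`generate_linear_cyclic` with the same seed.
    """
    if config.nonlinearity == "none":
        raise ValueError("generate_nonlinear requires nonlinearity != 'none'")
    if not 0.0 <= config.nonlinearity_strength <= 1.0:
        raise ValueError("nonlinearity_strength must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    linear = _linear_columns(replace(config, nonlinearity="none"), rng)
    s = config.nonlinearity_strength
    if s == 0.0:
        return _mix(config, linear)
    nonlin = _nonlinear_columns(config, rng)
    cols = np.sqrt(1.0 - s) * linear + np.sqrt(s) * nonlin
    return _mix(config, cols)


def spectral_peak_frequency(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float] = (1.0, 45.0),
) -> float:
    """Frequency of the maximum of a smoothed PSD within ``band``.

    Uses Welch's method with ~0.25 Hz resolution (or the best the series
    allows).  Raises on series shorter than 2 s or with zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2 * rate:
        raise ValueError("need at least 2 s of samples")
    if np.std(x) == 0:
        raise ValueError("zero-variance series has no spectral peak")
    nperseg = min(len(x), int(4 * rate))
    freqs, psd = sps.welch(x, fs=rate, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"no PSD bins inside band {band}")
    return float(freqs[mask][np.argmax(psd[mask])])
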