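"""Zero-phase band-pass filtering, cycle-peak detection and stationarity screening."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import MultichannelRecording

__all__ = [
    "BandDefinition",
    "BANDS",
    "StationarityResult",
    "average_reference",
    "bandpass_zero_phase",
    "detect_cycle_peaks",
    "stationarity_screen",
    "phillips_perron",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges ({self.low_hz}, {self.high_hz})")


#: The analysis bands: four narrow bands keyed to physiological rhythms
#: plus the broadband analysis range.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 1.5),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 7.5, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "broadband": BandDefinition("broadband", 1.0, 45.0),
}


def _resolve_band(band: BandDefinition | str) -> BandDefinition:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    return band


def bandpass_zero_phase(
    rec: MultichannelRecording,
    band: BandDefinition | str,
    order: int = 4,
) -> MultichannelRecording:
    """Forward-backward Butterworth band-pass (zero phase shift).

    ``order`` is the per-pass order; the effective magnitude response is
    the square of a Butterworth of that order.
    """
    band = _resolve_band(band)
    nyquist = rec.sampling_rate_hz / 2.0
    if band.high_hz >= nyquist:
        raise ValueError(
            f"band edge {band.high_hz} Hz >= Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(
        order,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=rec.sampling_rate_hz,
        output="sos",
    )
    ntaps = sos.shape[0]
    padlen = 3 * (2 * ntaps + 1)
    if rec.n_samples <= 3 * padlen:
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for zero-phase "
            f"filtering at order {order}"
        )
    filtered = sps.sosfiltfilt(sos, rec.samples, axis=0, padlen=padlen)
    return rec.with_samples(filtered)


def detect_cycle_peaks(
    rec: MultichannelRecording,
    channel: int | str,
    band: BandDefinition | str = "alpha",
    order: int = 4,
) -> np.ndarray:
    """Sample indices of local maxima of the band-filtered channel.

    Peaks closer than half the shortest in-band period are de-duplicated
    (the larger one is kept), suppressing ripple-induced double peaks.
    """
    band = _resolve_band(band)
    filtered = bandpass_zero_phase(rec, band, order=order)
    x = filtered.channel(channel)
    min_spacing = max(1, int(round(0.5 * rec.sampling_rate_hz / band.high_hz)))
    peaks, _ = sps.find_peaks(x, distance=min_spacing)
    if len(peaks) == 0:
        raise ValueError("no cycle peaks found (flat or degenerate signal)")
    return peaks


def average_reference(rec: MultichannelRecording) -> MultichannelRecording:
    """Re-reference each sample to the instantaneous channel mean.

    Optional toggle for real multichannel data; synthetic cohorts need
    no re-referencing.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=1, keepdims=True))


@dataclass
class StationarityResult:
    """Outcome of a single stationarity test at the 5% level."""

    test_name: str
    statistic: float
    p_value: float
    stationary_at_5pct: bool


def phillips_perron(x: np.ndarray, lags: int | None = None) -> tuple[float, float]:
    """Phillips-Perron Z-tau unit-root test (constant, no trend).

    Returns ``(statistic, p_value)``.  The statistic is the serial-
    correlation-robust correction of the Dickey-Fuller t-ratio, using a
    Bartlett-kernel (Newey-West) long-run variance; p-values come from
    the MacKinnon response-surface for the Dickey-Fuller distribution,
    which is the asymptotic law of Z-tau.
    """
    from statsmodels.tsa.adfvalues import mackinnonp

    x = np.asarray(x, dtype=float).ravel()
    n = len(x) - 1
    if n < 10:
        raise ValueError("series too short for Phillips-Perron test")
    y, ylag = x[1:], x[:-1]
    design = np.column_stack([np.ones(n), ylag])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    s2 = resid @ resid / (n - 2)
    xtx_inv = np.linalg.inv(design.T @ design)
    se_rho = np.sqrt(s2 * xtx_inv[1, 1])
    tau = (beta[1] - 1.0) / se_rho

    if lags is None:
        lags = int(np.ceil(12.0 * (n / 100.0) ** 0.25))
    gamma0 = resid @ resid / n
    lam2 = gamma0
    for j in range(1, lags + 1):
        gj = resid[j:] @ resid[:-j] / n
        lam2 += 2.0 * (1.0 - j / (lags + 1.0)) * gj
    lam2 = max(lam2, np.finfo(float).tiny)

    lam = np.sqrt(lam2)
    s = np.sqrt(s2)
    stat = np.sqrt(gamma0 / lam2) * tau - (lam2 - gamma0) * n * se_rho / (2.0 * lam * s)
    p = float(mackinnonp(stat, regression="c", N=1))
    return float(stat), p


def stationarity_screen(x: np.ndarray) -> list[StationarityResult]:
    """Run the KPSS and Phillips-Perron tests at the 5% level.

    KPSS has stationarity as its null (level-stationarity variant); PP
    has a unit root as its null.  The screen passes when KPSS fails to
    reject AND PP rejects, i.e. both tests agree the series is
    stationary.
    """
    from statsmodels.tsa.stattools import kpss

    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("need at least 100 samples for stationarity screening")
    if np.std(x) == 0:
        raise ValueError("constant series: stationarity tests undefined")

    with warnings.catch_warnings():
        # statsmodels warns when the statistic falls outside its p-value
        # interpolation table; the clamped value is what we want.
        warnings.simplefilter("ignore")
        kpss_stat, kpss_p, *_ = kpss(x, regression="c", nlags="auto")
    pp_stat, pp_p = phillips_perron(x)

    return [
        StationarityResult("KPSS", float(kpss_stat), float(kpss_p), kpss_p > 0.05),
        StationarityResult("PP", pp_stat, pp_p, pp_p < 0.05),
    ]


def screen_passes(results: list[StationarityResult]) -> bool:
    """True when every test in the screen judged the series stationary."""
    return all(r.stationary_at_5pct for r in results)
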