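"""End-matched segmentation keyed to the dominant cyclic component.

A base segment runs from one detected cycle peak to the peak nearest a
target length, so it spans an integer number ``k`` of realized periods
``T``.  Incremented variants keep the start fixed and extend the window
by ``delta_t`` milliseconds, deliberately breaking the end-match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .preprocess import BandDefinition, _resolve_band
from .recording import MultichannelRecording

__all__ = [
    "SegmentPlan",
    "Segment",
    "delta_t_series",
    "extract_end_matched",
    "increment_segment",
    "plan_consecutive_end_matched",
    "write_manifest",
]

# (step_ms, stop_ms) of the delta-t grid per band; each grid runs from 0
# to roughly one period of the band's cyclic component.
_DELTA_T_GRIDS: dict[str, tuple[float, float]] = {
    "delta": (20.0, 1000.0),
    "theta": (3.0, 126.0),
    "alpha": (2.0, 108.0),
    "beta": (1.0, 46.0),
}


@dataclass(frozen=True)
class SegmentPlan:
    """Bookkeeping for one analysis window: length = k*T + delta_t.

    ``length_samples`` counts both end points, i.e. it equals
    ``round((k*T_ms + delta_t_ms) * rate / 1000) + 1`` so that a k-period
    window of a sampled sinusoid starts and ends exactly on peaks.
    """

    k: int
    T_ms: float
    delta_t_ms: float
    start_index: int
    length_samples: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.T_ms <= 0:
            raise ValueError("T_ms must be positive")
        if self.delta_t_ms < 0:
            raise ValueError("delta_t_ms must be non-negative")
        if self.start_index < 0 or self.length_samples < 2:
            raise ValueError("invalid window bounds")


@dataclass
class Segment:
    """Extracted samples plus the plan that produced them."""

    samples: np.ndarray
    plan: SegmentPlan
    sampling_rate_hz: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n = self.samples.shape[0]
        if n != self.plan.length_samples:
            raise ValueError(
                f"sample count {n} does not match plan length "
                f"{self.plan.length_samples}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains NaN or Inf")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def delta_t_series(band: BandDefinition | str) -> np.ndarray:
    """The delta-t grid (ms) for one of the four named bands."""
    band = _resolve_band(band)
    if band.name not in _DELTA_T_GRIDS:
        raise ValueError(f"no delta-t series defined for band {band.name!r}")
    step, stop = _DELTA_T_GRIDS[band.name]
    n = int(round(stop / step)) + 1
    return step * np.arange(n)


def _slice_channels(
    rec: MultichannelRecording, channels: Sequence[int | str] | None
) -> tuple[np.ndarray, list[str]]:
    if channels is None:
        return rec.samples, list(rec.channel_labels)
    idx = [rec.channel_index(c) for c in channels]
    return rec.samples[:, idx], [rec.channel_labels[i] for i in idx]


def extract_end_matched(
    rec: MultichannelRecording,
    peaks: np.ndarray,
    target_length_s: float,
    start_peak: int = 0,
    channels: Sequence[int | str] | None = None,
) -> Segment:
    """Cut a segment spanning whole cyclic periods, peak to peak.

    The window starts at ``peaks[start_peak]`` and ends at the detected
    peak nearest ``target_length_s`` later; ``k`` is the number of
    inter-peak intervals spanned and ``T`` their mean.  The realized
    length may deviate from the target by up to half a period.
    If ``channels`` selects a single channel the samples are 1-D.
    """
    peaks = np.asarray(peaks, dtype=int)
    rate = rec.sampling_rate_hz
    if start_peak >= len(peaks) - 1:
        raise ValueError("not enough peaks after start_peak")
    p0 = int(peaks[start_peak])
    target_samples = target_length_s * rate
    spans = peaks[start_peak + 1 :] - p0
    end_offset = int(np.argmin(np.abs(spans - target_samples)))
    k = end_offset + 1
    p_end = int(peaks[start_peak + 1 + end_offset])
    if k < 2:
        raise ValueError("target length must cover at least two periods")
    span = p_end - p0
    T_ms = span / k * 1000.0 / rate
    plan = SegmentPlan(
        k=k, T_ms=T_ms, delta_t_ms=0.0, start_index=p0, length_samples=span + 1
    )
    data, labels = _slice_channels(rec, channels)
    samples = data[p0 : p_end + 1]
    if samples.shape[1] == 1:
        samples = samples[:, 0]
    return Segment(samples, plan, rate, labels)


def increment_segment(
    rec: MultichannelRecording,
    base: SegmentPlan,
    delta_t_ms: float,
    channels: Sequence[int | str] | None = None,
) -> Segment:
    """Re-cut the base window extended by ``delta_t_ms`` at the end.

    The start index is unchanged; the length grows by
    ``round(delta_t_ms * rate / 1000)`` samples (round half up; at
    1000 Hz all standard grids yield integers).
    """
    if delta_t_ms < 0:
        raise ValueError("delta_t_ms must be non-negative")
    rate = rec.sampling_rate_hz
    extra = _round_half_up(delta_t_ms * rate / 1000.0)
    base0 = replace(base, delta_t_ms=0.0)
    length = base.length_samples + extra
    stop = base.start_index + length
    if stop > rec.n_samples:
        raise ValueError(
            f"extended window [{base.start_index}, {stop}) exceeds recording "
            f"length {rec.n_samples}"
        )
    plan = SegmentPlan(
        k=base0.k,
        T_ms=base0.T_ms,
        delta_t_ms=float(delta_t_ms),
        start_index=base0.start_index,
        length_samples=length,
    )
    data, labels = _slice_channels(rec, channels)
    samples = data[base.start_index : stop]
    if samples.shape[1] == 1:
        samples = samples[:, 0]
    return Segment(samples, plan, rate, labels)


def write_manifest(
    plans: Sequence[SegmentPlan],
    path,
    subject: str = "subject0",
    channel: str = "ch0",
) -> None:
    """Write segment plans as a delimited-text manifest table."""
    header = "subject\tchannel\tstart_index\tk\tT_ms\tdelta_t_ms\tlength_samples"
    lines = [header]
    for p in plans:
        lines.append(
            f"{subject}\t{channel}\t{p.start_index}\t{p.k}\t{p.T_ms:.6g}\t"
            f"{p.delta_t_ms:.6g}\t{p.length_samples}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def plan_consecutive_end_matched(
    rec: MultichannelRecording,
    peaks: np.ndarray,
    target_length_s: float,
    n_segments: int,
    gap_samples: int = 0,
) -> list[SegmentPlan]:
    """Plans for ``n_segments`` non-overlapping end-matched base windows.

    Each window starts at the first detected peak at least
    ``gap_samples`` after the previous window's end.  Raises when the
    recording does not hold enough peaks.
    """
    peaks = np.asarray(peaks, dtype=int)
    plans: list[SegmentPlan] = []
    start_peak = 0
    for _ in range(n_segments):
        if start_peak >= len(peaks) - 1:
            raise ValueError(
                f"insufficient peaks for {n_segments} segments of "
                f"{target_length_s} s"
            )
        seg = extract_end_matched(rec, peaks, target_length_s, start_peak=start_peak)
        plans.append(seg.plan)
        end = seg.plan.start_index + seg.plan.length_samples - 1
        nxt = np.searchsorted(peaks, end + 1 + gap_samples)
        start_peak = int(nxt)
    return plans
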