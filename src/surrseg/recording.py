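"""Multichannel recording container and plain-text persistence.

The :class:`MultichannelRecording` is the carrier passed between every
pipeline stage: a (time x channel) float matrix, a sampling rate and
channel labels.  Recordings round-trip through a delimited text file plus
a ``key: value`` sidecar so that no binary formats are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["MultichannelRecording", "write_recording", "read_recording"]


@dataclass
class MultichannelRecording:
    """Sampled multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal values; units are arbitrary (microvolts for real EEG).
    sampling_rate_hz : float
        Sampling rate, strictly positive.
    channel_labels : list of str
        One label per column of ``samples``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (time x channel) matrix")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.samples.shape[1])]
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[1]} channels"
            )
        self.channel_labels = [str(c) for c in self.channel_labels]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel label or integer index to a column index."""
        if isinstance(channel, (int, np.integer)):
            idx = int(channel)
            if not 0 <= idx < self.n_channels:
                raise KeyError(f"channel index {idx} out of range")
            return idx
        try:
            return self.channel_labels.index(str(channel))
        except ValueError:
            raise KeyError(f"unknown channel label {channel!r}") from None

    def channel(self, channel: int | str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        return self.samples[:, self.channel_index(channel)]

    def with_samples(self, samples: np.ndarray) -> "MultichannelRecording":
        """Copy of this recording carrying different sample values."""
        return MultichannelRecording(
            samples=np.asarray(samples, dtype=float),
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=list(self.channel_labels),
        )


def write_recording(
    rec: MultichannelRecording,
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write a recording as a TSV matrix plus a ``.meta`` sidecar.

    The sidecar is ``key: value`` text holding the sampling rate, channel
    labels and any extra metadata (e.g. a generator config echo).
    """
    path = Path(path)
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.samples, delimiter="\t", header=header, comments="")
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "n_samples": rec.n_samples,
        "channel_labels": ",".join(rec.channel_labels),
    }
    if metadata:
        meta.update(metadata)
    lines = [f"{k}: {v}" for k, v in meta.items()]
    path.with_suffix(path.suffix + ".meta").write_text("\n".join(lines) + "\n")


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {meta_path}")
    meta: dict[str, str] = {}
    for line in meta_path.read_text().splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    samples = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    labels = meta.get("channel_labels", "")
    return MultichannelRecording(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channel_labels=[c for c in labels.split(",") if c],
    )
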