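"""Phase-randomized surrogate data.

Surrogates share the original's amplitude spectrum (hence power spectrum
and autocorrelation) but have independently rotated Fourier phases.  In
multivariate mode one rotation sequence is shared by all channels, which
preserves every cross-spectrum phase difference and therefore the linear
inter-channel correlation structure.

The DC bin, and the Nyquist bin when the length is even, are never
rotated: they must stay real for the inverse transform to be real.
No detrending, windowing or padding is applied — how the raw window
interacts with the DFT's periodic extension is exactly what the
downstream test probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import Segment

__all__ = [
    "SurrogateEnsemble",
    "apply_phase_rotation",
    "phase_randomize",
    "phase_randomize_multivariate",
    "build_ensemble",
]


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    if x.ndim != 2:
        raise ValueError("expected a 1-D series or a (time x channel) matrix")
    return x, False


def n_rotatable_bins(n_samples: int) -> int:
    """Number of positive-frequency bins excluding DC and Nyquist."""
    return (n_samples - 1) // 2


def apply_phase_rotation(x: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rotate the positive-frequency phases of ``x`` by ``angles``.

    ``angles`` has one entry per rotatable bin (see
    :func:`n_rotatable_bins`) and is applied identically to every
    channel.  With all-zero angles the input is returned unchanged up to
    round-off.
    """
    mat, was_1d = _as_matrix(x)
    n = mat.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not np.all(np.isfinite(mat)):
        raise ValueError("input contains NaN or Inf")
    angles = np.asarray(angles, dtype=float)
    nrot = n_rotatable_bins(n)
    if angles.shape != (nrot,):
        raise ValueError(f"expected {nrot} rotation angles, got {angles.shape}")
    spec = np.fft.rfft(mat, axis=0)
    rot = np.ones(spec.shape[0], dtype=complex)
    rot[1 : 1 + nrot] = np.exp(1j * angles)
    out = np.fft.irfft(spec * rot[:, None], n=n, axis=0)
    return out[:, 0] if was_1d else out


def _segment_samples(segment: Segment | np.ndarray) -> np.ndarray:
    return segment.samples if isinstance(segment, Segment) else np.asarray(segment)


def phase_randomize(
    segment: Segment | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One univariate surrogate: independent uniform phase rotations.

    For multichannel input each channel receives its own rotation
    sequence; use :func:`phase_randomize_multivariate` to preserve
    cross-channel structure.
    """
    x = _segment_samples(segment)
    mat, was_1d = _as_matrix(x)
    nrot = n_rotatable_bins(mat.shape[0])
    cols = [
        apply_phase_rotation(mat[:, c], rng.uniform(0.0, 2.0 * np.pi, nrot))
        for c in range(mat.shape[1])
    ]
    out = np.column_stack(cols)
    return out[:, 0] if was_1d else out


def phase_randomize_multivariate(
    segment: Segment | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One multivariate surrogate: a single rotation sequence shared by
    all channels, preserving cross-spectra up to a common phase."""
    x = _segment_samples(segment)
    mat, _ = _as_matrix(x)
    if mat.shape[1] < 2:
        raise ValueError("multivariate surrogate needs at least 2 channels")
    nrot = n_rotatable_bins(mat.shape[0])
    return apply_phase_rotation(mat, rng.uniform(0.0, 2.0 * np.pi, nrot))


@dataclass
class SurrogateEnsemble:
    """An original segment plus its phase-randomized realizations."""

    original: Segment
    surrogates: list[np.ndarray] = field(default_factory=list)
    n_surrogates: int = 20
    seed: int = 0


def write_ensemble_debug(ensemble: "SurrogateEnsemble", path) -> None:
    """Dump original and surrogates as columns of a delimited text file.

    Multichannel segments are flattened channel-major; intended for
    eyeballing surrogate waveforms, not for round-tripping.
    """
    cols = [np.asarray(ensemble.original.samples).ravel(order="F")]
    names = ["original"]
    for i, s in enumerate(ensemble.surrogates):
        cols.append(np.asarray(s).ravel(order="F"))
        names.append(f"surrogate{i:02d}")
    header = "\t".join(names)
    np.savetxt(path, np.column_stack(cols), delimiter="\t", header=header, comments="")


def build_ensemble(
    segment: Segment, n: int = 20, seed: int = 0
) -> SurrogateEnsemble:
    """Draw ``n`` independent surrogates from a seeded generator.

    Multichannel segments get multivariate (shared-rotation) surrogates;
    single-channel segments get univariate ones.
    """
    if n < 2:
        raise ValueError("need at least 2 surrogates for a spread estimate")
    rng = np.random.default_rng(seed)
    multichannel = segment.samples.ndim == 2 and segment.samples.shape[1] >= 2
    draw = phase_randomize_multivariate if multichannel else phase_randomize
    surrogates = [draw(segment, rng) for _ in range(n)]
    return SurrogateEnsemble(
        original=segment, surrogates=surrogates, n_surrogates=n, seed=seed
    )
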