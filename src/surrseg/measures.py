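"""Nonlinear discriminating statistics.

Five waveform statistics used as discriminators in the surrogate test:

* :func:`higuchi_fd` — Higuchi fractal dimension (time-domain curve
  length over coarse-graining scales, default ``k_max = 8``).
* :func:`katz_fd` — Katz fractal dimension (planar curve length over
  maximal extent, unit abscissa steps).
* :func:`lempel_ziv_complexity` — exhaustive-history phrase counting of
  the median-binarized sequence (Lempel-Ziv 1976, sequential
  Kaspar-Schuster algorithm).
* :func:`sample_entropy` — Richman-Moorman sample entropy
  (``m = 2``, ``r = 0.2 * SD``, Chebyshev distance, no self-matches).
* :func:`synchronization_likelihood` — recurrence-overlap measure of
  interdependence between two simultaneously recorded series.

All functions are deterministic and raise :class:`DegenerateSeriesError`
on inputs for which the statistic is undefined (e.g. constant series).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "DegenerateSeriesError",
    "HFDParams",
    "SampEnParams",
    "SLParams",
    "LZCResult",
    "MeasureValue",
    "evaluate_measures",
    "higuchi_fd",
    "katz_fd",
    "lempel_ziv_complexity",
    "sample_entropy",
    "synchronization_likelihood",
]


class DegenerateSeriesError(ValueError):
    """The statistic is undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class MeasureValue:
    """A named statistic value with an echo of the parameters used."""

    name: str
    value: float
    params: dict


@dataclass(frozen=True)
class HFDParams:
    k_max: int = 8

    def validate(self, n: int) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.k_max >= n / 2:
            raise ValueError(f"k_max = {self.k_max} too large for n = {n}")


@dataclass(frozen=True)
class SampEnParams:
    m_embed: int = 2
    r_factor: float = 0.2

    def validate(self) -> None:
        if self.m_embed < 1:
            raise ValueError("m_embed must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


@dataclass(frozen=True)
class SLParams:
    """Embedding and recurrence parameters for synchronization likelihood.

    Defaults follow common resting-EEG practice at 1000 Hz sampling:
    lag 7, dimension 136, 10 recurrences out of a 1 percent reference
    fraction within the time window (w1, w2).  Tests and cohort-level
    experiments use reduced embeddings; the statistic's contracts
    (identity -> 1, independence -> ~p_ref) are parameter-agnostic.
    """

    lag_l: int = 7
    dim_m: int = 136
    n_rec: int = 10
    p_ref: float = 0.01
    w1: int = 2000
    w2: int = 2999

    def validate(self, n: int) -> None:
        if min(self.lag_l, self.dim_m, self.n_rec) < 1:
            raise ValueError("lag_l, dim_m and n_rec must be positive")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must lie in (0, 1)")
        if self.w1 >= self.w2:
            raise ValueError("w1 must be < w2")
        if (self.dim_m - 1) * self.lag_l >= n:
            raise ValueError("embedding window exceeds series length")


def _as_series(x: np.ndarray, min_len: int, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_len:
        raise ValueError(f"{name} needs at least {min_len} samples, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} input contains NaN or Inf")
    return x


def higuchi_fd(x: np.ndarray, params: HFDParams = HFDParams()) -> float:
    """Higuchi fractal dimension.

    For each scale ``k`` in ``1..k_max`` and offset ``m`` in ``1..k``
    (1-indexed), the normalized curve length is

        L_m(k) = (N - 1) / (floor((N - m)/k) * k^2)
                 * sum_i |x(m + i k) - x(m + (i-1) k)|,

    averaged over offsets to give ``L(k)``; the dimension is the
    negative slope of the least-squares line of ``ln L(k)`` on
    ``ln k``.  A straight line yields exactly 1; uncorrelated noise
    approaches 2.
    """
    params.validate(len(np.atleast_1d(x)))
    x = _as_series(x, 10, "higuchi_fd")
    n = len(x)
    log_k = np.empty(params.k_max)
    log_l = np.empty(params.k_max)
    for k in range(1, params.k_max + 1):
        lengths = []
        for m0 in range(k):  # m0 = m - 1 (0-indexed offset)
            sub = x[m0::k]
            n_int = len(sub) - 1  # floor((N - m) / k)
            if n_int < 1:
                continue
            total = np.abs(np.diff(sub)).sum()
            lengths.append(total * (n - 1) / (n_int * k * k))
        lk = float(np.mean(lengths))
        if lk <= 0:
            raise DegenerateSeriesError("constant series: curve length is zero")
        log_k[k - 1] = np.log(k)
        log_l[k - 1] = np.log(lk)
    slope = np.polyfit(log_k, log_l, 1)[0]
    return float(-slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension.

    The waveform is treated as a planar curve with unit abscissa steps.
    With ``L`` the summed Euclidean length between successive points,
    ``d`` the maximum Euclidean distance of any point from the first,
    and ``n = N - 1`` steps:

        KFD = log10(n) / (log10(n) + log10(d / L)).

    Any strictly monotone line gives exactly 1 (``d = L``).
    """
    x = _as_series(x, 3, "katz_fd")
    n_steps = len(x) - 1
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    total_length = steps.sum()
    idx = np.arange(len(x), dtype=float)
    extent = np.sqrt(idx**2 + (x - x[0]) ** 2).max()
    if extent == 0 or total_length == 0:
        raise DegenerateSeriesError("constant series: extent is zero")
    return float(
        np.log10(n_steps) / (np.log10(n_steps) + np.log10(extent / total_length))
    )


class LZCResult(NamedTuple):
    """Raw phrase count and its length-normalized value."""

    c: int
    normalized: float


def _lz76_phrase_count(s: np.ndarray) -> int:
    """Phrase count of the exhaustive history (Kaspar-Schuster scan).

    The final phrase counts whether or not it is novel, per the original
    sequential algorithm: an all-equal sequence has c = 2 (for n > 1)
    and a strictly alternating one has c = 3.
    """
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    if n == 1:
        return 1
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] != s[l + k - 1]:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
        else:
            k += 1
            if l + k > n:
                c += 1
                break
    return c


def lempel_ziv_complexity(x: np.ndarray) -> LZCResult:
    """Lempel-Ziv complexity of the median-binarized series.

    Symbols: 1 where ``x > median(x)``, else 0 (ties binarize to 0).
    Returns the raw phrase count ``c`` of the LZ76 exhaustive history
    and the normalization ``c * log2(n) / n``.
    """
    x = _as_series(x, 2, "lempel_ziv_complexity")
    symbols = (x > np.median(x)).astype(np.int8)
    c = _lz76_phrase_count(symbols)
    n = len(symbols)
    return LZCResult(c=c, normalized=c * np.log2(n) / n)


def _embed(x: np.ndarray, m: int, lag: int = 1) -> np.ndarray:
    """Delay embedding: row i is (x[i], x[i+lag], ..., x[i+(m-1)lag])."""
    n_vec = len(x) - (m - 1) * lag
    if n_vec < 1:
        raise ValueError("series too short for embedding")
    idx = np.arange(n_vec)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


def sample_entropy(
    x: np.ndarray, params: SampEnParams = SampEnParams()
) -> float:
    """Sample entropy: -ln of the conditional match probability.

    Template pairs (i != j, self-matches excluded) are compared under
    the Chebyshev distance with tolerance ``r = r_factor * SD`` (SD is
    the population standard deviation of the segment).  Both the
    ``m``-point count ``B`` and the ``(m+1)``-point count ``A`` range
    over the first ``N - m`` templates.  Returns ``-ln(A / B)``;
    ``A = 0`` yields ``inf`` (no matches extend), and ``B = 0`` is
    degenerate.
    """
    params.validate()
    m = params.m_embed
    x = _as_series(x, m + 2, "sample_entropy")
    sd = x.std()
    if sd == 0:
        raise DegenerateSeriesError("constant series: tolerance r = 0")
    r = params.r_factor * sd
    n_templates = len(x) - m  # templates that have an (m+1)-th point
    emb_m = _embed(x, m)[:n_templates]
    emb_m1 = _embed(x, m + 1)
    b = int(np.count_nonzero(pdist(emb_m, metric="chebychev") <= r))
    a = int(np.count_nonzero(pdist(emb_m1, metric="chebychev") <= r))
    if b == 0:
        raise DegenerateSeriesError("no template matches at length m")
    if a == 0:
        return float("inf")
    return float(-np.log(a / b))


def synchronization_likelihood(
    x: np.ndarray,
    y: np.ndarray,
    params: SLParams = SLParams(),
) -> float:
    """Synchronization likelihood between two simultaneous series.

    Both series are delay-embedded with lag ``lag_l`` and dimension
    ``dim_m``.  For each reference time ``i`` the ``n_rec`` nearest
    embedded neighbours of ``x_i`` among times ``j`` with
    ``w1 < |i - j| < w2`` are its recurrences (the operational cutoff
    realizing the reference fraction ``p_ref``); likewise for ``y``.
    The likelihood at ``i`` is the fraction of x-recurrences that are
    simultaneously y-recurrences, averaged over reference times.

    Identical inputs give 1; independent inputs give approximately
    ``n_rec / N_window`` which is about ``p_ref`` when the parameters
    are mutually consistent.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    params.validate(len(x))
    x = _as_series(x, (params.dim_m - 1) * params.lag_l + 2, "synchronization_likelihood")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSeriesError("constant input series")

    ex = _embed(x, params.dim_m, params.lag_l)
    ey = _embed(y, params.dim_m, params.lag_l)
    n_vec = ex.shape[0]
    w1, w2, n_rec = params.w1, params.w2, params.n_rec

    sl_values = []
    offsets = np.arange(-(w2 - 1), w2)
    offsets = offsets[np.abs(offsets) > w1]
    for i in range(n_vec):
        j = i + offsets
        j = j[(j >= 0) & (j < n_vec)]
        if len(j) < n_rec:
            continue
        dx = np.max(np.abs(ex[j] - ex[i]), axis=1)
        dy = np.max(np.abs(ey[j] - ey[i]), axis=1)
        rx = j[np.argpartition(dx, n_rec - 1)[:n_rec]]
        ry = j[np.argpartition(dy, n_rec - 1)[:n_rec]]
        shared = np.intersect1d(rx, ry, assume_unique=True)
        sl_values.append(len(shared) / n_rec)
    if not sl_values:
        raise ValueError("no reference time has enough admissible recurrences")
    return float(np.mean(sl_values))


def evaluate_measures(
    samples: np.ndarray,
    names: tuple[str, ...] = ("HFD", "KFD", "LZC", "SampEn"),
    hfd_params: HFDParams = HFDParams(),
    sampen_params: SampEnParams = SampEnParams(),
    sl_params: SLParams = SLParams(),
) -> list[MeasureValue]:
    """Evaluate several statistics on one segment's samples.

    ``samples`` is a 1-D series for the univariate measures; "SL"
    additionally requires a second column.
    """
    samples = np.asarray(samples, dtype=float)
    first = samples[:, 0] if samples.ndim == 2 else samples
    out: list[MeasureValue] = []
    for name in names:
        if name == "HFD":
            out.append(
                MeasureValue("HFD", higuchi_fd(first, hfd_params), {"k_max": hfd_params.k_max})
            )
        elif name == "KFD":
            out.append(MeasureValue("KFD", katz_fd(first), {}))
        elif name == "LZC":
            res = lempel_ziv_complexity(first)
            out.append(MeasureValue("LZC", res.normalized, {"c": res.c}))
        elif name == "SampEn":
            out.append(
                MeasureValue(
                    "SampEn",
                    sample_entropy(first, sampen_params),
                    {"m_embed": sampen_params.m_embed, "r_factor": sampen_params.r_factor},
                )
            )
        elif name == "SL":
            if samples.ndim != 2 or samples.shape[1] < 2:
                raise ValueError("SL needs a two-channel segment")
            out.append(
                MeasureValue(
                    "SL",
                    synchronization_likelihood(samples[:, 0], samples[:, 1], sl_params),
                    {
                        "lag_l": sl_params.lag_l,
                        "dim_m": sl_params.dim_m,
                        "n_rec": sl_params.n_rec,
                        "p_ref": sl_params.p_ref,
                        "w1": sl_params.w1,
                        "w2": sl_params.w2,
                    },
                )
            )
        else:
            raise KeyError(f"unknown measure {name!r}")
    return out
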