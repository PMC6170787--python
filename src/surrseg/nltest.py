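"""Surrogate hypothesis test and degree-of-nonlinearity aggregation.

A discriminating statistic ``Q`` is computed for the original segment
and for each surrogate; the z-score of the original against the
surrogate distribution decides rejection at ``|z| > 1.96`` (two-tailed,
5 percent).  The degree of nonlinearity (DEG) is the percentage of
segments rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NonlinearityTestResult",
    "DegResult",
    "z_statistic",
    "degree_of_nonlinearity",
    "write_results_table",
    "RESULT_COLUMNS",
    "DEFAULT_Z_THRESHOLD",
]

DEFAULT_Z_THRESHOLD = 1.96


@dataclass
class NonlinearityTestResult:
    """One segment's surrogate test outcome."""

    q_data: float
    q_surr_mean: float
    q_surr_std: float
    z: float
    rejected: bool
    undefined: bool = False
    threshold: float = DEFAULT_Z_THRESHOLD
    alpha_level: float = 0.05


@dataclass
class DegResult:
    """Rejection counts over a set of segments."""

    n_segments: int
    n_significant: int
    deg_percent: float


def z_statistic(
    q_data: float,
    q_surrogates: Sequence[float],
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> NonlinearityTestResult:
    """z-score of the original statistic against the surrogate spread.

    Uses the sample (n-1) standard deviation of the surrogate values.
    A zero surrogate spread (or non-finite inputs) yields an
    ``undefined`` result that aggregation excludes; it is never counted
    as a rejection.
    """
    q_surr = np.asarray(q_surrogates, dtype=float)
    if q_surr.size < 2:
        raise ValueError("need at least 2 surrogate values")
    if not (np.isfinite(q_data) and np.all(np.isfinite(q_surr))):
        return NonlinearityTestResult(
            q_data=float(q_data),
            q_surr_mean=float("nan"),
            q_surr_std=float("nan"),
            z=float("nan"),
            rejected=False,
            undefined=True,
            threshold=threshold,
        )
    mean = float(q_surr.mean())
    std = float(q_surr.std(ddof=1))
    if std == 0.0:
        return NonlinearityTestResult(
            q_data=float(q_data),
            q_surr_mean=mean,
            q_surr_std=0.0,
            z=float("nan"),
            rejected=False,
            undefined=True,
            threshold=threshold,
        )
    z = (float(q_data) - mean) / std
    return NonlinearityTestResult(
        q_data=float(q_data),
        q_surr_mean=mean,
        q_surr_std=std,
        z=z,
        rejected=abs(z) > threshold,
        threshold=threshold,
    )


def degree_of_nonlinearity(
    results: Iterable[NonlinearityTestResult],
) -> DegResult:
    """DEG = 100 * n_significant / n over the well-defined segments.

    Segments flagged ``undefined`` are excluded from both numerator and
    denominator.
    """
    valid = [r for r in results if not r.undefined]
    if not valid:
        raise ValueError("no well-defined test results to aggregate")
    n_sig = sum(r.rejected for r in valid)
    return DegResult(
        n_segments=len(valid),
        n_significant=n_sig,
        deg_percent=100.0 * n_sig / len(valid),
    )


RESULT_COLUMNS = (
    "subject",
    "channel",
    "band",
    "delta_t_ms",
    "segment_id",
    "measure",
    "q_data",
    "q_surr_mean",
    "q_surr_std",
    "z",
    "rejected",
)


def write_results_table(rows: Iterable[dict], path) -> None:
    """Write per-segment test outcomes as a tidy delimited-text table.

    Each row is a dict carrying the :data:`RESULT_COLUMNS` keys (missing
    context keys are written empty).
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for row in rows:
        lines.append("\t".join(str(row.get(col, "")) for col in RESULT_COLUMNS))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
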