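"""Cohort-level experiment harness.

Runs the four study designs end-to-end on synthetic cohorts: the
delta-t sweep (how DEG depends on the segment-length increment), the
channel dependence (cyclic-component power per channel), the band
dependence (delta-t grids matched to four frequency bands) and the
segment-length study — each with one-way ANOVA and Bonferroni
correction at the group level.

Seeding: the cohort master seed is fanned out deterministically to each
(subject, segment, delta-t) so full runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as spstats

from .measures import (
    DegenerateSeriesError,
    HFDParams,
    SampEnParams,
    SLParams,
    higuchi_fd,
    katz_fd,
    lempel_ziv_complexity,
    sample_entropy,
    synchronization_likelihood,
)
from .nltest import DEFAULT_Z_THRESHOLD, degree_of_nonlinearity, z_statistic
from .preprocess import BANDS, bandpass_zero_phase, detect_cycle_peaks
from .recording import MultichannelRecording
from .segment import delta_t_series, increment_segment, plan_consecutive_end_matched
from .surrogate import build_ensemble
from .synth import SynthConfig, generate_linear_cyclic, generate_nonlinear

__all__ = [
    "CohortSpec",
    "SweepResult",
    "ChannelDependenceResult",
    "MEASURES",
    "subject_configs",
    "generate_subject",
    "subject_deg_profile",
    "run_delta_t_sweep",
    "run_channel_dependence",
    "run_band_sweep",
    "run_segment_length_study",
    "one_way_anova",
    "bonferroni_threshold",
]

# Reduced SL embedding for cohort work; the full-scale defaults in
# SLParams are available behind the sl_params argument.
REDUCED_SL = SLParams(lag_l=1, dim_m=3, n_rec=10, p_ref=0.05, w1=10, w2=210)


def _measure_fn(name: str, sl_params: SLParams | None = None) -> Callable:
    """Statistic evaluator over a (time,) or (time x channel) array."""
    def first_col(a: np.ndarray) -> np.ndarray:
        return a[:, 0] if a.ndim == 2 else a

    if name == "HFD":
        return lambda a: higuchi_fd(first_col(a), HFDParams())
    if name == "KFD":
        return lambda a: katz_fd(first_col(a))
    if name == "LZC":
        return lambda a: lempel_ziv_complexity(first_col(a)).normalized
    if name == "SampEn":
        return lambda a: sample_entropy(first_col(a), SampEnParams())
    if name == "SL":
        params = sl_params or REDUCED_SL
        def sl(a: np.ndarray) -> float:
            if a.ndim != 2 or a.shape[1] < 2:
                raise ValueError("SL needs a two-channel segment")
            return synchronization_likelihood(a[:, 0], a[:, 1], params)
        return sl
    raise KeyError(f"unknown measure {name!r}")


MEASURES = ("HFD", "KFD", "LZC", "SampEn", "SL")


@dataclass
class CohortSpec:
    """Specification of a synthetic pseudo-subject cohort."""

    n_subjects: int
    n_segments_per_subject: int
    seed: int = 0
    sampling_rate_hz: float = 200.0
    alpha_freq_hz: float = 10.0
    alpha_freq_jitter_hz: float = 0.0
    alpha_rel_power: float | Sequence[float] = 0.5
    noise_exponent: float = 1.0
    channel_labels: Sequence[str] = ("O1",)
    nonlinearity: str = "none"
    nonlinearity_strength: float = 0.0
    duration_s: float | None = None
    target_length_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_segments_per_subject < 1:
            raise ValueError("cohort sizes must be positive")


def _subject_seed(cohort_seed: int, subject: int, stream: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(cohort_seed), int(subject), int(stream)])


def _required_duration(
    cohort: CohortSpec,
    target_length_s: float,
    max_delta_t_ms: float,
    seg_period_s: float | None = None,
) -> float:
    # margins scale with the period of the component driving the
    # segmentation (inter-segment gaps and end-matching slack are each
    # up to one such period)
    period = seg_period_s if seg_period_s is not None else 1.0 / cohort.alpha_freq_hz
    per_segment = target_length_s + 2.0 * period
    return (
        cohort.n_segments_per_subject * per_segment
        + max_delta_t_ms / 1000.0
        + 3.0
    )


def subject_configs(
    cohort: CohortSpec,
    target_length_s: float | None = None,
    max_delta_t_ms: float = 120.0,
    seg_period_s: float | None = None,
) -> list[SynthConfig]:
    """Expand the cohort into per-subject generator configs.

    Each subject gets an independent child seed and (optionally) a
    jittered dominant frequency; the recording duration is sized to fit
    the requested number of end-matched segments plus the largest
    delta-t extension, unless the cohort fixes ``duration_s``.
    """
    target = target_length_s if target_length_s is not None else cohort.target_length_s
    duration = cohort.duration_s or _required_duration(
        cohort, target, max_delta_t_ms, seg_period_s
    )
    configs = []
    for si in range(cohort.n_subjects):
        ss = _subject_seed(cohort.seed, si, 0)
        rng = np.random.default_rng(ss)
        freq = cohort.alpha_freq_hz
        if cohort.alpha_freq_jitter_hz > 0:
            freq += rng.uniform(-1.0, 1.0) * cohort.alpha_freq_jitter_hz
        configs.append(
            SynthConfig(
                duration_s=duration,
                sampling_rate_hz=cohort.sampling_rate_hz,
                alpha_freq_hz=freq,
                alpha_rel_power=cohort.alpha_rel_power,
                noise_exponent=cohort.noise_exponent,
                channel_labels=list(cohort.channel_labels),
                nonlinearity=cohort.nonlinearity,
                nonlinearity_strength=cohort.nonlinearity_strength,
                seed=int(rng.integers(2**63)),
            )
        )
    return configs


def generate_subject(config: SynthConfig) -> MultichannelRecording:
    if config.nonlinearity == "none":
        return generate_linear_cyclic(config)
    return generate_nonlinear(config)


def subject_deg_profile(
    rec: MultichannelRecording,
    *,
    delta_ts: Sequence[float],
    measures: Sequence[str],
    n_segments: int,
    band: str = "alpha",
    target_length_s: float = 5.0,
    n_surrogates: int = 20,
    seed: int | np.random.SeedSequence = 0,
    ref_channel: int | str = 0,
    analysis_channels: Sequence[int | str] | None = None,
    threshold: float = DEFAULT_Z_THRESHOLD,
    sl_params: SLParams | None = None,
    apply_broadband: bool = True,
    details: list[dict] | None = None,
) -> dict[str, np.ndarray]:
    """DEG (percent) per measure at each delta-t for one recording.

    Cycle peaks are detected on the band-filtered reference channel;
    segments are cut from the broadband-filtered signal.  Surrogate
    ensembles are built once per (segment, delta-t) and shared by all
    measures.  Segments whose statistic is degenerate or whose surrogate
    spread vanishes are excluded from the DEG denominator.

    When ``details`` is a list, one tidy record per (segment, delta-t,
    measure) is appended to it (see :data:`surrseg.nltest.RESULT_COLUMNS`).
    """
    work = bandpass_zero_phase(rec, "broadband") if apply_broadband else rec
    peaks = detect_cycle_peaks(rec, ref_channel, band)
    plans = plan_consecutive_end_matched(work, peaks, target_length_s, n_segments)
    if analysis_channels is None:
        if "SL" in measures:
            if rec.n_channels < 2:
                raise ValueError("SL requires a second channel")
            other = 1 if rec.channel_index(ref_channel) == 0 else 0
            analysis_channels = [ref_channel, other]
        else:
            analysis_channels = [ref_channel]

    fns = {m: _measure_fn(m, sl_params) for m in measures}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    cell_seeds = ss.spawn(n_segments * len(delta_ts))

    results: dict[str, list[list]] = {m: [[] for _ in delta_ts] for m in measures}
    for si, plan in enumerate(plans):
        for ti, dt in enumerate(delta_ts):
            seg = increment_segment(work, plan, float(dt), channels=analysis_channels)
            ens = build_ensemble(
                seg, n_surrogates, seed=cell_seeds[si * len(delta_ts) + ti]
            )
            for m, fn in fns.items():
                try:
                    q = fn(seg.samples)
                    q_surr = [fn(s) for s in ens.surrogates]
                except DegenerateSeriesError:
                    continue
                res = z_statistic(q, q_surr, threshold)
                results[m][ti].append(res)
                if details is not None:
                    details.append(
                        {
                            "channel": rec.channel_labels[
                                rec.channel_index(ref_channel)
                            ],
                            "band": band,
                            "delta_t_ms": float(dt),
                            "segment_id": si,
                            "measure": m,
                            "q_data": res.q_data,
                            "q_surr_mean": res.q_surr_mean,
                            "q_surr_std": res.q_surr_std,
                            "z": res.z,
                            "rejected": res.rejected,
                        }
                    )

    deg = {}
    for m in measures:
        deg[m] = np.array(
            [degree_of_nonlinearity(cell).deg_percent for cell in results[m]]
        )
    return deg


@dataclass
class SweepResult:
    """Per-subject DEG values over the levels of one experimental factor."""

    factor: str
    levels: list
    deg_matrix: np.ndarray  # (n_subjects, n_levels)
    measure: str
    anova_f: float
    anova_p: float
    bonferroni_m: int
    significant: bool

    def group_mean(self) -> np.ndarray:
        return self.deg_matrix.mean(axis=0)

    def deflection(self) -> float:
        """Max minus min of the group-mean DEG profile."""
        gm = self.group_mean()
        return float(gm.max() - gm.min())

    def to_frame(self):
        import pandas as pd

        records = []
        for si in range(self.deg_matrix.shape[0]):
            for li, level in enumerate(self.levels):
                records.append(
                    {
                        "subject": si,
                        "factor": self.factor,
                        "level": level,
                        "measure": self.measure,
                        "deg_percent": self.deg_matrix[si, li],
                    }
                )
        return pd.DataFrame.from_records(records)


def _make_sweep_result(
    factor: str,
    levels: Sequence,
    deg_matrix: np.ndarray,
    measure: str,
    bonferroni_m: int,
    alpha: float = 0.05,
) -> SweepResult:
    if deg_matrix.shape[1] < 2:
        f, p = float("nan"), float("nan")
    else:
        f, p = one_way_anova(
            [deg_matrix[:, j] for j in range(deg_matrix.shape[1])]
        )
    return SweepResult(
        factor=factor,
        levels=list(levels),
        deg_matrix=deg_matrix,
        measure=measure,
        anova_f=f,
        anova_p=p,
        bonferroni_m=bonferroni_m,
        significant=p < bonferroni_threshold(alpha, bonferroni_m),
    )


def run_delta_t_sweep(
    cohort: CohortSpec,
    measures: Sequence[str] = ("HFD",),
    band: str = "alpha",
    delta_ts: Sequence[float] | None = None,
    n_surrogates: int = 20,
    sl_params: SLParams | None = None,
    bonferroni_m: int | None = None,
    apply_broadband: bool = True,
) -> dict[str, SweepResult]:
    """The segment-length-increment design over a synthetic cohort.

    ``apply_broadband=False`` skips the 1-45 Hz pre-filter; useful when
    the nonlinearity of interest lives near the Nyquist frequency (e.g.
    a map component iterated at the sampling rate).
    """
    if cohort.n_subjects < 2:
        raise ValueError("ANOVA needs at least 2 subjects")
    if delta_ts is None:
        delta_ts = delta_t_series(band)
    delta_ts = np.asarray(delta_ts, dtype=float)
    m_corr = bonferroni_m if bonferroni_m is not None else len(measures)

    configs = subject_configs(
        cohort,
        cohort.target_length_s,
        max_delta_t_ms=float(np.max(delta_ts)),
        seg_period_s=1.0 / BANDS[band].low_hz,
    )
    deg = {m: np.zeros((cohort.n_subjects, len(delta_ts))) for m in measures}
    for si, config in enumerate(configs):
        rec = generate_subject(config)
        profile = subject_deg_profile(
            rec,
            delta_ts=delta_ts,
            measures=measures,
            n_segments=cohort.n_segments_per_subject,
            band=band,
            target_length_s=cohort.target_length_s,
            n_surrogates=n_surrogates,
            seed=_subject_seed(cohort.seed, si, 1),
            sl_params=sl_params,
            apply_broadband=apply_broadband,
        )
        for m in measures:
            deg[m][si] = profile[m]

    return {
        m: _make_sweep_result("delta_t", delta_ts.tolist(), deg[m], m, m_corr)
        for m in measures
    }


@dataclass
class ChannelDependenceResult:
    """Delta-t sweeps per pseudo-channel plus their deflections."""

    per_channel: dict[str, SweepResult]
    deflections: dict[str, float] = field(default_factory=dict)

    def ordered_channels(self) -> list[str]:
        """Channels sorted by decreasing deflection."""
        return sorted(self.deflections, key=self.deflections.get, reverse=True)


def run_channel_dependence(
    cohort: CohortSpec,
    measure: str = "HFD",
    band: str = "alpha",
    delta_ts: Sequence[float] | None = None,
    n_surrogates: int = 20,
) -> ChannelDependenceResult:
    """Delta-t sweeps per channel; channels differ in cyclic power.

    The cohort's ``alpha_rel_power`` must give one value per channel.
    Peaks are re-detected per analyzed channel.
    """
    if len(cohort.channel_labels) < 2:
        raise ValueError("channel dependence needs at least 2 channels")
    if delta_ts is None:
        delta_ts = delta_t_series(band)
    delta_ts = np.asarray(delta_ts, dtype=float)

    configs = subject_configs(
        cohort, cohort.target_length_s, max_delta_t_ms=float(np.max(delta_ts))
    )
    n_ch = len(cohort.channel_labels)
    deg = np.zeros((n_ch, cohort.n_subjects, len(delta_ts)))
    for si, config in enumerate(configs):
        rec = generate_subject(config)
        for ci, label in enumerate(cohort.channel_labels):
            profile = subject_deg_profile(
                rec,
                delta_ts=delta_ts,
                measures=[measure],
                n_segments=cohort.n_segments_per_subject,
                band=band,
                target_length_s=cohort.target_length_s,
                n_surrogates=n_surrogates,
                seed=np.random.SeedSequence(
                    [int(cohort.seed), si, 1, ci]
                ),
                ref_channel=label,
            )
            deg[ci, si] = profile[measure]

    per_channel = {}
    deflections = {}
    for ci, label in enumerate(cohort.channel_labels):
        res = _make_sweep_result(
            "delta_t", delta_ts.tolist(), deg[ci], measure, n_ch
        )
        per_channel[label] = res
        deflections[label] = res.deflection()
    return ChannelDependenceResult(per_channel=per_channel, deflections=deflections)


def run_band_sweep(
    cohort: CohortSpec,
    measure: str = "HFD",
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta"),
    n_delta_t_points: int | None = None,
    n_surrogates: int = 20,
) -> dict[str, SweepResult]:
    """Delta-t sweeps with segmentation matched to each band in turn.

    ``n_delta_t_points`` thins each band's grid to that many evenly
    spaced values (always keeping 0 and the endpoint), which keeps
    desk-scale runs affordable; ``None`` uses the full grids.
    """
    out = {}
    for band in bands:
        grid = delta_t_series(band)
        if n_delta_t_points is not None and n_delta_t_points < len(grid):
            idx = np.round(
                np.linspace(0, len(grid) - 1, n_delta_t_points)
            ).astype(int)
            grid = grid[idx]
        sweep = run_delta_t_sweep(
            cohort,
            measures=[measure],
            band=band,
            delta_ts=grid,
            n_surrogates=n_surrogates,
            bonferroni_m=len(bands),
        )
        out[band] = sweep[measure]
    return out


def run_segment_length_study(
    cohort: CohortSpec,
    measures: Sequence[str] = ("HFD",),
    lengths_s: Sequence[float] = (5.0, 10.0, 15.0, 20.0),
    band: str = "alpha",
    n_surrogates: int = 20,
    bonferroni_m: int | None = None,
    sl_params: SLParams | None = None,
    apply_broadband: bool = True,
) -> dict[str, SweepResult]:
    """End-matched DEG (delta-t = 0) at substantially different lengths."""
    m_corr = (
        bonferroni_m
        if bonferroni_m is not None
        else len(measures) * len(lengths_s)
    )
    longest = max(lengths_s)
    spec_duration = cohort.duration_s or _required_duration(
        cohort, longest, max_delta_t_ms=0.0
    )
    sized = CohortSpec(
        **{
            **cohort.__dict__,
            "duration_s": spec_duration,
            "target_length_s": longest,
        }
    )
    configs = subject_configs(sized, longest, max_delta_t_ms=0.0)

    deg = {
        m: np.zeros((cohort.n_subjects, len(lengths_s))) for m in measures
    }
    for si, config in enumerate(configs):
        rec = generate_subject(config)
        for li, length in enumerate(lengths_s):
            profile = subject_deg_profile(
                rec,
                delta_ts=[0.0],
                measures=measures,
                n_segments=cohort.n_segments_per_subject,
                band=band,
                target_length_s=float(length),
                n_surrogates=n_surrogates,
                seed=np.random.SeedSequence([int(cohort.seed), si, 1, li]),
                sl_params=sl_params,
                apply_broadband=apply_broadband,
            )
            for m in measures:
                deg[m][si, li] = profile[m][0]

    return {
        m: _make_sweep_result("segment_length", list(lengths_s), deg[m], m, m_corr)
        for m in measures
    }


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Degenerate cases are resolved explicitly: no between-group variance
    gives ``(0, 1)``; zero within-group variance with distinct group
    means gives ``(inf, 0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return float("inf"), 0.0
    f = (ssb / dfb) / (ssw / dfw)
    p = float(spstats.f.sf(f, dfb, dfw))
    return float(f), p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
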