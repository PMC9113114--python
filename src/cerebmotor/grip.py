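"""Precision-grip force-trace scoring.

Scores 15 s isometric precision-grip trials into a per-trial force-variability
endpoint: the coefficient of variation (CoV = SD / mean) of the sustained
phase of the force trace.  The processing chain is

1. zero-phase low-pass filtering (4th-order Butterworth, 15 Hz cutoff);
2. rise-offset detection: the earliest point where the rate of force increase
   falls below 5% of its peak while force sits within 90-110% of the
   sustained-phase mean (the mean is resolved iteratively, since it depends
   on the offset);
3. sustained-phase extraction: the 12 s window before the stop cue,
   restricted to after the rise offset, minus any zero-force span longer
   than 1 s;
4. validity: a trial must retain at least 8 s of sustained output;
5. CoV and its natural log (the modelling scale for force variability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal


class GripExclusion(str, Enum):
    NONE = "none"
    SHORT_SUSTAINED = "short_sustained"
    NO_ONSET = "no_onset"
    OTHER = "other"


@dataclass
class ForceTimeSeries:
    """One trial's force trace (time s, force N) with its stop-cue time."""

    time: np.ndarray
    force: np.ndarray
    stop_cue_time: float
    hand: str = "right"
    trial_id: int | str = 1
    participant_id: str = ""
    annotations: dict | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.force.shape:
            raise ValueError("time and force must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")
        if not (self.time[0] <= self.stop_cue_time <= self.time[-1] + self.dt):
            raise ValueError("stop_cue_time outside trace")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class GripConfig:
    filter_order: int = 4
    filter_cutoff: float = 15.0  # Hz
    sustained_window: float = 12.0  # s before stop cue
    zero_release_max: float = 1.0  # s; spans strictly longer are excised
    min_sustained: float = 8.0  # s retained required for validity
    rate_threshold_fraction: float = 0.05
    force_band: tuple[float, float] = (0.90, 1.10)
    zero_force_epsilon: float = 0.0016  # N, the transducer resolution

    def __post_init__(self):
        if not 0 < self.rate_threshold_fraction < 1:
            raise ValueError("rate_threshold_fraction must be in (0, 1)")
        lo, hi = self.force_band
        if not lo < 1 < hi:
            raise ValueError("force_band must bracket 1")


@dataclass(frozen=True)
class GripTrialResult:
    participant_id: str
    hand: str
    trial_id: int | str
    valid: bool
    exclusion_reason: GripExclusion
    rise_offset_time: float | None = None
    retained_duration: float | None = None
    sustained_mean: float | None = None
    sustained_sd: float | None = None
    cov: float | None = None
    log_cov: float | None = None


@dataclass(frozen=True)
class MVCResult:
    hand: str
    mvc: float
    trial_maxima: tuple[float, float, float]


# -- filtering ---------------------------------------------------------------

_REL_DT_TOL = 0.01


def _check_uniform(time: np.ndarray) -> float:
    dt = np.diff(time)
    if dt.size == 0:
        raise ValueError("need at least 2 samples")
    med = np.median(dt)
    if np.max(np.abs(dt - med)) > _REL_DT_TOL * med:
        raise ValueError("sampling is not uniform")
    return float(med)


def lowpass_filter(series: ForceTimeSeries, config: GripConfig | None = None) -> ForceTimeSeries:
    """Zero-phase (forward-backward) Butterworth low-pass; DC gain 1."""
    cfg = config or GripConfig()
    dt = _check_uniform(series.time)
    fs = 1.0 / dt
    if cfg.filter_cutoff >= fs / 2:
        raise ValueError(f"cutoff {cfg.filter_cutoff} Hz >= Nyquist {fs / 2} Hz")
    if series.time.size < int(0.5 * fs):
        raise ValueError("trace shorter than 0.5 s")
    sos = signal.butter(cfg.filter_order, cfg.filter_cutoff, fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, series.force)
    return ForceTimeSeries(
        time=series.time,
        force=filtered,
        stop_cue_time=series.stop_cue_time,
        hand=series.hand,
        trial_id=series.trial_id,
        participant_id=series.participant_id,
        annotations=series.annotations,
    )


# -- MVC ---------------------------------------------------------------------


def compute_mvc(trial_traces: list[ForceTimeSeries], hand: str | None = None) -> MVCResult:
    """MVC = mean of the per-trial force maxima over exactly three trials."""
    hand = hand or (trial_traces[0].hand if trial_traces else "unknown")
    if len(trial_traces) != 3:
        raise ValueError(
            f"MVC for hand {hand!r} requires exactly 3 trials, got {len(trial_traces)}"
        )
    maxima = tuple(float(np.max(tr.force)) for tr in trial_traces)
    return MVCResult(hand=hand, mvc=float(np.mean(maxima)), trial_maxima=maxima)


# -- sustained-phase extraction ----------------------------------------------


def locate_rise_offset(
    series: ForceTimeSeries, config: GripConfig | None = None, n_iter: int = 2
) -> float | None:
    """End of the initial force rise, or None if no sample qualifies.

    The defining rule references the sustained-phase mean, which itself
    depends on where the rise ends; the mean is initialized from the final
    pre-cue window and the rule re-applied once with the refined mean.
    """
    cfg = config or GripConfig()
    t, f = series.time, series.force
    rate = np.gradient(f, t)
    peak_rate = float(np.max(rate))
    if peak_rate <= 0:
        return None

    window = (t >= series.stop_cue_time - cfg.sustained_window) & (t < series.stop_cue_time)
    if not window.any():
        return None
    mean_est = float(np.mean(f[window]))
    offset = None
    for _ in range(n_iter):
        lo, hi = cfg.force_band[0] * mean_est, cfg.force_band[1] * mean_est
        ok = (
            (rate < cfg.rate_threshold_fraction * peak_rate)
            & (f >= lo)
            & (f <= hi)
            & (t <= series.stop_cue_time)
        )
        if not ok.any():
            return None
        offset = float(t[np.argmax(ok)])
        seg = window & (t >= offset)
        if not seg.any():
            return None
        mean_est = float(np.mean(f[seg]))
    return offset


@dataclass(frozen=True)
class SustainedSegment:
    time: np.ndarray
    force: np.ndarray
    retained_duration: float
    valid: bool
    reason: GripExclusion


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def extract_sustained(
    series: ForceTimeSeries,
    rise_offset: float | None,
    config: GripConfig | None = None,
) -> SustainedSegment:
    """Sustained samples in [cue-12 s, cue) ∩ [rise offset, ∞) minus long releases.

    A zero-force span (force below the transducer resolution) is excised only
    if strictly longer than 1 s; a trial is valid iff at least 8 s remain.
    """
    cfg = config or GripConfig()
    if rise_offset is None:
        return SustainedSegment(
            np.empty(0), np.empty(0), 0.0, False, GripExclusion.NO_ONSET
        )
    t, f = series.time, series.force
    dt = series.dt
    keep = (
        (t >= series.stop_cue_time - cfg.sustained_window)
        & (t < series.stop_cue_time)
        & (t >= rise_offset)
    )
    zero = keep & (np.abs(f) < cfg.zero_force_epsilon)
    drop = np.zeros_like(zero)
    for start, stop in _zero_runs(zero):
        if (stop - start) * dt > cfg.zero_release_max * (1 + 1e-9):
            drop[start:stop] = True
    keep &= ~drop
    retained = float(keep.sum() * dt)
    valid = retained >= cfg.min_sustained * (1 - 1e-9)
    return SustainedSegment(
        time=t[keep],
        force=f[keep],
        retained_duration=retained,
        valid=valid,
        reason=GripExclusion.NONE if valid else GripExclusion.SHORT_SUSTAINED,
    )


# -- CoV ---------------------------------------------------------------------


def compute_cov(
    segment: SustainedSegment,
    series: ForceTimeSeries,
    rise_offset: float | None = None,
) -> GripTrialResult:
    """CoV = sample SD / mean of the sustained force; log is natural."""
    base = dict(
        participant_id=series.participant_id, hand=series.hand, trial_id=series.trial_id
    )
    if not segment.valid:
        return GripTrialResult(
            valid=False,
            exclusion_reason=segment.reason,
            rise_offset_time=rise_offset,
            retained_duration=segment.retained_duration,
            **base,
        )
    mean = float(np.mean(segment.force))
    if mean <= 0:
        return GripTrialResult(
            valid=False,
            exclusion_reason=GripExclusion.OTHER,
            rise_offset_time=rise_offset,
            retained_duration=segment.retained_duration,
            **base,
        )
    sd = float(np.std(segment.force, ddof=1))
    cov = sd / mean
    return GripTrialResult(
        valid=True,
        exclusion_reason=GripExclusion.NONE,
        rise_offset_time=rise_offset,
        retained_duration=segment.retained_duration,
        sustained_mean=mean,
        sustained_sd=sd,
        cov=cov,
        log_cov=float(np.log(cov)) if cov > 0 else None,
        **base,
    )


def score_trial(series: ForceTimeSeries, config: GripConfig | None = None) -> GripTrialResult:
    """Full per-trial chain: filter -> rise offset -> sustained phase -> CoV."""
    cfg = config or GripConfig()
    filtered = lowpass_filter(series, cfg)
    offset = locate_rise_offset(filtered, cfg)
    segment = extract_sustained(filtered, offset, cfg)
    return compute_cov(segment, filtered, rise_offset=offset)


def score_trials(
    trials: list[ForceTimeSeries], config: GripConfig | None = None
) -> pd.DataFrame:
    """Score a batch of trials into a tidy per-trial results table."""
    rows = []
    for tr in trials:
        r = score_trial(tr, config)
        rows.append(
            {
                "participant_id": r.participant_id,
                "hand": r.hand,
                "trial_id": r.trial_id,
                "valid": r.valid,
                "exclusion_reason": r.exclusion_reason.value,
                "rise_offset_time": r.rise_offset_time,
                "retained_duration": r.retained_duration,
                "sustained_mean": r.sustained_mean,
                "sustained_sd": r.sustained_sd,
                "cov": r.cov,
                "log_cov": r.log_cov,
            }
        )
    return pd.DataFrame(rows)
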