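"""Synthetic visually guided saccade trials.

Each trial: central fixation (1.5-2 s), then a horizontal target step of
+/-12 or +/-24 degrees shown for 1.5 s.  The eye launches after a configured
latency and follows a logistic position profile whose duration obeys a
main-sequence rule (duration ~ 2.2 ms/deg x amplitude + 21 ms), landing at
``gain`` x target.  Optional corrective saccades, blinks (missing samples),
and band-unlimited white position noise emulate the failure modes the scoring
stage must survive.  Ground truth (onset/offset/landing/latency/peak
velocity) is annotated for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..saccades import GazeTimeSeries

MAIN_SEQUENCE_SLOPE = 2.2  # ms per degree
MAIN_SEQUENCE_INTERCEPT = 21.0  # ms


def saccade_duration_ms(amplitude_deg: float) -> float:
    return MAIN_SEQUENCE_SLOPE * abs(amplitude_deg) + MAIN_SEQUENCE_INTERCEPT


@dataclass(frozen=True)
class SaccadeTrialSpec:
    target_amplitude: float  # signed degrees, |.| in {12, 24}
    latency_ms: float = 220.0
    gain: float = 1.0
    fixation_duration: float = 1.75  # s
    target_duration: float = 1.5  # s
    sample_rate: float = 500.0
    position_noise_sd: float = 0.0  # deg, white
    corrective: tuple[float, float] | None = None  # (delay ms after offset, gain)
    blink: tuple[float, float] | None = None  # (start ms after target onset, duration ms)

    def __post_init__(self):
        if abs(self.target_amplitude) not in (12.0, 24.0):
            raise ValueError("|target_amplitude| must be 12 or 24 degrees")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.latency_ms < 0:
            raise ValueError("latency must be >= 0")
        dur = saccade_duration_ms(self.gain * self.target_amplitude)
        if self.latency_ms + dur > self.target_duration * 1000.0:
            raise ValueError("latency + saccade duration exceeds target window")


def _logistic_step(t_ms: np.ndarray, onset_ms: float, amplitude: float) -> np.ndarray:
    """Clamped logistic from 0 to ``amplitude`` starting at ``onset_ms``."""
    dur = saccade_duration_ms(amplitude)
    k = 2.0 * np.log(49.0) / dur  # 2% -> 98% transit over dur
    mid = onset_ms + dur / 2.0
    raw = 1.0 / (1.0 + np.exp(np.clip(-k * (t_ms - mid), -700.0, 700.0)))
    lo = 1.0 / (1.0 + np.exp(k * dur / 2.0))
    x = amplitude * (raw - lo) / (1.0 - 2.0 * lo)
    x[t_ms <= onset_ms] = 0.0
    x[t_ms >= onset_ms + dur] = amplitude
    return x


def generate_saccade_trial(
    spec: SaccadeTrialSpec,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    trial_id: int = 1,
    block: int = 1,
) -> GazeTimeSeries:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1000.0 / spec.sample_rate
    total_ms = (spec.fixation_duration + spec.target_duration) * 1000.0
    t = np.arange(0.0, total_ms, dt)
    target_onset = spec.fixation_duration * 1000.0

    landing = spec.gain * spec.target_amplitude
    onset = target_onset + spec.latency_ms
    dur = saccade_duration_ms(landing)
    x = _logistic_step(t, onset, landing)

    ann = {
        "true_onset_ms": onset,
        "true_offset_ms": onset + dur,
        "true_landing_deg": landing,
        "true_latency_ms": spec.latency_ms,
        # exact |dx/dt| maximum of the clamped, renormalized logistic (deg/s)
        "true_peak_velocity": abs(landing)
        * (2.0 * np.log(49.0) / dur)
        / 4.0
        / (1.0 - 2.0 / (1.0 + np.exp(np.log(49.0))))
        * 1000.0,
    }

    if spec.corrective is not None:
        delay, cgain = spec.corrective
        remaining = spec.target_amplitude - landing
        x = x + _logistic_step(t, onset + dur + delay, cgain * remaining)
        ann["corrective_onset_ms"] = onset + dur + delay

    if spec.position_noise_sd > 0:
        x = x + rng.normal(0, spec.position_noise_sd, size=t.size)
    y = np.zeros_like(t)
    if spec.position_noise_sd > 0:
        y = y + rng.normal(0, spec.position_noise_sd, size=t.size)

    if spec.blink is not None:
        b0, bdur = spec.blink
        m = (t >= target_onset + b0) & (t < target_onset + b0 + bdur)
        x[m] = np.nan
        y[m] = np.nan

    return GazeTimeSeries(
        time=t,
        x=x,
        y=y,
        target_amplitude=spec.target_amplitude,
        target_onset_time=target_onset,
        trial_id=trial_id,
        participant_id=participant_id,
        block=block,
        annotations=ann,
    )


@dataclass(frozen=True)
class SaccadeSessionConfig:
    """60-trial session: 2 blocks x 30 trials, amplitudes +/-12 and +/-24
    balanced (15 trials per amplitude x direction cell), pseudorandom order."""

    n_trials: int = 60
    n_blocks: int = 2
    latency_mean_ms: float = 220.0
    latency_sd_ms: float = 40.0
    latency_min_ms: float = 90.0
    gain_mean: float = 0.95
    gain_sd: float = 0.05
    position_noise_sd: float = 0.02
    blink_rate: float = 0.0
    corrective_rate: float = 0.5


def generate_saccade_session(
    participant_id: str,
    config: SaccadeSessionConfig | None = None,
    seed: int | np.random.Generator = 0,
    gain_mean: float | None = None,
) -> list[GazeTimeSeries]:
    cfg = config or SaccadeSessionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = [s * a for a in (12.0, 24.0) for s in (-1.0, 1.0)]
    reps = cfg.n_trials // len(cells)
    targets = np.array(cells * reps + cells[: cfg.n_trials - reps * len(cells)])
    rng.shuffle(targets)
    per_block = cfg.n_trials // cfg.n_blocks
    gmean = cfg.gain_mean if gain_mean is None else gain_mean

    trials = []
    for i, amp in enumerate(targets):
        latency = max(cfg.latency_min_ms, rng.normal(cfg.latency_mean_ms, cfg.latency_sd_ms))
        gain = max(0.5, rng.normal(gmean, cfg.gain_sd))
        blink = None
        if rng.uniform() < cfg.blink_rate:
            blink = (float(rng.uniform(0, 800)), float(rng.uniform(60, 150)))
        corrective = None
        if rng.uniform() < cfg.corrective_rate:
            corrective = (float(rng.uniform(80, 150)), float(rng.uniform(0.6, 0.95)))
        spec = SaccadeTrialSpec(
            target_amplitude=float(amp),
            latency_ms=float(latency),
            gain=float(gain),
            fixation_duration=float(rng.uniform(1.5, 2.0)),
            position_noise_sd=cfg.position_noise_sd,
            corrective=corrective,
            blink=blink,
        )
        trials.append(
            generate_saccade_trial(
                spec,
                rng,
                participant_id=participant_id,
                trial_id=i + 1,
                block=i // per_block + 1,
            )
        )
    return trials
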