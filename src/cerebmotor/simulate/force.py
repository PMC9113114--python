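"""Synthetic precision-grip force traces.

Task model: the participant rests (zero force), reacts to the go cue, ramps
force up over ``rise_time`` with a smooth half-cosine profile, then holds a
plateau at ``target_fraction`` x MVC until the stop cue at the end of the
15 s trial.  Hold-phase variability is multiplicative noise around the
plateau with a configurable true coefficient of variation (CoV); its spectrum
is an equal-power pink/white mixture band-limited to 0.4-12 Hz so that the
15 Hz low-pass scoring filter passes it essentially untouched.  Optional
release events force contiguous zero-force spans, emulating transducer
releases that the scoring stage must excise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grip import ForceTimeSeries

NOISE_BAND = (0.4, 12.0)  # Hz


@dataclass(frozen=True)
class ForceTrialSpec:
    mvc: float
    target_fraction: float = 0.15
    trial_duration: float = 15.0
    sample_rate: float = 200.0
    reaction_time: float = 0.35
    rise_time: float = 0.3  # ballistic rise: the task cues a maximally fast press
    latent_cov: float = 0.0
    pink_fraction: float = 0.5
    release_events: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must be in (0, 1)")
        if self.mvc <= 0:
            raise ValueError("mvc must be positive")
        if self.latent_cov < 0:
            raise ValueError("latent_cov must be >= 0")
        if any(d < 0 for _, d in self.release_events):
            raise ValueError("release durations must be >= 0")
        if self.trial_duration < self.reaction_time + self.rise_time + 8.0:
            raise ValueError(
                "trial too short: need reaction + rise + 8 s of sustained output"
            )


def _band_limited_noise(
    n: int, fs: float, pink_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD noise with an equal-power pink/white mix on NOISE_BAND."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = NOISE_BAND
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError("noise band empty at this length/sample rate")
    amp = np.zeros_like(freqs)
    white = np.where(band, 1.0, 0.0)
    with np.errstate(divide="ignore"):
        pink = np.where(band, 1.0 / np.sqrt(np.maximum(freqs, lo)), 0.0)
    # scale each component to unit total power, then mix by power fraction
    white /= np.sqrt((white**2).sum())
    pink /= np.sqrt((pink**2).sum())
    amp = np.sqrt(pink_fraction) * pink + np.sqrt(1.0 - pink_fraction) * white
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_force_trial(
    spec: ForceTrialSpec,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    hand: str = "right",
    trial_id: int = 1,
) -> ForceTimeSeries:
    """One 15 s force trace with ground-truth annotations.

    Annotations: ``true_rise_offset`` (s), ``true_cov`` (exact sample CoV of
    the noiseless-release plateau), ``plateau_level`` (N).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = spec.sample_rate
    n = int(round(spec.trial_duration * fs))
    t = np.arange(n) / fs
    plateau = spec.target_fraction * spec.mvc

    force = np.zeros(n)
    t0, t1 = spec.reaction_time, spec.reaction_time + spec.rise_time
    rising = (t >= t0) & (t < t1)
    force[rising] = plateau * 0.5 * (1 - np.cos(np.pi * (t[rising] - t0) / spec.rise_time))
    hold = t >= t1
    force[hold] = plateau

    if spec.latent_cov > 0:
        noise = _band_limited_noise(int(hold.sum()), fs, spec.pink_fraction, rng)
        force[hold] = plateau * (1.0 + spec.latent_cov * noise)

    for start, dur in spec.release_events:
        force[(t >= start) & (t < start + dur)] = 0.0

    return ForceTimeSeries(
        time=t,
        force=force,
        stop_cue_time=spec.trial_duration,
        hand=hand,
        trial_id=trial_id,
        participant_id=participant_id,
        annotations={
            "true_rise_offset": t1,
            "true_cov": float(spec.latent_cov),
            "plateau_level": plateau,
        },
    )


def generate_mvc_trials(
    mvc: float,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    hand: str = "right",
    sample_rate: float = 200.0,
) -> list[ForceTimeSeries]:
    """Three 3 s maximal-effort trials; per-trial peaks annotated exactly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = []
    for k in range(3):
        peak = mvc * (1.0 + rng.normal(0, 0.04))
        n = int(round(3.0 * sample_rate))
        t = np.arange(n) / sample_rate
        prof = peak * np.sin(np.pi * np.minimum(t / 3.0, 1.0)) ** 2
        # ensure the analytic peak is attained on the sample grid
        prof[np.argmax(prof)] = peak
        trials.append(
            ForceTimeSeries(
                time=t,
                force=prof,
                stop_cue_time=3.0,
                hand=hand,
                trial_id=k + 1,
                participant_id=participant_id,
                annotations={"true_peak": peak},
            )
        )
    return trials


@dataclass(frozen=True)
class GripSessionConfig:
    """Cohort-level grip task: 3 trials per hand at 15% MVC.

    ``log_cov_*`` parametrize each participant's latent CoV:
    ``log cov = intercept + asd_shift*[ASD] + age_slope*age_c + N(0, sd)``.
    """

    trials_per_hand: int = 3
    log_cov_intercept: float = float(np.log(0.045))
    log_cov_asd_shift: float = 0.35
    log_cov_age_slope: float = -0.03
    log_cov_sd: float = 0.30
    release_rate: float = 0.0  # probability a trial contains one release


def generate_grip_session(
    participants, config: GripSessionConfig | None = None, seed: int = 0
) -> list[ForceTimeSeries]:
    """Force trials for a whole cohort (both hands, MVC-scaled targets)."""
    cfg = config or GripSessionConfig()
    rng = np.random.default_rng(seed)
    age = participants["age"].to_numpy(dtype=float)
    group = participants["group"].to_numpy()
    age_c = age.copy()
    for g in np.unique(group):
        m = group == g
        age_c[m] = age[m] - age[m].mean()

    trials: list[ForceTimeSeries] = []
    for i, row in enumerate(participants.itertuples(index=False)):
        log_cov = (
            cfg.log_cov_intercept
            + cfg.log_cov_asd_shift * (row.group == "ASD")
            + cfg.log_cov_age_slope * age_c[i]
            + rng.normal(0, cfg.log_cov_sd)
        )
        for hand in ("left", "right"):
            mvc = row.mvc_left if hand == "left" else row.mvc_right
            for k in range(cfg.trials_per_hand):
                releases = ()
                if rng.uniform() < cfg.release_rate:
                    start = rng.uniform(4.0, 12.0)
                    releases = ((start, rng.uniform(0.3, 1.8)),)
                spec = ForceTrialSpec(
                    mvc=mvc,
                    reaction_time=rng.uniform(0.25, 0.5),
                    rise_time=rng.uniform(0.2, 0.4),
                    latent_cov=float(np.exp(log_cov)),
                    release_events=releases,
                )
                trials.append(
                    generate_force_trial(
                        spec,
                        rng,
                        participant_id=row.participant_id,
                        hand=hand,
                        trial_id=k + 1,
                    )
                )
    return trials
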