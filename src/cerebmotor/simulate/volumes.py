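"""Synthetic cerebellar ROI volume tables.

Eighteen regions of interest (cm^3): seven left/right lobule pairs, three
vermal composites, and cerebellar white matter.  Baseline means/SDs default to
the published TD-control cohort values; the ASD arm is produced by additive
per-ROI group shifts (default: the printed ASD-TD difference).  Optional sex,
group-by-sex, hemisphere and per-group age effects are injected additively,
with age entered group-mean-centered so that marginal ROI means stay at their
calibrated values regardless of the age structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._trunc import rvs_matched
from ..rois import LATERALIZED_BASES, MIDLINE_ROIS, ROI_NAMES

# (mean, sd) in cm^3 per ROI per group -- published cohort calibration.
TD_VOLUME_PARAMS: dict[str, tuple[float, float]] = {
    "left_lobules_I_V": (6.57, 0.93),
    "left_lobule_VI": (10.85, 1.44),
    "left_crus_I": (15.53, 1.96),
    "left_crus_II_VIIB": (15.45, 2.18),
    "left_lobule_VIII": (12.32, 1.74),
    "left_lobule_IX": (3.72, 0.67),
    "left_lobule_X": (0.61, 0.11),
    "right_lobules_I_V": (6.47, 0.98),
    "right_lobule_VI": (10.45, 1.48),
    "right_crus_I": (15.95, 2.04),
    "right_crus_II_VIIB": (14.35, 2.07),
    "right_lobule_VIII": (12.70, 1.63),
    "right_lobule_IX": (3.64, 0.67),
    "right_lobule_X": (0.60, 0.09),
    "vermis_I_V": (2.53, 0.30),
    "vermis_VI_VII": (1.65, 0.20),
    "vermis_VIII_X": (2.53, 0.32),
    "white_matter": (13.49, 1.41),
}
ASD_VOLUME_PARAMS: dict[str, tuple[float, float]] = {
    "left_lobules_I_V": (6.48, 0.99),
    "left_lobule_VI": (10.82, 1.18),
    "left_crus_I": (15.85, 2.05),
    "left_crus_II_VIIB": (15.34, 2.03),
    "left_lobule_VIII": (12.38, 1.51),
    "left_lobule_IX": (3.71, 0.66),
    "left_lobule_X": (0.59, 0.10),
    "right_lobules_I_V": (6.33, 0.93),
    "right_lobule_VI": (10.68, 1.20),
    "right_crus_I": (15.92, 2.34),
    "right_crus_II_VIIB": (14.02, 2.34),
    "right_lobule_VIII": (13.21, 1.94),
    "right_lobule_IX": (3.68, 0.66),
    "right_lobule_X": (0.62, 0.09),
    "vermis_I_V": (2.41, 0.33),
    "vermis_VI_VII": (1.54, 0.18),
    "vermis_VIII_X": (2.46, 0.31),
    "white_matter": (13.25, 1.25),
}

#: per-group white-matter growth with age (cm^3 / year), as reported for the
#: study cohort: positive in TD, near-flat in ASD.
DEFAULT_AGE_SLOPES: dict[str, dict[str, float]] = {
    "white_matter": {"TD": 0.129, "ASD": 0.035}
}


def _zeros() -> dict[str, float]:
    return {roi: 0.0 for roi in ROI_NAMES}


@dataclass(frozen=True)
class VolumeEffectsConfig:
    """Additive effect structure over the 18-ROI baseline.

    ``baseline`` holds TD (mean, sd) per ROI; ``group_shift`` moves ASD means;
    ``sex_shift`` moves female means; ``group_sex_shift`` moves ASD-female
    means on top of both; ``hemisphere_shift`` adds to the *left* member of a
    lateralized pair; ``age_slope`` (cm^3/year, per group) multiplies
    group-centered age.  ``noise_scale`` scales every residual SD.
    """

    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TD_VOLUME_PARAMS)
    )
    group_shift: dict[str, float] = field(
        default_factory=lambda: {
            roi: ASD_VOLUME_PARAMS[roi][0] - TD_VOLUME_PARAMS[roi][0]
            for roi in ROI_NAMES
        }
    )
    group_sd: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            roi: {"TD": TD_VOLUME_PARAMS[roi][1], "ASD": ASD_VOLUME_PARAMS[roi][1]}
            for roi in ROI_NAMES
        }
    )
    sex_shift: dict[str, float] = field(default_factory=_zeros)
    group_sex_shift: dict[str, float] = field(default_factory=_zeros)
    hemisphere_shift: dict[str, float] = field(
        default_factory=lambda: {base: 0.0 for base in LATERALIZED_BASES}
    )
    age_slope: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AGE_SLOPES.items()}
    )
    noise_scale: float = 1.0
    #: volumes are redrawn below this fraction of baseline to stay positive
    lower_bound_fraction: float = 0.1

    def __post_init__(self):
        missing = set(ROI_NAMES) - set(self.baseline)
        if missing:
            raise ValueError(f"baseline missing ROIs: {sorted(missing)}")
        for roi, (m, s) in self.baseline.items():
            if m <= 0:
                raise ValueError(f"baseline mean for {roi} must be > 0")
            if s < 0:
                raise ValueError(f"baseline SD for {roi} must be >= 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def generate_volume_table(
    participants: pd.DataFrame,
    effects: VolumeEffectsConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Participant x 18-ROI volume table (cm^3), one row per participant."""
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    for col in ("participant_id", "group", "sex", "age"):
        if col not in participants.columns:
            raise ValueError(f"participants table missing column {col!r}")
    eff = effects or VolumeEffectsConfig()
    rng = np.random.default_rng(seed)

    group = participants["group"].to_numpy()
    female = (participants["sex"].to_numpy() == "F").astype(float)
    asd = (group == "ASD").astype(float)
    age = participants["age"].to_numpy(dtype=float)
    age_c = age.copy()
    for g in np.unique(group):
        m = group == g
        age_c[m] = age[m] - age[m].mean()

    out = pd.DataFrame({"participant_id": participants["participant_id"].to_numpy()})
    for roi in ROI_NAMES:
        base_mean, base_sd = eff.baseline[roi]
        mean = (
            base_mean
            + asd * eff.group_shift.get(roi, 0.0)
            + female * eff.sex_shift.get(roi, 0.0)
            + asd * female * eff.group_sex_shift.get(roi, 0.0)
        )
        if roi.startswith("left_"):
            mean = mean + eff.hemisphere_shift.get(roi[len("left_"):], 0.0)
        slopes = eff.age_slope.get(roi, {})
        mean = mean + age_c * np.array([slopes.get(g, 0.0) for g in group])

        sd_by_group = eff.group_sd.get(roi, {"TD": base_sd, "ASD": base_sd})
        low = eff.lower_bound_fraction * base_mean
        vals = np.empty(len(out))
        for g in ("TD", "ASD"):
            m = group == g
            if not m.any():
                continue
            sd = sd_by_group.get(g, base_sd) * eff.noise_scale
            if sd == 0:
                vals[m] = np.maximum(mean[m], low)
            else:
                # moment-matched truncation on the group-mean offset scale
                noise = rvs_matched(0.0, sd, low - mean[m].mean(), np.inf, int(m.sum()), rng)
                vals[m] = np.maximum(mean[m] + noise, low)
        out[roi] = vals
    return out
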