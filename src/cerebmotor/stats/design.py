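"""Model specification and design coding for the association analyses.

All design factors in this study are two-level (group TD/ASD, sex M/F, hand,
hemisphere, target amplitude 12/24 deg, target direction), so every fixed
effect carries 1 numerator df.  Factors are coded 0/1 (second level = 1) and
interactions are products of the coded columns; continuous predictors are ROI
volume (cm^3) and group-mean-centered age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: factor -> (level coded 0, level coded 1)
FACTOR_LEVELS: dict[str, tuple] = {
    "group": ("TD", "ASD"),
    "sex": ("M", "F"),
    "hand": ("left", "right"),
    "hemisphere": ("left", "right"),
    "amplitude": (12.0, 24.0),
    "direction": ("leftward", "rightward"),
}
CONTINUOUS = ("age_c", "volume")


def center_age(table: pd.DataFrame, group_col: str = "group", age_col: str = "age") -> pd.DataFrame:
    """Add ``age_c``: age centered within each group (group-mean centering)."""
    if age_col not in table.columns or group_col not in table.columns:
        raise ValueError(f"need columns {age_col!r} and {group_col!r}")
    out = table.copy()
    grouped = out.groupby(group_col, observed=True)[age_col]
    if (grouped.size() == 0).any():
        raise ValueError("empty group")
    out["age_c"] = out[age_col] - grouped.transform("mean")
    return out


def encode_design(data: pd.DataFrame) -> pd.DataFrame:
    """Append 0/1 codes (suffix ``_c``) for every known factor present."""
    out = data.copy()
    for factor, (lo, hi) in FACTOR_LEVELS.items():
        if factor in out.columns:
            vals = out[factor]
            ok = vals.isin([lo, hi])
            if not ok.all():
                bad = sorted(set(vals[~ok]))
                raise ValueError(f"unknown levels for {factor}: {bad}")
            out[f"{factor}_c"] = (vals == hi).astype(float)
    return out


def term_columns(term: str, data: pd.DataFrame) -> np.ndarray:
    """Design column for a term such as ``group``, ``group:sex`` or ``volume``."""
    cols = []
    for part in term.split(":"):
        name = f"{part}_c" if part in FACTOR_LEVELS else part
        if name not in data.columns:
            raise ValueError(f"term {term!r}: column {name!r} not in data")
        cols.append(data[name].to_numpy(dtype=float))
    return np.prod(cols, axis=0)


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, predictor sets and interaction structure for one model."""

    outcome: str
    level1: tuple[str, ...] = ()
    level2: tuple[str, ...] = ()
    interactions: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()  # of no interest (never tested for pruning)
    random_intercept: bool = True
    group_col: str = "participant_id"

    def __post_init__(self):
        mains = set(self.level1) | set(self.level2) | set(self.covariates)
        for inter in self.interactions:
            for part in inter.split(":"):
                if part not in mains:
                    raise ValueError(
                        f"interaction {inter!r} references {part!r} without a main effect"
                    )

    @property
    def fixed_terms(self) -> tuple[str, ...]:
        return tuple(self.level1) + tuple(self.level2) + tuple(self.covariates) + tuple(
            self.interactions
        )

    def drop(self, term: str) -> "ModelSpec":
        if term not in self.interactions:
            raise ValueError(f"{term!r} is not an interaction of this spec")
        return ModelSpec(
            outcome=self.outcome,
            level1=self.level1,
            level2=self.level2,
            interactions=tuple(t for t in self.interactions if t != term),
            covariates=self.covariates,
            random_intercept=self.random_intercept,
            group_col=self.group_col,
        )


from ..rois import MIDLINE_ROIS  # noqa: E402  (re-exported for spec building)

#: confirmatory (FDR-controlled) ROI sets for the brain-behavior analyses
PRIMARY_GRIP_ROIS = ("lobules_I_V", "lobule_VI", "crus_I")
PRIMARY_SACCADE_ROIS = ("vermis_VI_VII",)


def build_spec(family: str, outcome: str, roi: str | None = None) -> ModelSpec:
    """Model spec for one analysis family.

    Families: ``behavior-group-grip``, ``behavior-group-saccade``,
    ``volume-group-lateralized``, ``volume-group-midline``,
    ``brain-behavior-grip``, ``brain-behavior-saccade``,
    ``brain-clinical-lateralized``, ``brain-clinical-midline``.
    """
    if family == "behavior-group-grip":
        return ModelSpec(
            outcome=outcome,
            level1=("hand",),
            level2=("group", "sex", "age_c"),
            interactions=("group:hand", "group:sex", "group:age_c"),
        )
    if family == "behavior-group-saccade":
        return ModelSpec(
            outcome=outcome,
            level1=("amplitude", "direction"),
            level2=("group", "sex", "age_c"),
            interactions=(
                "group:direction",
                "group:amplitude",
                "amplitude:direction",
                "group:sex",
                "group:age_c",
                "group:amplitude:direction",
            ),
        )
    if family == "volume-group-lateralized":
        if roi in MIDLINE_ROIS:
            raise ValueError(f"{roi!r} is a midline ROI; use volume-group-midline")
        return ModelSpec(
            outcome=outcome,
            level1=("hemisphere",),
            level2=("group", "sex", "age_c"),
            interactions=(
                "group:hemisphere",
                "group:sex",
                "group:age_c",
                "group:sex:hemisphere",
            ),
        )
    if family == "volume-group-midline":
        return ModelSpec(
            outcome=outcome,
            level2=("group", "sex", "age_c"),
            interactions=("group:sex", "group:age_c"),
            random_intercept=False,
        )
    if family == "brain-behavior-grip":
        return ModelSpec(
            outcome=outcome,
            level1=("hand",),
            level2=("group", "volume", "age_c"),
            covariates=("sex",),
            interactions=(
                "group:hand",
                "group:volume",
                "hand:volume",
                "group:hand:volume",
            ),
        )
    if family == "brain-behavior-saccade":
        return ModelSpec(
            outcome=outcome,
            level1=("amplitude", "direction"),
            level2=("group", "volume", "age_c"),
            covariates=("sex",),
            interactions=(
                "group:amplitude",
                "group:direction",
                "group:volume",
                "amplitude:volume",
                "direction:volume",
                "group:amplitude:volume",
                "group:direction:volume",
            ),
        )
    if family == "brain-clinical-lateralized":
        return ModelSpec(
            outcome=outcome,
            level1=("hemisphere",),
            level2=("volume", "sex"),
            interactions=("sex:volume",),
        )
    if family == "brain-clinical-midline":
        return ModelSpec(
            outcome=outcome,
            level2=("volume", "sex"),
            interactions=("sex:volume",),
            random_intercept=False,
        )
    raise ValueError(f"unknown analysis family {family!r}")
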