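"""Outcome-level simulators with injectable brain-behavior couplings.

Trace-level generators are the realistic route, but parameter-recovery and
type-I calibration studies of the association stage need thousands of model
fits; these helpers generate scored outcomes (trial-level log force CoV,
cell-level saccade error) directly from a linear mixed model with known
coefficients, a participant random intercept, and residual noise -- the
exact data-generating process the association models assume.

Coefficients are expressed over the 0/1 design codes used by the modelling
layer (group: ASD=1; sex: F=1; hand/hemisphere: right=1; amplitude: 24=1;
direction: rightward=1; ``age_c`` group-centered years; ``volume`` cm^3), so
an entry like ``{"group:volume": 0.5}`` injects a group-specific volume
slope that the matching family should recover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..stats.design import center_age, encode_design, term_columns


def _expand_grid(participants: pd.DataFrame, level1: dict[str, list]) -> pd.DataFrame:
    out = participants.copy()
    for name, levels in level1.items():
        out = out.merge(pd.DataFrame({name: levels}), how="cross")
    return out


def simulate_linear_outcomes(
    participants: pd.DataFrame,
    coefficients: dict[str, float],
    outcome: str = "y",
    level1: dict[str, list] | None = None,
    volume: pd.Series | pd.DataFrame | None = None,
    random_intercept_sd: float = 0.2,
    residual_sd: float = 0.2,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Long outcome table from a known linear mixed model.

    ``coefficients`` maps terms ("1" for the intercept, "group", "age_c",
    "volume", "group:volume", ...) to true values.  ``level1`` expands each
    participant over within-subject factor levels (e.g. ``{"hand": ["left",
    "right"]}``); ``n_reps`` repeats each cell (trial replicates).
    ``volume`` (indexed like ``participants``) attaches an ROI volume column.
    """
    rng = np.random.default_rng(seed)
    pt = center_age(participants)
    if volume is not None:
        pt = pt.assign(volume=np.asarray(volume, dtype=float))
    data = _expand_grid(pt, level1 or {})
    if n_reps > 1:
        data = data.merge(pd.DataFrame({"trial_id": range(1, n_reps + 1)}), how="cross")
    enc = encode_design(data)

    mu = np.zeros(len(enc))
    for term, coef in coefficients.items():
        if term == "1":
            mu += coef
        else:
            mu += coef * term_columns(term, enc)

    u = rng.normal(0, random_intercept_sd, size=len(pt))
    u_map = dict(zip(pt["participant_id"], u))
    mu += np.array([u_map[p] for p in enc["participant_id"]])
    mu += rng.normal(0, residual_sd, size=len(enc))
    data[outcome] = mu
    return data


def simulate_grip_outcomes(
    participants: pd.DataFrame,
    coefficients: dict[str, float] | None = None,
    volume: pd.Series | None = None,
    trials_per_hand: int = 3,
    random_intercept_sd: float = 0.25,
    residual_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Trial-level log force CoV with optional volume couplings."""
    coefs = {"1": float(np.log(0.05)), "group": 0.3, "age_c": -0.03}
    if coefficients:
        coefs.update(coefficients)
    out = simulate_linear_outcomes(
        participants,
        coefs,
        outcome="log_cov",
        level1={"hand": ["left", "right"]},
        volume=volume,
        random_intercept_sd=random_intercept_sd,
        residual_sd=residual_sd,
        n_reps=trials_per_hand,
        seed=seed,
    )
    out["valid"] = True
    return out


def simulate_saccade_outcomes(
    participants: pd.DataFrame,
    coefficients: dict[str, float] | None = None,
    volume: pd.Series | None = None,
    random_intercept_sd: float = 0.3,
    residual_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-level mean saccade error (deg) with optional volume couplings."""
    coefs = {"1": 1.2, "amplitude": 0.8, "direction": -0.1}
    if coefficients:
        coefs.update(coefficients)
    out = simulate_linear_outcomes(
        participants,
        coefs,
        outcome="mean_error",
        level1={"amplitude": [12.0, 24.0], "direction": ["leftward", "rightward"]},
        volume=volume,
        random_intercept_sd=random_intercept_sd,
        residual_sd=residual_sd,
        seed=seed,
    )
    return out
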