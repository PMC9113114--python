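"""Analysis-family orchestration: joins scored behavior, ROI volumes and
clinical scores, runs the pruned mixed models per family, and applies
Benjamini-Hochberg control within each confirmatory family.

Family structure:

* behavior group contrasts (force variability; saccade error / error SD);
* volume group contrasts (7 lateralized ROI models with a hemisphere
  level-1 factor; 4 midline regressions) -- BH-corrected per set;
* brain-behavior associations: per-ROI models, confirmatory for the primary
  ROI sets (grip: lobules I-V, VI, Crus I per side; saccades: vermal VI-VII)
  and exploratory (uncorrected) for all other ROIs;
* brain-clinical associations in the ASD arm (ADOS severity, RBS-R total),
  exploratory, with sex x volume moderation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..rois import LATERALIZED_BASES, MIDLINE_ROIS
from .design import (
    PRIMARY_GRIP_ROIS,
    PRIMARY_SACCADE_ROIS,
    build_spec,
    center_age,
)
from .fdr import benjamini_hochberg
from .lmm import FittedModel, prune_interactions

PARTICIPANT_COLS = ["participant_id", "group", "sex", "age_c"]


def _participants_centered(participants: pd.DataFrame) -> pd.DataFrame:
    return center_age(participants)[PARTICIPANT_COLS + ["ados_css", "rbsr_total"]]


def _outcome_view(table: pd.DataFrame, level1, outcome: str) -> pd.DataFrame:
    """Only the columns a family needs: id, level-1 factors, the outcome.

    Keeps joins unambiguous when an outcome table already carries
    participant-level columns (as the outcome-level simulators do)."""
    cols = ["participant_id", *level1, outcome]
    return table[cols]


def _terms_table(fitted: FittedModel, family: str, roi: str | None, model: str) -> pd.DataFrame:
    t = fitted.terms.copy()
    t.insert(0, "family", family)
    t.insert(1, "roi", roi or "")
    t.insert(2, "model", model)
    t["method"] = fitted.method
    t["pruned_terms"] = "; ".join(r["term"] for r in fitted.pruning_trace)
    return t


def run_behavior_group_family(
    grip_results: pd.DataFrame, participants: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """Group contrast on log force CoV (trial-level, hand as level 1)."""
    pt = _participants_centered(participants)
    valid = grip_results[grip_results["valid"]]
    data = _outcome_view(valid, ["hand"], "log_cov").merge(pt, on="participant_id")
    spec = build_spec("behavior-group-grip", "log_cov")
    fitted = prune_interactions(spec, data)
    return _terms_table(fitted, "behavior-group", None, "log_cov"), {"log_cov": fitted}


def run_saccade_group_family(
    summaries: pd.DataFrame, participants: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """Group contrasts on saccade error and error variability (cell-level)."""
    pt = _participants_centered(participants)
    tables, fits = [], {}
    for outcome in ("mean_error", "error_sd"):
        sub = summaries.dropna(subset=[outcome])
        data = _outcome_view(sub, ["amplitude", "direction"], outcome).merge(
            pt, on="participant_id"
        )
        spec = build_spec("behavior-group-saccade", outcome)
        fitted = prune_interactions(spec, data)
        tables.append(_terms_table(fitted, "behavior-group", None, outcome))
        fits[outcome] = fitted
    return pd.concat(tables, ignore_index=True), fits


def _lateral_long(volumes: pd.DataFrame, base: str) -> pd.DataFrame:
    rows = []
    for hemi in ("left", "right"):
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": volumes["participant_id"],
                    "hemisphere": hemi,
                    "volume": volumes[f"{hemi}_{base}"],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_volume_group_family(
    volumes: pd.DataFrame, participants: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """Group contrasts per ROI; BH across each ROI set's group terms."""
    pt = _participants_centered(participants)
    tables, fits = [], {}
    for base in LATERALIZED_BASES:
        data = _lateral_long(volumes, base).merge(pt, on="participant_id")
        spec = build_spec("volume-group-lateralized", "volume", roi=base)
        fitted = prune_interactions(spec, data)
        tables.append(_terms_table(fitted, "volume-group-lateralized", base, "volume"))
        fits[base] = fitted
    for roi in MIDLINE_ROIS:
        data = volumes[["participant_id", roi]].rename(columns={roi: "volume"}).merge(
            pt, on="participant_id"
        )
        spec = build_spec("volume-group-midline", "volume")
        fitted = prune_interactions(spec, data)
        tables.append(_terms_table(fitted, "volume-group-midline", roi, "volume"))
        fits[roi] = fitted
    table = pd.concat(tables, ignore_index=True)
    table = _apply_bh(table, family_terms={"volume-group-lateralized": "group",
                                           "volume-group-midline": "group"})
    return table, fits


def _roi_volume_columns() -> list[tuple[str, str]]:
    """(model label, volume column) pairs covering all 18 ROIs."""
    out = [
        (f"{hemi}_{base}", f"{hemi}_{base}")
        for base in LATERALIZED_BASES
        for hemi in ("left", "right")
    ]
    out += [(roi, roi) for roi in MIDLINE_ROIS]
    return out


def _is_primary(roi_col: str, primary_bases: tuple[str, ...]) -> bool:
    base = roi_col.split("_", 1)[1] if roi_col.startswith(("left_", "right_")) else roi_col
    return base in primary_bases


def run_brain_behavior_family(
    outcome_table: pd.DataFrame,
    volumes: pd.DataFrame,
    participants: pd.DataFrame,
    modality: str,
    outcome: str,
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """Per-ROI brain-behavior models; BH over the primary ROI set only.

    ``modality``: "grip" (hand level 1) or "saccade" (amplitude/direction
    level 1).  ``outcome_table`` is trial-level (grip) or cell-level
    (saccades) and must carry ``participant_id``.
    """
    pt = _participants_centered(participants)
    primary = PRIMARY_GRIP_ROIS if modality == "grip" else PRIMARY_SACCADE_ROIS
    family = f"brain-behavior-{modality}"
    tables, fits = [], {}
    level1 = ["hand"] if modality == "grip" else ["amplitude", "direction"]
    view = _outcome_view(outcome_table, level1, outcome)
    for label, col in _roi_volume_columns():
        vol = volumes[["participant_id", col]].rename(columns={col: "volume"})
        data = view.merge(vol, on="participant_id").merge(pt, on="participant_id")
        spec = build_spec(family, outcome)
        fitted = prune_interactions(spec, data)
        tab = _terms_table(fitted, family, label, outcome)
        tab["confirmatory"] = _is_primary(col, primary)
        tables.append(tab)
        fits[label] = fitted
    table = pd.concat(tables, ignore_index=True)
    table = _apply_bh(
        table, family_terms={family: "volume"}, confirmatory_only=True
    )
    return table, fits


def run_clinical_family(
    volumes: pd.DataFrame, participants: pd.DataFrame, outcome: str
) -> tuple[pd.DataFrame, dict[str, FittedModel]]:
    """ASD-only clinical associations (exploratory, uncorrected)."""
    pt = center_age(participants)
    pt = pt[pt["group"] == "ASD"][
        ["participant_id", "sex", "age_c", "ados_css", "rbsr_total"]
    ]
    tables, fits = [], {}
    for base in LATERALIZED_BASES:
        data = _lateral_long(volumes, base).merge(pt, on="participant_id")
        data = data.dropna(subset=[outcome])
        spec = build_spec("brain-clinical-lateralized", outcome)
        fitted = prune_interactions(spec, data)
        tab = _terms_table(fitted, "brain-clinical", base, outcome)
        tab["confirmatory"] = False
        tables.append(tab)
        fits[base] = fitted
    for roi in MIDLINE_ROIS:
        data = volumes[["participant_id", roi]].rename(columns={roi: "volume"}).merge(
            pt, on="participant_id"
        )
        data = data.dropna(subset=[outcome])
        spec = build_spec("brain-clinical-midline", outcome)
        fitted = prune_interactions(spec, data)
        tab = _terms_table(fitted, "brain-clinical", roi, outcome)
        tab["confirmatory"] = False
        tables.append(tab)
        fits[roi] = fitted
    return pd.concat(tables, ignore_index=True), fits


def _apply_bh(
    table: pd.DataFrame,
    family_terms: dict[str, str],
    q: float = 0.05,
    confirmatory_only: bool = False,
) -> pd.DataFrame:
    """Flag BH decisions for the designated term within each family."""
    out = table.copy()
    out["bh_family"] = False
    out["bh_rejected"] = pd.NA
    out["bh_p_crit"] = np.nan
    for fam, term in family_terms.items():
        mask = (out["family"] == fam) & (out["term"] == term)
        if confirmatory_only and "confirmatory" in out.columns:
            mask &= out["confirmatory"].fillna(False).astype(bool)
        if not mask.any():
            continue
        res = benjamini_hochberg(out.loc[mask, "p"].tolist(), q=q, family=fam)
        out.loc[mask, "bh_family"] = True
        out.loc[mask, "bh_rejected"] = list(res.rejected)
        out.loc[mask, "bh_p_crit"] = res.p_crit
    return out


def run_all_families(
    participants: pd.DataFrame,
    grip_results: pd.DataFrame | None = None,
    saccade_summary: pd.DataFrame | None = None,
    volumes: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every family the supplied inputs allow; returns tidy tables."""
    out: dict[str, pd.DataFrame] = {}
    if grip_results is not None:
        out["behavior_group_grip"], _ = run_behavior_group_family(grip_results, participants)
    if saccade_summary is not None:
        out["behavior_group_saccade"], _ = run_saccade_group_family(
            saccade_summary, participants
        )
    if volumes is not None:
        out["volume_group"], _ = run_volume_group_family(volumes, participants)
        if grip_results is not None:
            out["brain_behavior_grip"], _ = run_brain_behavior_family(
                grip_results[grip_results["valid"]],
                volumes,
                participants,
                "grip",
                "log_cov",
            )
        if saccade_summary is not None:
            out["brain_behavior_saccade_error"], _ = run_brain_behavior_family(
                saccade_summary.dropna(subset=["mean_error"]),
                volumes,
                participants,
                "saccade",
                "mean_error",
            )
        if (participants["group"] == "ASD").any():
            for outcome in ("ados_css", "rbsr_total"):
                key = f"clinical_{outcome}"
                out[key], _ = run_clinical_family(volumes, participants, outcome)
    return out
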