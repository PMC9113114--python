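"""Cerebellar ROI volume-table ingestion.

Normalizes external segmentation output into the 18-ROI schema used by the
association stage: left/right lobules I-V, lobule VI, Crus I, Crus II/VIIB
(reported jointly), lobule VIII, lobule IX, lobule X, plus vermal composites
I-V, VI-VII, VIII-X and cerebellar white matter.  Finer per-lobule labels
from common segmentation tools are summed into these composites via a
configurable alias map; volumes are converted to cm^3.  Raw volumes are kept
as-is (no intracranial-volume normalization).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .rois import ROI_NAMES

ID_COLUMN = "participant_id"
_ID_ALIASES = ("participant_id", "participant", "subject", "subject_id", "id")


def load_alias_map(path: str | Path | None = None) -> dict[str, list[list[str]]]:
    """Canonical ROI -> list of alternatives; each alternative is a list of
    source columns summed into the composite (a bare string is a 1-list)."""
    if path is None:
        src = resources.files("cerebmotor").joinpath("data/roi_aliases.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    amap: dict[str, list[list[str]]] = {}
    for roi, alternatives in raw.items():
        parsed = []
        for alt in alternatives:
            parts = [alt] if isinstance(alt, str) else list(alt)
            parsed.append([str(p).lower().strip() for p in parts])
        amap[roi] = parsed
    unknown = set(amap) - set(ROI_NAMES)
    if unknown:
        raise ValueError(f"alias map contains non-canonical ROIs: {sorted(unknown)}")
    return amap


def load_volume_table(
    path: str | Path,
    unit: str = "cm3",
    alias_map: dict[str, list[list[str]]] | None = None,
) -> pd.DataFrame:
    """Read a participant x ROI CSV into the canonical 18-column schema.

    ``unit`` is ``"cm3"`` or ``"mm3"`` (converted).  Missing canonical ROIs
    raise a named error; unknown columns are reported in the error rather
    than silently dropped; non-positive volumes raise with the offending
    rows named.
    """
    if unit not in ("cm3", "mm3"):
        raise ValueError(f"unit must be 'cm3' or 'mm3', got {unit!r}")
    df = pd.read_csv(path)
    amap = alias_map or load_alias_map()
    lower = {c.lower().strip(): c for c in df.columns}

    id_col = next((lower[a] for a in _ID_ALIASES if a in lower), None)
    if id_col is None:
        raise ValueError(f"no participant-id column found (tried {_ID_ALIASES})")

    out = pd.DataFrame({ID_COLUMN: df[id_col]})
    consumed = {id_col.lower().strip()}
    missing = []
    for roi in ROI_NAMES:
        alternatives = [[roi.lower()]] + amap.get(roi, [])
        cols: list[str] = []
        for alt in alternatives:
            # an alternative applies only if every one of its parts is present
            if all(p in lower for p in alt):
                cols = [lower[p] for p in alt]
                break
        if not cols:
            missing.append(roi)
            continue
        consumed.update(c.lower().strip() for c in cols)
        out[roi] = df[cols].sum(axis=1)

    if missing:
        raise ValueError(f"volume table missing ROI columns: {missing}")

    leftovers = [c for c in df.columns if c.lower().strip() not in consumed]
    if leftovers:
        raise ValueError(
            f"unrecognized columns (map them or remove them): {leftovers}"
        )

    if unit == "mm3":
        out[list(ROI_NAMES)] = out[list(ROI_NAMES)] / 1000.0

    bad = out.index[(out[list(ROI_NAMES)] <= 0).any(axis=1)]
    if len(bad):
        ids = out.loc[bad, ID_COLUMN].tolist()
        raise ValueError(f"non-positive volumes for participants: {ids}")
    return out


def save_volume_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def derive_composites(table: pd.DataFrame) -> pd.DataFrame:
    """Append ``total_cerebellum`` = exact sum of the 18 ROI columns."""
    missing = [r for r in ROI_NAMES if r not in table.columns]
    if missing:
        raise ValueError(f"table missing ROI columns: {missing}")
    out = table.copy()
    out["total_cerebellum"] = out[list(ROI_NAMES)].sum(axis=1)
    return out


def to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Lateralized ROIs to long form: participant, roi base, hemisphere, volume."""
    records = []
    for roi in ROI_NAMES:
        if roi.startswith(("left_", "right_")):
            hemi, base = roi.split("_", 1)
        else:
            hemi, base = "midline", roi
        sub = table[[ID_COLUMN, roi]].rename(columns={roi: "volume"})
        sub = sub.assign(roi=base, hemisphere=hemi)
        records.append(sub)
    return pd.concat(records, ignore_index=True)
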