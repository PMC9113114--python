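"""Plain-text interchange formats for trials, manifests and tables.

Force trials: CSV with columns ``time,force`` (s, N).  Gaze trials: CSV with
``time_ms,x_deg,y_deg``.  Each trial family is indexed by a manifest CSV
carrying per-trial metadata and relative file paths, so every scoring stage
can run from files alone.  A run manifest (YAML) records seeds and configs
for bit-for-bit reproduction.  A minimal reader for the EyeLink ASC sample
dialect (``time xpos ypos pupil``) is provided with pixel-to-degree
conversion.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grip import ForceTimeSeries
from .saccades import GazeTimeSeries

FORCE_MANIFEST = "grip_manifest.csv"
GAZE_MANIFEST = "gaze_manifest.csv"


def write_force_trials(trials: list[ForceTimeSeries], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "force").mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        rel = f"force/{tr.participant_id}_{tr.hand}_{tr.trial_id}.csv"
        pd.DataFrame({"time": tr.time, "force": tr.force}).to_csv(
            outdir / rel, index=False, float_format="%.6f"
        )
        rows.append(
            {
                "participant_id": tr.participant_id,
                "hand": tr.hand,
                "trial_id": tr.trial_id,
                "stop_cue_time": tr.stop_cue_time,
                "path": rel,
            }
        )
    manifest = outdir / FORCE_MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_force_trials(manifest: str | Path) -> list[ForceTimeSeries]:
    manifest = Path(manifest)
    meta = pd.read_csv(manifest)
    trials = []
    for row in meta.itertuples(index=False):
        path = manifest.parent / row.path
        try:
            df = pd.read_csv(path)
            trials.append(
                ForceTimeSeries(
                    time=df["time"].to_numpy(),
                    force=df["force"].to_numpy(),
                    stop_cue_time=float(row.stop_cue_time),
                    hand=row.hand,
                    trial_id=row.trial_id,
                    participant_id=row.participant_id,
                )
            )
        except Exception as exc:
            raise ValueError(f"corrupt force trial file {path}: {exc}") from exc
    return trials


def write_gaze_trials(trials: list[GazeTimeSeries], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "gaze").mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trials:
        rel = f"gaze/{tr.participant_id}_b{tr.block}_{tr.trial_id}.csv"
        pd.DataFrame({"time_ms": tr.time, "x_deg": tr.x, "y_deg": tr.y}).to_csv(
            outdir / rel, index=False, float_format="%.4f"
        )
        rows.append(
            {
                "participant_id": tr.participant_id,
                "trial_id": tr.trial_id,
                "block": tr.block,
                "target_amplitude": tr.target_amplitude,
                "target_onset_time": tr.target_onset_time,
                "path": rel,
            }
        )
    manifest = outdir / GAZE_MANIFEST
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_gaze_trials(manifest: str | Path) -> list[GazeTimeSeries]:
    manifest = Path(manifest)
    meta = pd.read_csv(manifest)
    trials = []
    for row in meta.itertuples(index=False):
        path = manifest.parent / row.path
        try:
            df = pd.read_csv(path)
            trials.append(
                GazeTimeSeries(
                    time=df["time_ms"].to_numpy(),
                    x=df["x_deg"].to_numpy(),
                    y=df["y_deg"].to_numpy(),
                    target_amplitude=float(row.target_amplitude),
                    target_onset_time=float(row.target_onset_time),
                    trial_id=row.trial_id,
                    participant_id=row.participant_id,
                    block=int(row.block),
                )
            )
        except Exception as exc:
            raise ValueError(f"corrupt gaze trial file {path}: {exc}") from exc
    return trials


def read_eyelink_asc_samples(
    path: str | Path,
    target_amplitude: float,
    target_onset_time: float,
    pixels_per_degree: float = 1.0,
    screen_center: tuple[float, float] = (0.0, 0.0),
    participant_id: str = "",
    trial_id: int | str = 1,
    block: int = 1,
) -> GazeTimeSeries:
    """Parse EyeLink ASC sample lines (``time xpos ypos pupil``).

    Non-sample lines (events, messages) are skipped; missing samples
    (dots) become NaN.  Positions are converted from screen pixels to
    degrees relative to ``screen_center``.
    """
    t, xs, ys = [], [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 4 or not parts[0].replace(".", "", 1).isdigit():
            continue

        def _num(tok: str) -> float:
            try:
                return float(tok)
            except ValueError:
                return np.nan

        t.append(float(parts[0]))
        xs.append(_num(parts[1]))
        ys.append(_num(parts[2]))
    if not t:
        raise ValueError(f"no sample lines found in {path}")
    x = (np.array(xs) - screen_center[0]) / pixels_per_degree
    y = (np.array(ys) - screen_center[1]) / pixels_per_degree
    return GazeTimeSeries(
        time=np.array(t),
        x=x,
        y=y,
        target_amplitude=target_amplitude,
        target_onset_time=target_onset_time,
        trial_id=trial_id,
        participant_id=participant_id,
        block=block,
    )


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_run_manifest(path: str | Path, **sections) -> None:
    """YAML manifest of seeds and configs sufficient to reproduce a run."""
    Path(path).write_text(
        yaml.safe_dump(_to_plain(sections), sort_keys=True, default_flow_style=False)
    )
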