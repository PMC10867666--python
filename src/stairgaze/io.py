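"""Readers and writers for the per-participant recording directories.

One directory per participant per direction, holding plain-text CSVs:

* ``gaze.csv``    — t_s, az_deg, el_deg         (nominal 200 Hz)
* ``imu.csv``     — t_s, z_disp                 (vertical head displacement)
* ``frames.csv``  — t_s, label                  (nominal 30 Hz AOI labels)
* ``blinks.csv``  — start_s, end_s
* ``meta.json``   — participant, group, direction, staircase geometry
* ``ground_truth.json`` (generator output only)

A cohort directory holds one sub-directory per walk plus ``manifest.json``.
All timestamps are seconds as floats; files are UTF-8, comma-delimited,
with a header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import StaircaseGeometry, make_staircase
from .synth import (
    AoiLayout,
    GeneratorParams,
    GroundTruth,
    ParticipantMeta,
    Recording,
    TrueFixation,
    TrueSaccade,
)
from .traces import FrameLabels, GazeTrace, ImuTrace, StepRef, parse_label


class LoadError(ValueError):
    """A recording file is missing or malformed; the message names the file
    and, where possible, the row."""


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.is_file():
        raise LoadError(f"{path.name}: file not found in {path.parent}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LoadError(f"{path.name}: missing columns {missing}")
    return df


def _check_monotonic(t: np.ndarray, fname: str) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        # the offending sample is the second of the pair; +2 for header row
        # and 1-based numbering
        raise LoadError(f"{fname}: non-increasing timestamp at row {int(bad[0]) + 3}")


def write_recording(out_dir: str | Path, rec: Recording, truth: GroundTruth | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_s": rec.gaze.t, "az_deg": rec.gaze.az, "el_deg": rec.gaze.el}).to_csv(
        out / "gaze.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame({"t_s": rec.imu.t, "z_disp": rec.imu.z}).to_csv(
        out / "imu.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame({"t_s": rec.frames.t, "label": rec.frames.labels}).to_csv(
        out / "frames.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame(rec.blinks, columns=["start_s", "end_s"]).to_csv(
        out / "blinks.csv", index=False, float_format="%.6f"
    )
    meta = {
        "participant": rec.meta.participant,
        "group": rec.meta.group,
        "direction": rec.meta.direction,
        "staircases": [
            {"n_steps": g.n_steps, "run_cm": g.run_cm, "rise_cm": g.rise_cm}
            for g in rec.staircases
        ],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(_truth_to_json(truth), indent=1))
    return out


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "saccades": [dataclasses.asdict(s) for s in truth.saccades],
        "fixation_sequence": [
            {"label": str(f.label), "start_s": f.start_s, "end_s": f.end_s}
            for f in truth.fixation_sequence
        ],
        "foot_placements": [list(map(float, p)) for p in truth.foot_placements],
        "layout": dataclasses.asdict(truth.layout),
        "params": dataclasses.asdict(truth.params),
    }


def _truth_from_json(d: dict) -> GroundTruth:
    # JSON object keys are strings; offset weights are integer-keyed
    params = dict(d["params"])
    params["step_offset_weights"] = {
        int(k): v for k, v in params["step_offset_weights"].items()
    }
    d = {**d, "params": params}
    return GroundTruth(
        saccades=[TrueSaccade(**s) for s in d["saccades"]],
        fixation_sequence=[
            TrueFixation(parse_label(f["label"]), f["start_s"], f["end_s"])
            for f in d["fixation_sequence"]
        ],
        foot_placements=[np.asarray(p) for p in d["foot_placements"]],
        params=GeneratorParams(**d["params"]),
        layout=AoiLayout(**d["layout"]),
    )


def read_recording(rec_dir: str | Path) -> Recording:
    """Load and validate one recording directory."""
    d = Path(rec_dir)
    meta_path = d / "meta.json"
    if not meta_path.is_file():
        raise LoadError(f"meta.json: file not found in {d}")
    meta = json.loads(meta_path.read_text())
    staircases = tuple(
        make_staircase(s["n_steps"], s["run_cm"], s["rise_cm"]) for s in meta["staircases"]
    )

    g = _read_csv(d / "gaze.csv", ["t_s", "az_deg", "el_deg"])
    _check_monotonic(g["t_s"].to_numpy(), "gaze.csv")
    gaze = GazeTrace(g["t_s"].to_numpy(), g["az_deg"].to_numpy(), g["el_deg"].to_numpy())

    m = _read_csv(d / "imu.csv", ["t_s", "z_disp"])
    _check_monotonic(m["t_s"].to_numpy(), "imu.csv")
    imu = ImuTrace(m["t_s"].to_numpy(), m["z_disp"].to_numpy())

    f = _read_csv(d / "frames.csv", ["t_s", "label"])
    _check_monotonic(f["t_s"].to_numpy(), "frames.csv")
    frames = FrameLabels(f["t_s"].to_numpy(), f["label"].astype(str).to_numpy())
    n_by_stair = {i + 1: geo.n_steps for i, geo in enumerate(staircases)}
    try:
        frames.validate_labels(n_by_stair)
    except ValueError as e:
        raise LoadError(f"frames.csv: {e}") from e

    b = _read_csv(d / "blinks.csv", ["start_s", "end_s"])
    blinks = [(float(r.start_s), float(r.end_s)) for r in b.itertuples()]
    for i, (s, e) in enumerate(blinks):
        if e <= s:
            raise LoadError(f"blinks.csv: inverted interval at row {i + 2}")

    return Recording(
        gaze, imu, frames, blinks, staircases,  # type: ignore[arg-type]
        ParticipantMeta(meta["participant"], meta["group"], meta["direction"]),
    )


def read_ground_truth(rec_dir: str | Path) -> GroundTruth:
    path = Path(rec_dir) / "ground_truth.json"
    if not path.is_file():
        raise LoadError(f"ground_truth.json: file not found in {rec_dir}")
    return _truth_from_json(json.loads(path.read_text()))


def write_cohort(
    out_dir: str | Path,
    walks: list[tuple[Recording, GroundTruth]],
    exclusions: list[dict] | None = None,
) -> Path:
    """Write every walk to ``<participant>_<direction>/`` plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec, truth in walks:
        name = f"{rec.meta.participant}_{rec.meta.direction}"
        write_recording(out / name, rec, truth)
        entries.append(
            {
                "dir": name,
                "participant": rec.meta.participant,
                "group": rec.meta.group,
                "direction": rec.meta.direction,
            }
        )
    manifest = {"recordings": entries, "exclusions": exclusions or []}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(cohort_dir: str | Path) -> tuple[list[Recording], dict]:
    d = Path(cohort_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.is_file():
        raise LoadError(f"manifest.json: file not found in {d}")
    manifest = json.loads(manifest_path.read_text())
    recs = [read_recording(d / e["dir"]) for e in manifest["recordings"]]
    return recs, manifest
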