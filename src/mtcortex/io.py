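"""CSV schemas for traces, detections, tracks, events and measurements.

All tables are plain CSV with µm coordinates at full float precision.
Readers validate the documented schema and raise errors that name the
file and the offending column; unknown extra columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detection import CometDetection
from .geometry import InvalidParameterError, PolyPath
from .tracks import CometTrack


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# -- polyline traces --------------------------------------------------------

def write_polypaths(path: str | Path, paths: list[PolyPath]) -> None:
    rows = []
    for p in paths:
        for i, (x, y) in enumerate(p.vertices):
            rows.append({"path_id": p.path_id, "kind": p.kind,
                         "vertex_index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_polypaths(path: str | Path) -> list[PolyPath]:
    df = pd.read_csv(path)
    _require(df, ["path_id", "vertex_index", "x_um", "y_um"], path)
    paths = []
    for pid, g in df.groupby("path_id", sort=False):
        g = g.sort_values("vertex_index")
        kind = g["kind"].iloc[0] if "kind" in g.columns else "junction"
        try:
            paths.append(PolyPath(g[["x_um", "y_um"]].to_numpy(),
                                  kind=kind, path_id=str(pid)))
        except InvalidParameterError as exc:
            raise SchemaError(f"{path}: path {pid!r} invalid: {exc}") from exc
    return paths


# -- detections -------------------------------------------------------------

DETECTION_COLUMNS = ["image_id", "frame", "x_um", "y_um", "area_um2", "intensity"]


def write_detections(path: str | Path, detections: list[CometDetection]) -> None:
    pd.DataFrame([{"image_id": d.image_id, "frame": d.frame, "x_um": d.x,
                   "y_um": d.y, "area_um2": d.area, "intensity": d.intensity}
                  for d in detections]).to_csv(path, index=False)


def read_detections(path: str | Path) -> list[CometDetection]:
    df = pd.read_csv(path)
    _require(df, DETECTION_COLUMNS, path)
    return [CometDetection(x=r.x_um, y=r.y_um, area=r.area_um2,
                           intensity=r.intensity, frame=int(r.frame),
                           image_id=None if pd.isna(r.image_id) else str(r.image_id))
            for r in df.itertuples()]


# -- tracks -----------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "cell_id", "treatment", "frame", "x_um", "y_um"]


def write_tracks(path: str | Path, tracks: list[CometTrack]) -> None:
    rows = []
    for t in tracks:
        for fr, (x, y) in zip(t.frames, t.positions):
            rows.append({"track_id": t.track_id, "cell_id": t.cell_id,
                         "treatment": t.treatment, "frame": int(fr),
                         "x_um": x, "y_um": y,
                         "frame_interval_s": t.frame_interval})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path: str | Path, frame_interval: float | None = None) -> list[CometTrack]:
    df = pd.read_csv(path)
    _require(df, TRACK_COLUMNS, path)
    if frame_interval is None:
        if "frame_interval_s" not in df.columns:
            raise SchemaError(f"{path}: missing column(s) ['frame_interval_s'] "
                              "(or pass frame_interval=)")
    tracks = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        fi = frame_interval if frame_interval is not None else float(g.frame_interval_s.iloc[0])
        try:
            tracks.append(CometTrack(
                track_id=str(tid), frames=g.frame.to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(), frame_interval=fi,
                cell_id=str(g.cell_id.iloc[0]), treatment=str(g.treatment.iloc[0])))
        except InvalidParameterError as exc:
            raise SchemaError(f"{path}: track {tid!r} invalid: {exc}") from exc
    return tracks


# -- profiles ---------------------------------------------------------------

def write_profiles(path: str | Path, profiles, group: str = "") -> None:
    rows = []
    for pi, prof in enumerate(profiles):
        for k, (off, val) in enumerate(zip(prof.offsets, prof.samples)):
            rows.append({"group": group, "path_id": prof.path_id,
                         "position_index": pi, "sample_index": k,
                         "offset_um": off, "intensity": val})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_peaks(path: str | Path, peaks: np.ndarray, group: str,
                path_ids=None) -> None:
    pd.DataFrame({
        "group": group,
        "path_id": path_ids if path_ids is not None else [""] * len(peaks),
        "position_index": np.arange(len(peaks)),
        "peak": peaks,
    }).to_csv(path, index=False)


# -- tidy measurement tables ------------------------------------------------

def read_measurements(path: str | Path) -> dict[str, np.ndarray]:
    """Read a tidy (group, value) CSV into labelled arrays for group_stats."""
    df = pd.read_csv(path)
    _require(df, ["group", "value"], path)
    return {str(g): sub.value.to_numpy(dtype=float)
            for g, sub in df.groupby("group", sort=False)}
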