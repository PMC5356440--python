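"""Comet-track linking and post-tracking dynamics analysis.

The scientific content here is the post-tracking pipeline applied to
plus-end comet trajectories: bend-based splitting of abnormally bendy
tracks (orientation change of consecutive segments above 30° splits the
track), classification of each track into growth and pause events by a
speed-threshold run-length rule, per-cell summaries of growth speed and
growth length, and the four-bin speed-group distribution whose upper edge
(vmax) is the mean speed plus one standard deviation of the fastest cell.

Linking per-frame detections into tracks is deliberately simple plumbing —
greedy mutual-nearest-neighbour association with gap tolerance — standing
in for dedicated trackers; it is validated only on low-density synthetic
fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import DegenerateInputError, InvalidParameterError, orientation_difference

logger = logging.getLogger(__name__)

SPEED_GROUP_LABELS = ("very slow", "slow", "fast", "very fast")


@dataclass
class CometTrack:
    """Time-ordered comet positions with calibration.

    ``frames`` are strictly increasing integers (gaps allowed after linking
    across missed detections); ``positions`` are µm; ``frame_interval`` is
    the acquisition interval in seconds.
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    frame_interval: float
    cell_id: str = "cell0"
    treatment: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=int)
        p = np.asarray(self.positions, dtype=float)
        if f.ndim != 1 or len(f) < 2:
            raise InvalidParameterError("a track needs at least 2 frames")
        if np.any(np.diff(f) <= 0):
            raise InvalidParameterError("frames must be strictly increasing")
        if p.shape != (len(f), 2) or not np.all(np.isfinite(p)):
            raise InvalidParameterError("positions must be finite (n_frames, 2)")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")
        self.frames = f
        self.positions = p

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def step_lengths(self) -> np.ndarray:
        """Per-segment displacement in µm."""
        d = np.diff(self.positions, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    def step_speeds(self) -> np.ndarray:
        """Per-segment speed in µm/min (gap-aware)."""
        dt_min = np.diff(self.frames) * self.frame_interval / 60.0
        return self.step_lengths() / dt_min


@dataclass
class TrackEvent:
    """A maximal growth or pause run within one track."""

    state: Literal["growth", "pause"]
    start_frame: int
    end_frame: int
    mean_speed: float     # µm/min over the event's segments
    path_length: float    # µm travelled during the event
    n_segments: int
    track_id: str = ""

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise InvalidParameterError("event end_frame must exceed start_frame")


@dataclass
class SpeedGroupTable:
    """Four-bin comet-speed distribution for one treatment."""

    treatment: str
    vmax: float
    edges: np.ndarray          # 5 non-decreasing edges, last = vmax
    labels: tuple = SPEED_GROUP_LABELS
    counts: np.ndarray = None
    percentages: np.ndarray = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) != 5 or np.any(np.diff(e) < 0) or abs(e[-1] - self.vmax) > 1e-9:
            raise InvalidParameterError("need 5 non-decreasing edges ending at vmax")
        self.edges = e
        if self.counts is not None and self.counts.sum() > 0:
            assert abs(self.percentages.sum() - 100.0) < 1e-6


# ---------------------------------------------------------------------------
# linking (plumbing)
# ---------------------------------------------------------------------------

def _xy(det) -> tuple[float, float]:
    if hasattr(det, "x"):
        return float(det.x), float(det.y)
    return float(det[0]), float(det[1])


def link_detections(per_frame: Sequence[Sequence], max_disp: float,
                    max_gap: int = 0, frame_interval: float = 1.0,
                    cell_id: str = "cell0", treatment: str = "control") -> list[CometTrack]:
    """Greedy mutual-nearest-neighbour linking of per-frame detections.

    Frame by frame, candidate (track, detection) pairs within
    ``max_disp x (frames elapsed)`` are assigned in order of increasing
    distance (so every accepted pair is mutually nearest among the
    remaining candidates).  A track that finds no detection for more than
    ``max_gap`` consecutive frames is closed.  Tracks shorter than 2 frames
    are dropped; each detection joins at most one track.
    """
    if max_disp <= 0:
        raise InvalidParameterError("max_disp must be positive")
    if max_gap < 0:
        raise InvalidParameterError("max_gap must be >= 0")
    active: list[dict] = []
    done: list[dict] = []
    for t, dets in enumerate(per_frame):
        pts = np.array([_xy(d) for d in dets]).reshape(-1, 2)
        # close tracks that have exceeded the gap budget
        still = []
        for tr in active:
            if t - tr["frames"][-1] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        pairs = []
        for ti, tr in enumerate(active):
            elapsed = t - tr["frames"][-1]
            budget = max_disp * elapsed
            d = np.hypot(pts[:, 0] - tr["pos"][-1][0], pts[:, 1] - tr["pos"][-1][1])
            for di in np.flatnonzero(d <= budget):
                pairs.append((float(d[di]), ti, int(di)))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            active[ti]["frames"].append(t)
            active[ti]["pos"].append(pts[di])
        for di in range(len(pts)):
            if di not in used_d:
                active.append({"frames": [t], "pos": [pts[di]]})
    done.extend(active)
    tracks = []
    for i, tr in enumerate(sorted(done, key=lambda d: (d["frames"][0], d["pos"][0][0]))):
        if len(tr["frames"]) < 2:
            continue
        tracks.append(CometTrack(
            track_id=f"track_{i}", frames=np.array(tr["frames"]),
            positions=np.array(tr["pos"]), frame_interval=frame_interval,
            cell_id=cell_id, treatment=treatment))
    return tracks


# ---------------------------------------------------------------------------
# bend-based splitting
# ---------------------------------------------------------------------------

def split_on_bend(track: CometTrack, theta_max: float = 30.0) -> list[CometTrack]:
    """Split a track wherever consecutive segments bend more than ``theta_max``.

    Segment orientations are frame-to-frame direction angles; the absolute
    difference between consecutive segment orientations is folded to
    [0°, 180°] and a split is made where it is *strictly greater* than the
    threshold.  Zero-length segments carry no direction and inherit the
    last defined orientation (they never trigger a split by themselves).
    Fragments keep their parent's calibration and metadata and get ids
    ``<parent>#k``.
    """
    d = np.diff(track.positions, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    angles = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    # carry last defined orientation through zero-length segments
    last = None
    eff = np.empty(len(angles))
    for i in range(len(angles)):
        if lengths[i] > 0:
            last = angles[i]
        eff[i] = np.nan if last is None else last
    split_after = []  # segment index i: split between segment i and i+1
    for i in range(len(angles) - 1):
        a, b = eff[i], eff[i + 1]
        if np.isnan(a) or np.isnan(b):
            continue
        if orientation_difference(a, b) > theta_max:
            split_after.append(i)
    if not split_after:
        return [track]
    fragments = []
    seg_start = 0
    bounds = split_after + [len(angles) - 1]
    for k, seg_end in enumerate(bounds):
        fr = track.frames[seg_start:seg_end + 2]
        pos = track.positions[seg_start:seg_end + 2]
        if len(fr) >= 2:
            fragments.append(CometTrack(
                track_id=f"{track.track_id}#{k}", frames=fr, positions=pos,
                frame_interval=track.frame_interval, cell_id=track.cell_id,
                treatment=track.treatment, meta=dict(track.meta)))
        seg_start = seg_end + 1
    return fragments


# ---------------------------------------------------------------------------
# growth/pause event classification
# ---------------------------------------------------------------------------

def segment_events(track: CometTrack, pause_speed_max: float = 1.5,
                   min_pause_frames: int = 2) -> list[TrackEvent]:
    """Classify a track into alternating growth and pause events.

    Per-segment speeds below ``pause_speed_max`` µm/min form pause events
    when they run for at least ``min_pause_frames`` consecutive segments;
    everything else is growth.  Events tile the track: contiguous,
    non-overlapping in segments, covering every frame.  A track with fewer
    segments than ``min_pause_frames`` yields a single event classified by
    its mean speed.
    """
    if pause_speed_max <= 0:
        raise InvalidParameterError("pause_speed_max must be positive")
    if min_pause_frames < 1:
        raise InvalidParameterError("min_pause_frames must be >= 1")
    speeds = track.step_speeds()
    lengths = track.step_lengths()
    n = len(speeds)

    def make_event(i: int, j: int, state: str) -> TrackEvent:
        return TrackEvent(state=state,
                          start_frame=int(track.frames[i]),
                          end_frame=int(track.frames[j + 1]),
                          mean_speed=float(speeds[i:j + 1].mean()),
                          path_length=float(lengths[i:j + 1].sum()),
                          n_segments=j - i + 1,
                          track_id=track.track_id)

    if n < min_pause_frames:
        state = "pause" if speeds.mean() < pause_speed_max else "growth"
        return [make_event(0, n - 1, state)]

    below = speeds < pause_speed_max
    is_pause = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= min_pause_frames:
                is_pause[i:j + 1] = True
            i = j + 1
        else:
            i += 1

    events: list[TrackEvent] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and is_pause[j + 1] == is_pause[i]:
            j += 1
        events.append(make_event(i, j, "pause" if is_pause[i] else "growth"))
        i = j + 1
    return events


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def events_table(tracks: Iterable[CometTrack],
                 events_per_track: Iterable[list[TrackEvent]]) -> pd.DataFrame:
    rows = []
    for track, events in zip(tracks, events_per_track):
        for k, ev in enumerate(events):
            rows.append({
                "track_id": track.track_id, "cell_id": track.cell_id,
                "treatment": track.treatment, "event_index": k,
                "state": ev.state, "start_frame": ev.start_frame,
                "end_frame": ev.end_frame, "mean_speed_um_min": ev.mean_speed,
                "length_um": ev.path_length, "n_segments": ev.n_segments,
            })
    return pd.DataFrame(rows)


def dynamics_summary(tracks: list[CometTrack],
                     events_per_track: list[list[TrackEvent]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-treatment comet-dynamics summary.

    Per cell: mean growth-event speed (µm/min), mean growth length (µm),
    percentage of events growing / pausing (denominator: all events), the
    same percentages by time (secondary convention), and comet count.  The
    treatment-level numbers are means of cell means — the cell, not the
    track, is the unit of replication.
    """
    if not tracks:
        raise DegenerateInputError("no tracks to summarize")
    table = events_table(tracks, events_per_track)
    if table.empty:
        raise DegenerateInputError("no events to summarize")
    cells = []
    for (treatment, cell), g in table.groupby(["treatment", "cell_id"]):
        growth = g[g.state == "growth"]
        if len(g) == 0:
            logger.warning("cell %s has no events; excluded", cell)
            continue
        # event duration in frames weights the percent-time convention
        dur = g.end_frame - g.start_frame
        cells.append({
            "treatment": treatment, "cell_id": cell,
            "mean_growth_speed_um_min": growth.mean_speed_um_min.mean() if len(growth) else np.nan,
            "mean_growth_length_um": growth.length_um.mean() if len(growth) else np.nan,
            "pct_events_growing": 100.0 * len(growth) / len(g),
            "pct_events_pausing": 100.0 * (len(g) - len(growth)) / len(g),
            "pct_time_growing": 100.0 * dur[g.state == "growth"].sum() / dur.sum(),
            "n_comets": g.track_id.nunique(),
            "n_events": len(g),
        })
    per_cell = pd.DataFrame(cells)
    per_treatment = per_cell.groupby("treatment").agg(
        mean_growth_speed_um_min=("mean_growth_speed_um_min", "mean"),
        mean_growth_length_um=("mean_growth_length_um", "mean"),
        pct_events_growing=("pct_events_growing", "mean"),
        pct_events_pausing=("pct_events_pausing", "mean"),
        pct_time_growing=("pct_time_growing", "mean"),
        n_cells=("cell_id", "nunique"),
    ).reset_index()
    return per_cell, per_treatment


def speed_groups(event_speeds: pd.DataFrame,
                 edges: np.ndarray | None = None) -> dict[str, SpeedGroupTable]:
    """Four-bin speed-group distribution per treatment with the vmax rule.

    ``event_speeds`` holds one row per growth event with columns
    ``cell_id``, ``treatment``, ``speed`` (µm/min).  The fastest cell is
    the cell with the highest mean speed across *all* treatments; vmax is
    that cell's mean plus one (sample) standard deviation.  Four equal-width
    bins partition [0, vmax]; the last bin is right-closed and speeds above
    vmax count in it, preserving resolution at low-to-medium speeds.
    """
    required = {"cell_id", "treatment", "speed"}
    if not required.issubset(event_speeds.columns):
        raise InvalidParameterError(f"event_speeds needs columns {sorted(required)}")
    if event_speeds.empty or (event_speeds.speed < 0).any():
        raise InvalidParameterError("speeds must be non-empty and >= 0")
    cell_means = event_speeds.groupby("cell_id").speed.mean()
    fastest = cell_means.idxmax()
    fast_speeds = event_speeds.loc[event_speeds.cell_id == fastest, "speed"]
    sd = float(fast_speeds.std(ddof=1)) if len(fast_speeds) > 1 else 0.0
    vmax = float(fast_speeds.mean()) + sd
    if vmax <= 0:
        raise DegenerateInputError("vmax must be positive (all speeds zero?)")
    if edges is None:
        edges = np.linspace(0.0, vmax, 5)
    tables: dict[str, SpeedGroupTable] = {}
    for treatment, g in event_speeds.groupby("treatment"):
        # bins [e0,e1), [e1,e2), [e2,e3), [e3,vmax]; speeds > vmax -> top bin
        idx = np.minimum(np.digitize(g.speed.to_numpy(), edges[1:4]), 3)
        counts = np.bincount(idx, minlength=4)
        tables[str(treatment)] = SpeedGroupTable(
            treatment=str(treatment), vmax=vmax, edges=np.asarray(edges),
            counts=counts, percentages=100.0 * counts / counts.sum())
    return tables
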