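"""Polyline geometry in calibrated (µm) coordinates.

All modules share one coordinate convention: continuous positions in µm,
origin at the top-left corner of the field, x increasing rightward and y
increasing downward (image convention).  Orientations of undirected
structures (junctions, fibrils) live on [0°, 180°); approach angles between
a filament and a junction tangent are acute, on [0°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from shapely.geometry import LineString, Point

PathKind = Literal["junction", "filament"]


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too small/empty for the operation."""


@dataclass
class PolyPath:
    """Ordered chain of 2D vertices in µm (a junction or microtubule trace).

    For filament traces the *last* vertex is the cortex-proximal end; the
    targeting metrics measure approach direction from the final segment.
    """

    vertices: np.ndarray
    kind: PathKind = "junction"
    path_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidParameterError("PolyPath needs >=2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("PolyPath vertices must be finite")
        seg = np.diff(v, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise InvalidParameterError("consecutive PolyPath vertices must be distinct")
        self.vertices = v

    # -- basic measures -------------------------------------------------
    @property
    def segment_vectors(self) -> np.ndarray:
        return np.diff(self.vertices, axis=0)

    @property
    def segment_lengths(self) -> np.ndarray:
        d = self.segment_vectors
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starts at 0)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)

    # -- local frames ----------------------------------------------------
    def point_at(self, s: float) -> np.ndarray:
        """Position at arc length ``s`` (clamped to [0, length])."""
        p = self.as_linestring().interpolate(float(np.clip(s, 0.0, self.length)))
        return np.array([p.x, p.y])

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent of the segment containing arc length ``s``.

        At interior vertices the tangent is the normalized mean of the two
        adjacent segment directions; ends use the single adjacent segment.
        """
        cum = self.arclengths
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(max(i, 0), len(cum) - 2)
        vecs = self.segment_vectors
        if s == cum[i] and 0 < i:  # exactly on an interior vertex
            t = _unit(vecs[i - 1]) + _unit(vecs[i])
            if np.hypot(*t) < 1e-12:  # anti-parallel hairpin: fall back
                t = vecs[i]
        else:
            t = vecs[i]
        return _unit(t)

    def normal_at(self, s: float) -> np.ndarray:
        """Unit normal (tangent rotated +90°: (tx, ty) -> (-ty, tx))."""
        tx, ty = self.tangent_at(s)
        return np.array([-ty, tx])

    def tangent_angle_at(self, s: float) -> float:
        """Tangent orientation in degrees, folded to [0°, 180°)."""
        tx, ty = self.tangent_at(s)
        return float(np.degrees(np.arctan2(ty, tx)) % 180.0)

    def distance_to(self, point: Iterable[float]) -> float:
        x, y = point
        return float(self.as_linestring().distance(Point(float(x), float(y))))

    def end_direction(self, window: float = 1.0) -> np.ndarray:
        """Unit direction of travel into the final vertex.

        Averages over the last ``window`` µm of the path, because cortical
        approach is a local property of the proximal tip, not of the whole
        trace.
        """
        if window <= 0:
            raise InvalidParameterError("window must be positive")
        start = self.point_at(max(self.length - window, 0.0))
        d = self.vertices[-1] - start
        if np.hypot(*d) < 1e-12:
            d = self.segment_vectors[-1]
        return _unit(d)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise InvalidParameterError("cannot normalize zero vector")
    return np.asarray(v, dtype=float) / n


def fold_orientation(deg: float | np.ndarray) -> np.ndarray | float:
    """Fold an angle in degrees onto the orientation range [0°, 180°)."""
    return np.mod(deg, 180.0)


def orientation_difference(a_deg, b_deg):
    """Absolute difference between two *directions*, folded to [0°, 180°]."""
    d = np.abs(np.mod(np.asarray(a_deg) - np.asarray(b_deg) + 180.0, 360.0) - 180.0)
    return d


def acute_angle(a_deg, b_deg):
    """Acute angle between two undirected orientations, in [0°, 90°]."""
    d = np.abs(np.mod(np.asarray(a_deg) - np.asarray(b_deg), 180.0))
    return np.minimum(d, 180.0 - d)


def fold_to_acute(deg):
    """Fold any angle in degrees into the acute range [0°, 90°] by reflection."""
    m = np.mod(np.asarray(deg, dtype=float), 180.0)
    return np.minimum(m, 180.0 - m)


def direction_angle(vec: np.ndarray) -> float:
    """Direction of a 2D vector in degrees on (-180°, 180°]."""
    return float(np.degrees(np.arctan2(vec[1], vec[0])))
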