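"""Microtubule cortical-targeting metrics.

Three complementary read-outs of how microtubules approach a cell-cell
junction:

* the percentage of microtubules approaching the cortex at perpendicular
  angles (45-90° to the junction tangent), scored per 10 x 10 µm cortical
  box;
* the number of microtubules making cortical contact per 10 µm of
  junction;
* an image-level nematic (structure-tensor) analysis giving the
  predominant orientation and 0-1 anisotropy of fibrillar texture in a
  region of interest, from the circular average of intensity gradients —
  reported relative to the junction tangent as an acute angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (DegenerateInputError, InvalidParameterError, PolyPath,
                       acute_angle, direction_angle, fold_orientation)
from .images import ImageGrid

DEFAULT_BOX_SIDE = 10.0       # µm
DEFAULT_D_CONTACT = 0.25      # µm (~2-3 px at 0.1 µm/px calibration)
PERPENDICULAR_RANGE = (45.0, 90.0)


@dataclass
class CorticalBox:
    """Axis-aligned square scoring region on the cortex."""

    centre: tuple[float, float]
    side: float = DEFAULT_BOX_SIDE
    junction_id: str | None = None
    box_id: str | None = None

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise InvalidParameterError("box side must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.centre
        r = self.side / 2.0
        return (cx - r, cy - r, cx + r, cy + r)

    def contains(self, x, y) -> np.ndarray:
        """Left/top edges inclusive, right/bottom exclusive (tiling-safe)."""
        x0, y0, x1, y1 = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


def box_on_junction(junction: PolyPath, side: float = DEFAULT_BOX_SIDE,
                    s: float | None = None) -> CorticalBox:
    """A cortical box centred on the junction (midpoint by default)."""
    s = junction.length / 2.0 if s is None else s
    cx, cy = junction.point_at(s)
    return CorticalBox((float(cx), float(cy)), side, junction.path_id)


@dataclass
class OrientationResult:
    """Predominant fibril orientation (degrees, [0°,180°)) and anisotropy."""

    orientation: float
    anisotropy: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not 0.0 <= self.anisotropy <= 1.0 + 1e-9:
            raise InvalidParameterError("anisotropy must lie in [0, 1]")


@dataclass
class PerpendicularScore:
    percentage: float      # NaN when undefined
    n_in_box: int
    n_perpendicular: int

    @property
    def defined(self) -> bool:
        return self.n_in_box > 0


def approach_angle(filament: PolyPath, junction: PolyPath,
                   window: float = 1.0) -> float:
    """Acute angle (degrees) between a filament's cortical approach and the
    local junction tangent.

    The approach direction is taken over the filament's cortex-proximal
    ``window`` µm (its last vertex is the proximal end); the junction
    tangent is evaluated at the point of the junction nearest that end.
    """
    tip = filament.vertices[-1]
    line = junction.as_linestring()
    from shapely.geometry import Point
    s = line.project(Point(tip[0], tip[1]))
    tangent_deg = junction.tangent_angle_at(float(s))
    approach_deg = fold_orientation(direction_angle(filament.end_direction(window)))
    return float(acute_angle(approach_deg, tangent_deg))


def perpendicular_fraction(filaments: list[PolyPath], junction: PolyPath,
                           box: CorticalBox, lo: float = PERPENDICULAR_RANGE[0],
                           hi: float = PERPENDICULAR_RANGE[1]) -> PerpendicularScore:
    """Percentage of in-box microtubules approaching at [lo, hi] degrees.

    Both bounds are inclusive (the perpendicular band is the closed range
    45-90°).  A filament is scored if its cortex-proximal end lies in the
    box; a box with no filaments yields an undefined (NaN) percentage that
    callers exclude from group means.
    """
    if not (0 <= lo < hi <= 90):
        raise InvalidParameterError("need 0 <= lo < hi <= 90 degrees")
    in_box = [f for f in filaments
              if bool(box.contains(f.vertices[-1, 0], f.vertices[-1, 1]))]
    if not in_box:
        return PerpendicularScore(float("nan"), 0, 0)
    angles = np.array([approach_angle(f, junction) for f in in_box])
    n_perp = int(np.count_nonzero((angles >= lo) & (angles <= hi)))
    return PerpendicularScore(100.0 * n_perp / len(in_box), len(in_box), n_perp)


def contacts_per_10um(filaments: list[PolyPath], junction: PolyPath,
                      d_contact: float = DEFAULT_D_CONTACT) -> float:
    """Cortical contacts per 10 µm of junction.

    A filament contacts the junction when its cortex-proximal endpoint lies
    within ``d_contact`` µm of the junction polyline; each filament counts
    at most once and the count is normalized to a 10 µm stretch.
    """
    if d_contact <= 0:
        raise InvalidParameterError("d_contact must be positive")
    if junction.length <= 0:
        raise DegenerateInputError("junction has zero length")
    n = sum(1 for f in filaments
            if junction.distance_to(f.vertices[-1]) <= d_contact)
    return n * 10.0 / junction.length


def nematic_orientation(image: ImageGrid,
                        roi: tuple[int, int, int, int] | None = None,
                        smoothing_sigma_px: float = 1.0,
                        energy_floor: float = 1e-8) -> OrientationResult:
    """Structure-tensor orientation and anisotropy of fibrillar texture.

    Computes per-pixel intensity gradients (centred finite differences
    after light Gaussian pre-smoothing), averages the gradient
    second-moment tensor over the ROI, and reports the fibril axis — the
    eigenvector of the *smaller* eigenvalue, perpendicular to the dominant
    gradient direction — as an orientation in [0°, 180°), with anisotropy
    ``(l1 - l2) / (l1 + l2)`` in [0, 1].  When the total gradient energy is
    below ``energy_floor`` x (dynamic range)² the orientation is undefined
    (a constant region has no texture), flagged rather than raised.

    ``roi`` is (row0, col0, row1, col1) in pixels, half-open; the whole
    image is used when omitted.
    """
    values = image.values
    if roi is not None:
        r0, c0, r1, c1 = roi
        if not (0 <= r0 < r1 <= values.shape[0] and 0 <= c0 < c1 <= values.shape[1]):
            raise InvalidParameterError("roi must lie within the image")
        if (r1 - r0) < 3 or (c1 - c0) < 3:
            raise InvalidParameterError("roi must span at least 3x3 pixels")
        values = values[max(r0 - 2, 0):r1 + 2, max(c0 - 2, 0):c1 + 2]
        inner = (slice(r0 - max(r0 - 2, 0), r0 - max(r0 - 2, 0) + (r1 - r0)),
                 slice(c0 - max(c0 - 2, 0), c0 - max(c0 - 2, 0) + (c1 - c0)))
    else:
        if values.shape[0] < 3 or values.shape[1] < 3:
            raise InvalidParameterError("image must span at least 3x3 pixels")
        inner = (slice(None), slice(None))
    smoothed = gaussian_filter(values, smoothing_sigma_px)
    gy, gx = np.gradient(smoothed)
    gx = gx[inner]
    gy = gy[inner]
    jxx = float(np.mean(gx * gx))
    jyy = float(np.mean(gy * gy))
    jxy = float(np.mean(gx * gy))
    energy = jxx + jyy
    scale = float(values.max() - values.min())
    if energy <= energy_floor * max(scale, 1e-30) ** 2 or scale == 0.0:
        return OrientationResult(float("nan"), 0.0, False)
    # gradient axis: 0.5 atan2(2Jxy, Jxx - Jyy); fibrils run perpendicular
    grad_axis = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    orientation = float(fold_orientation(grad_axis + 90.0))
    disc = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    anisotropy = float(disc / energy)
    return OrientationResult(orientation, min(anisotropy, 1.0), True)


def junction_relative_angle(result: OrientationResult,
                            junction_tangent_deg: float) -> float:
    """Acute angle between a fibril orientation and the junction tangent.

    Propagates undefined orientations as NaN.
    """
    if not result.defined:
        return float("nan")
    return float(acute_angle(result.orientation, junction_tangent_deg))
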