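"""Seeded synthetic microscopy scenes with known ground truth.

Real epithelial images behind the quantities this package measures are not
publicly deposited, so every downstream stage is validated by parameter
recovery on simulated data instead: a polygonal cell mosaic stands in for
the adherens-junction network, ridge renderings for junction-marker and
microtubule stains, punctate fields for cortical ninein, elliptical spots
for plus-end comets, and two-state (growth/pause) Markov trajectories for
live comet tracks.

Every generator is a pure function of its parameters and a seed: the same
call twice yields bit-identical output, and every rendered object carries
exactly one ground-truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import LineString, box

from .geometry import InvalidParameterError, PolyPath, fold_to_acute
from .images import ImageGrid
from .tracks import CometTrack

DEFAULT_PIXEL_SIZE = 0.1  # µm/px: the 0.2-1.2 µm² comet gate maps to 20-120 px


@dataclass
class Punctum:
    x: float
    y: float
    amplitude: float
    on_junction: bool


@dataclass
class SynthScene:
    """Bundle of one synthetic field's content and its ground truth."""

    field_size: tuple[float, float]
    pixel_size: float
    seed: int
    cell_paths: list[PolyPath] = field(default_factory=list)
    puncta: list[Punctum] = field(default_factory=list)
    filaments: list[PolyPath] = field(default_factory=list)
    truth_tracks: list[CometTrack] = field(default_factory=list)
    images: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cell mosaic
# ---------------------------------------------------------------------------

def make_cell_mosaic(n_cells: int, field: tuple[float, float], seed: int) -> list[PolyPath]:
    """Voronoi partition of the field into ``n_cells`` convex cells.

    Returns each *internal* edge (shared by two cells) once, as a junction
    PolyPath whose ``meta['cells']`` names the two adjacent cells.  The
    field border itself is not returned: one cell has no internal junctions.

    Seed points are drawn uniformly; the tessellation is clipped to the
    field by mirroring each seed across all four borders, which makes every
    original cell's region finite.
    """
    w, h = float(field[0]), float(field[1])
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if w <= 0 or h <= 0:
        raise InvalidParameterError("field dimensions must be positive")
    if n_cells == 1:
        return []
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
    mirrored = np.vstack([
        pts,
        pts * [-1, 1],                   # across x=0
        pts * [1, -1],                   # across y=0
        np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),
    ])
    vor = Voronoi(mirrored)
    frame = box(0.0, 0.0, w, h)
    edges: list[PolyPath] = []
    for (p, q), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_cells or q >= n_cells:
            continue  # only edges between two original cells are internal
        if -1 in ridge:
            continue  # unbounded ridges involve mirror cells only
        seg = LineString(vor.vertices[ridge])
        clipped = seg.intersection(frame)
        if clipped.is_empty or clipped.length < 1e-9:
            continue
        coords = np.asarray(clipped.coords)
        edges.append(PolyPath(coords, kind="junction",
                              path_id=f"edge_{min(p, q)}_{max(p, q)}",
                              meta={"cells": (int(min(p, q)), int(max(p, q)))}))
    edges.sort(key=lambda e: e.path_id)
    return edges


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _blank_raster(field: tuple[float, float], pixel_size: float) -> np.ndarray:
    w, h = field
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    return np.zeros((int(round(h / pixel_size)), int(round(w / pixel_size))))


def _add_ridges(values: np.ndarray, pixel_size: float, paths: list[PolyPath],
                sigma: float, amplitude: float) -> None:
    """Add a Gaussian-cross-section ridge for each path (in place).

    Intensity at perpendicular distance d from the path centreline is
    amplitude * exp(-d^2 / 2 sigma^2); per path the *minimum* distance over
    its segments is used so joints are not double counted.
    """
    h, w = values.shape
    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    cutoff = 6.0 * sigma  # truncation error < 2e-8 of the amplitude
    for path in paths:
        v = path.vertices
        x0 = max(v[:, 0].min() - cutoff, xs[0])
        x1 = min(v[:, 0].max() + cutoff, xs[-1])
        y0 = max(v[:, 1].min() - cutoff, ys[0])
        y1 = min(v[:, 1].max() + cutoff, ys[-1])
        ci = np.flatnonzero((xs >= x0) & (xs <= x1))
        ri = np.flatnonzero((ys >= y0) & (ys <= y1))
        if ci.size == 0 or ri.size == 0:
            continue
        X, Y = np.meshgrid(xs[ci], ys[ri])
        dmin = np.full(X.shape, np.inf)
        for (ax, ay), (bx, by) in zip(v[:-1], v[1:]):
            abx, aby = bx - ax, by - ay
            denom = abx * abx + aby * aby
            t = np.clip(((X - ax) * abx + (Y - ay) * aby) / denom, 0.0, 1.0)
            dx = X - (ax + t * abx)
            dy = Y - (ay + t * aby)
            np.minimum(dmin, np.hypot(dx, dy), out=dmin)
        values[np.ix_(ri, ci)] += amplitude * np.exp(-dmin**2 / (2.0 * sigma**2))


def _add_gaussian_spots(values: np.ndarray, pixel_size: float,
                        positions: np.ndarray, amplitudes: np.ndarray,
                        sigma: float) -> None:
    h, w = values.shape
    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    cutoff = 4.0 * sigma
    for (px, py), amp in zip(positions, amplitudes):
        ci = np.flatnonzero(np.abs(xs - px) <= cutoff)
        ri = np.flatnonzero(np.abs(ys - py) <= cutoff)
        if ci.size == 0 or ri.size == 0:
            continue
        gx = np.exp(-(xs[ci] - px) ** 2 / (2 * sigma**2))
        gy = np.exp(-(ys[ri] - py) ** 2 / (2 * sigma**2))
        values[np.ix_(ri, ci)] += amp * np.outer(gy, gx)


def render_junction_scene(paths: list[PolyPath], profile_sigma: float,
                          amplitude: float, background: float, noise_sd: float,
                          field: tuple[float, float],
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          seed: int = 0,
                          exposure_group: str | None = None) -> ImageGrid:
    """Render junction traces as Gaussian-cross-section ridges.

    Emulates a fixed-exposure junction-marker stain: constant background,
    ridge amplitude per path, additive Gaussian read noise (sd ``noise_sd``)
    and a floor at zero intensity.
    """
    if profile_sigma <= 0:
        raise InvalidParameterError("profile_sigma must be positive")
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    values = _blank_raster(field, pixel_size) + float(background)
    if amplitude > 0:
        _add_ridges(values, pixel_size, paths, profile_sigma, amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ImageGrid(np.clip(values, 0.0, None), pixel_size, exposure_group)


# ---------------------------------------------------------------------------
# cortical puncta
# ---------------------------------------------------------------------------

def place_cortical_puncta(paths: list[PolyPath], field: tuple[float, float],
                          base_density: float, junction_density: float,
                          band_width: float, enrichment_factor: float,
                          amplitude: float = 100.0,
                          punctum_sigma: float = 0.15,
                          background: float = 0.0, noise_sd: float = 0.0,
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          seed: int = 0) -> tuple[list[Punctum], ImageGrid]:
    """Scatter cortically enriched puncta over a junction mosaic.

    Background puncta are homogeneous Poisson over the field at
    ``base_density`` /µm².  Junctional puncta are Poisson along each path
    with linear density ``junction_density * enrichment_factor`` /µm, then
    displaced along the local normal by Normal(0, band_width/2) so ~95% of
    the enriched signal lies within ±band_width of the junction line.  The
    enrichment factor is the dial the junction-profile analysis must
    recover: halving it halves the expected junctional peak.
    """
    if base_density < 0 or junction_density < 0 or enrichment_factor < 0:
        raise InvalidParameterError("densities and enrichment must be >= 0")
    if band_width <= 0:
        raise InvalidParameterError("band_width must be positive")
    rng = np.random.default_rng(seed)
    w, h = field
    puncta: list[Punctum] = []

    n_bg = rng.poisson(base_density * w * h)
    for x, y in rng.uniform([0, 0], [w, h], size=(n_bg, 2)):
        puncta.append(Punctum(float(x), float(y), amplitude, False))

    lam = junction_density * enrichment_factor
    for path in paths:
        n_j = rng.poisson(lam * path.length) if lam > 0 else 0
        if n_j == 0:
            continue
        ss = rng.uniform(0.0, path.length, size=n_j)
        offs = rng.normal(0.0, band_width / 2.0, size=n_j)
        for s, off in zip(ss, offs):
            p = path.point_at(s) + off * path.normal_at(s)
            if 0 <= p[0] <= w and 0 <= p[1] <= h:
                puncta.append(Punctum(float(p[0]), float(p[1]), amplitude, True))

    values = _blank_raster(field, pixel_size) + float(background)
    if puncta:
        pos = np.array([[p.x, p.y] for p in puncta])
        amps = np.array([p.amplitude for p in puncta])
        _add_gaussian_spots(values, pixel_size, pos, amps, punctum_sigma)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return puncta, ImageGrid(np.clip(values, 0.0, None), pixel_size)


# ---------------------------------------------------------------------------
# filament fields
# ---------------------------------------------------------------------------

def draw_filament_set(paths: list[PolyPath], field: tuple[float, float],
                      n_filaments: int, target_angle: float, kappa: float,
                      length_range: tuple[float, float] = (2.0, 6.0),
                      standoff: float = 0.05,
                      render: bool = True,
                      filament_sigma: float = 0.12, amplitude: float = 100.0,
                      background: float = 0.0, noise_sd: float = 0.0,
                      pixel_size: float = DEFAULT_PIXEL_SIZE,
                      seed: int = 0) -> tuple[list[PolyPath], ImageGrid | None]:
    """Draw straight filaments whose cortex-proximal ends abut the junctions.

    Each filament's approach angle to the local junction tangent is drawn
    from a von Mises distribution centred at ``target_angle`` with
    concentration ``kappa``, folded onto [0°, 90°]; kappa=0 is uniform on
    [0°, 90°] and large kappa concentrates all mass at the target.  The
    ground-truth angle is stored in each filament's ``meta['angle_truth']``.
    Filament vertices are ordered distal -> proximal (last vertex at the
    cortex).
    """
    if not 0 <= target_angle <= 90:
        raise InvalidParameterError("target_angle must lie in [0, 90] degrees")
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if n_filaments < 0:
        raise InvalidParameterError("n_filaments must be >= 0")
    if not paths:
        raise InvalidParameterError("need at least one junction path")
    kappa = min(kappa, 1e6)
    rng = np.random.default_rng(seed)
    w, h = field
    lengths_cum = np.cumsum([p.length for p in paths])
    filaments: list[PolyPath] = []
    for i in range(n_filaments):
        # pick an anchor point uniformly over total junction length
        u = rng.uniform(0.0, lengths_cum[-1])
        pi = int(np.searchsorted(lengths_cum, u))
        path = paths[pi]
        s = u - (lengths_cum[pi - 1] if pi > 0 else 0.0)
        anchor = path.point_at(s)
        tangent = path.tangent_at(s)
        # approach angle: von Mises offset mapped onto a 180° window, folded
        # delta spans (-pi, pi]; degrees(delta)/2 spans a 180° window which the
        # acute fold maps onto [0°, 90°] (uniform there when kappa = 0)
        delta = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
        angle = float(fold_to_acute(target_angle + np.degrees(delta) / 2.0))
        sign = rng.choice([-1.0, 1.0])
        side = rng.choice([-1.0, 1.0])
        a = np.radians(sign * angle)
        ca, sa = np.cos(a), np.sin(a)
        direction = np.array([tangent[0] * ca - tangent[1] * sa,
                              tangent[0] * sa + tangent[1] * ca])
        normal = np.array([-tangent[1], tangent[0]]) * side
        # make sure the filament leaves the junction towards `side`
        if np.dot(direction, normal) < 0:
            direction = -direction
        length = rng.uniform(*length_range)
        proximal = anchor + standoff * normal
        distal = proximal + length * direction
        filaments.append(PolyPath(np.vstack([distal, proximal]), kind="filament",
                                  path_id=f"fil_{i}",
                                  meta={"angle_truth": angle,
                                        "junction_id": path.path_id,
                                        "anchor_s": float(s)}))
    image = None
    if render:
        values = _blank_raster(field, pixel_size) + float(background)
        inside = [f for f in filaments]
        _add_ridges(values, pixel_size, inside, filament_sigma, amplitude)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        image = ImageGrid(np.clip(values, 0.0, None), pixel_size)
    return filaments, image


# ---------------------------------------------------------------------------
# comet fields (fixed images)
# ---------------------------------------------------------------------------

@dataclass
class TrueComet:
    x: float
    y: float
    area: float           # requested analytic area, µm²
    amplitude: float
    frame: int = 0


def simulate_comet_frames(field: tuple[float, float], density: float,
                          area_range: tuple[float, float] = (0.3, 1.0),
                          amplitude: float = 100.0, background: float = 10.0,
                          noise_sd: float = 0.0,
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          n_frames: int = 1,
                          min_separation: float = 0.0,
                          seed: int = 0) -> tuple[list[list[TrueComet]], ImageGrid | list[ImageGrid]]:
    """Scatter elliptical comet spots over a background field.

    The comet count per frame is Poisson(density x field_area / 100 µm²) —
    density is expressed per 100 µm² to match per-box counting.  Each comet
    is a uniform-intensity ellipse whose analytic area is uniform in
    ``area_range`` and whose axis ratio and orientation are random.
    Centres are kept one maximal spot radius inside the field so every
    ground-truth comet is fully rendered; ``min_separation`` > 0 thins the
    positions to a hard-core pattern (the count stays Poisson) for
    constructing scenes whose spots are individually resolvable.
    """
    w, h = field
    if density < 0:
        raise InvalidParameterError("density must be >= 0")
    a0, a1 = area_range
    if not (0 < a0 <= a1 < w * h):
        raise InvalidParameterError("area_range must lie within (0, field area)")
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames: list[list[TrueComet]] = []
    images: list[ImageGrid] = []
    lam = density * (w * h) / 100.0
    for fr in range(n_frames):
        n = rng.poisson(lam)
        comets = []
        values = _blank_raster(field, pixel_size) + float(background)
        ys_pix = (np.arange(values.shape[0]) + 0.5) * pixel_size
        xs_pix = (np.arange(values.shape[1]) + 0.5) * pixel_size
        margin = min(np.sqrt(a1 * 2.2 / np.pi) + pixel_size, 0.25 * min(w, h))
        placed: list[tuple[float, float]] = []
        for _ in range(n):
            for _attempt in range(200):
                cx, cy = rng.uniform([margin, margin], [w - margin, h - margin])
                if min_separation <= 0 or all(
                        np.hypot(cx - px_, cy - py_) >= min_separation
                        for px_, py_ in placed):
                    break
            placed.append((cx, cy))
            area = rng.uniform(a0, a1)
            ratio = rng.uniform(1.3, 2.2)
            phi = rng.uniform(0, np.pi)
            semi_a = np.sqrt(area * ratio / np.pi)
            semi_b = np.sqrt(area / (ratio * np.pi))
            comets.append(TrueComet(float(cx), float(cy), float(area), amplitude, fr))
            ci = np.flatnonzero(np.abs(xs_pix - cx) <= semi_a + pixel_size)
            ri = np.flatnonzero(np.abs(ys_pix - cy) <= semi_a + pixel_size)
            if ci.size == 0 or ri.size == 0:
                continue
            X, Y = np.meshgrid(xs_pix[ci] - cx, ys_pix[ri] - cy)
            u = X * np.cos(phi) + Y * np.sin(phi)
            v = -X * np.sin(phi) + Y * np.cos(phi)
            mask = (u / semi_a) ** 2 + (v / semi_b) ** 2 <= 1.0
            sub = values[np.ix_(ri, ci)]
            sub[mask] = background + amplitude
            values[np.ix_(ri, ci)] = sub
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        frames.append(comets)
        images.append(ImageGrid(np.clip(values, 0.0, None), pixel_size))
    if n_frames == 1:
        return frames, images[0]
    return frames, images


# ---------------------------------------------------------------------------
# dynamic comet trajectories
# ---------------------------------------------------------------------------

def simulate_dynamic_tracks(n_tracks: int, v_growth: float, v_sd: float,
                            p_gp: float, p_pg: float, frame_interval: float = 2.0,
                            n_frames: int = 40,
                            field: tuple[float, float] = (50.0, 50.0),
                            pause_jitter: float = 0.01,
                            cell_id: str = "cell0", treatment: str = "control",
                            seed: int = 0) -> list[CometTrack]:
    """Simulate two-state (growth/pause) comet trajectories.

    Each track is a Markov chain over {growth, pause} with per-frame
    transition probabilities ``p_gp`` (growth->pause) and ``p_pg``
    (pause->growth), started in growth.  In growth the comet advances along
    a persistent random direction by Normal(v_growth, v_sd) µm/min x
    frame_interval; in pause only isotropic positional jitter of sd
    ``pause_jitter`` µm remains (the default 0.01 µm models localization
    error; at the default 2 s interval it keeps apparent pause speeds well
    below typical growth speeds).  Per-frame state labels are stored in
    ``track.meta['states']`` as the ground truth for event classification.
    The long-run pause fraction is p_gp / (p_gp + p_pg).
    """
    if not (0 <= p_gp <= 1 and 0 <= p_pg <= 1):
        raise InvalidParameterError("transition probabilities must lie in [0, 1]")
    if v_growth <= 0:
        raise InvalidParameterError("v_growth must be positive")
    if frame_interval <= 0:
        raise InvalidParameterError("frame_interval must be positive")
    if n_frames < 2:
        raise InvalidParameterError("a track needs at least 2 frames")
    rng = np.random.default_rng(seed)
    dt_min = frame_interval / 60.0
    tracks: list[CometTrack] = []
    w, h = field
    for t in range(n_tracks):
        pos = rng.uniform([0.2 * w, 0.2 * h], [0.8 * w, 0.8 * h])
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        state = "growth"
        states = [state]
        positions = [pos.copy()]
        for _ in range(1, n_frames):
            if state == "growth":
                speed = max(rng.normal(v_growth, v_sd), 0.0)
                step = speed * dt_min * direction
            else:
                step = rng.normal(0.0, pause_jitter, size=2)
            pos = pos + step
            positions.append(pos.copy())
            # transition applies between this frame and the next
            if state == "growth":
                if rng.random() < p_gp:
                    state = "pause"
            else:
                if rng.random() < p_pg:
                    state = "growth"
            states.append(state)
        tracks.append(CometTrack(
            track_id=f"sim_{t}",
            frames=np.arange(n_frames),
            positions=np.asarray(positions),
            frame_interval=frame_interval,
            cell_id=cell_id,
            treatment=treatment,
            meta={"states": states},
        ))
    return tracks
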