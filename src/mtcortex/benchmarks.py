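"""Parameter-recovery benchmarks run against the synthetic generators.

Each function builds a seeded synthetic data set with known ground truth,
runs the corresponding measurement stage, and reports how well the truth
is recovered.  These are the package's own end-to-end validation
experiments; the test suite asserts tolerances on their outputs and the
acceptance script reports them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import profiles, synthetic, targeting, tracks
from .detection import detect_comets
from .images import ImageGrid
from .stats import choose_and_run_test

logger = logging.getLogger(__name__)


def profile_ridge_recovery(sigma: float = 0.3, amplitude: float = 100.0,
                           n_positions: int = 7) -> dict:
    """Extract default profiles across a noise-free Gaussian ridge.

    Returns the profile geometry and the relative error of the centre
    sample against the known ridge amplitude.
    """
    path = synthetic.PolyPath([[1.0, 10.0], [19.0, 10.0]])
    image = synthetic.render_junction_scene([path], sigma, amplitude, 0.0,
                                            0.0, (20.0, 20.0), 0.1, 0)
    out = profiles.extract_profiles(image, path, n_positions, background=0.0)
    centre = np.array([p.samples[(len(p.samples) - 1) // 2] for p in out])
    return {
        "n_samples": len(out[0].samples),
        "spacing_um": out[0].spacing,
        "span_um": out[0].span,
        "centre_error_pct": float(100.0 * np.max(np.abs(centre - amplitude))
                                  / amplitude),
        "peak_at_centre": bool(all(int(np.argmax(p.samples)) == 10 for p in out)),
    }


def _profile_arm(mosaic, field, enrichment: float, seed: int,
                 n_positions: int = 4) -> np.ndarray:
    _, image = synthetic.place_cortical_puncta(
        mosaic, field, base_density=0.05, junction_density=6.0,
        band_width=0.4, enrichment_factor=enrichment, noise_sd=1.0, seed=seed)
    collected = []
    for junction in mosaic:
        if junction.length >= 2.0:
            collected.extend(profiles.extract_profiles(image, junction,
                                                       n_positions))
    peaks, _, _ = profiles.peak_intensities(collected)
    return peaks


def enrichment_recovery(seed: int, ratios=(1.0, 0.5, 0.25),
                        n_cells: int = 25,
                        field=(50.0, 50.0)) -> dict[float, float]:
    """Measured percent reduction for each junctional-enrichment ratio.

    Control and treated arms share the cell mosaic (the perturbation
    changes enrichment, not geometry) and use ~200 profiles per arm.
    """
    mosaic = synthetic.make_cell_mosaic(n_cells, field, seed)
    control = _profile_arm(mosaic, field, 1.0, seed * 7 + 1)
    out = {}
    for i, ratio in enumerate(ratios):
        treated = _profile_arm(mosaic, field, ratio, seed * 7 + 11 + i)
        change = profiles.relative_peak_change(control, treated)
        out[ratio] = change["percent_reduction"]
    return out


def perpendicular_uniform(seed: int, n_filaments: int = 1000) -> dict:
    """Perpendicular fraction of a uniform-angle filament field (truth 50%)."""
    mosaic = synthetic.make_cell_mosaic(25, (50.0, 50.0), seed)
    fils, _ = synthetic.draw_filament_set(mosaic, (50.0, 50.0), n_filaments,
                                          45.0, 0.0, render=False, seed=seed + 1)
    by_id = {j.path_id: j for j in mosaic}
    angles = np.array([targeting.approach_angle(f, by_id[f.meta["junction_id"]])
                       for f in fils])
    pct = 100.0 * np.mean((angles >= 45.0) & (angles <= 90.0))
    return {"pct_perpendicular": float(pct), "n": n_filaments,
            "se_pct": float(100.0 * np.sqrt(0.25 / n_filaments))}


def stripe_orientation_recovery(thetas=(10.0, 37.0, 80.0), n: int = 200) -> dict:
    """Structure-tensor recovery of closed-form stripe orientations."""
    errors, anisotropies = [], []
    xs = (np.arange(n) + 0.5) * 0.1
    X, Y = np.meshgrid(xs, xs)
    for theta in thetas:
        t = np.radians(theta)
        vals = 50.0 + 40.0 * np.sin(2 * np.pi * (-X * np.sin(t) + Y * np.cos(t)))
        res = targeting.nematic_orientation(ImageGrid(np.clip(vals, 0, None), 0.1))
        err = abs(res.orientation - theta)
        errors.append(min(err, 180.0 - err))
        anisotropies.append(res.anisotropy)
    rng = np.random.default_rng(12)
    noise = ImageGrid(np.abs(rng.normal(100, 10, (100, 100))), 0.1)
    noise_res = targeting.nematic_orientation(noise)
    return {"max_error_deg": float(max(errors)),
            "min_anisotropy": float(min(anisotropies)),
            "noise_anisotropy": float(noise_res.anisotropy)}


def detection_benchmark(seed: int, n_scenes: int = 3,
                        density: float = 5.0, snr: float = 5.0) -> dict:
    """Precision/recall of comet detection on constructed separated scenes."""
    amplitude = 100.0
    precisions, recalls = [], []
    for k in range(n_scenes):
        truth, image = synthetic.simulate_comet_frames(
            (30.0, 30.0), density, amplitude=amplitude,
            noise_sd=amplitude / snr, min_separation=2.0, seed=seed + k)
        detections = detect_comets(image)
        used: set[int] = set()
        tp = 0
        for d in detections:
            best, bd = None, np.inf
            for i, c in enumerate(truth[0]):
                if i in used:
                    continue
                dd = np.hypot(d.x - c.x, d.y - c.y)
                if dd < bd:
                    bd, best = dd, i
            if bd <= 0.3:
                tp += 1
                used.add(best)
        precisions.append(tp / len(detections) if detections else 0.0)
        recalls.append(tp / len(truth[0]) if truth[0] else 1.0)
    return {"precision": float(np.min(precisions)),
            "recall": float(np.min(recalls)), "n_scenes": n_scenes}


def dynamics_recovery(seed: int, n_tracks: int = 500, v_growth: float = 12.0,
                      p_gp: float = 0.1, p_pg: float = 0.3) -> dict:
    """Recovery of growth speed and pause occupancy from simulated tracks."""
    sim = synthetic.simulate_dynamic_tracks(n_tracks, v_growth, 2.0, p_gp,
                                            p_pg, seed=seed)
    events = [tracks.segment_events(t) for t in sim]
    _, per_treatment = tracks.dynamics_summary(sim, events)
    v = float(per_treatment.mean_growth_speed_um_min.iloc[0])
    pause_time = 1.0 - float(per_treatment.pct_time_growing.iloc[0]) / 100.0
    return {
        "recovered_speed_um_min": v,
        "speed_error_pct": 100.0 * abs(v - v_growth) / v_growth,
        "pause_time_fraction": pause_time,
        "stationary_expectation": p_gp / (p_gp + p_pg),
        "n_tracks": n_tracks,
    }


def type_i_error(seed: int, n_sim: int = 2000, n: int = 20,
                 alpha: float = 0.05) -> dict:
    """Empirical size of the routed two-group procedure on null normal data."""
    rejections = 0
    for i in range(n_sim):
        rng = np.random.default_rng(seed + i)
        res = choose_and_run_test({"A": rng.normal(0, 1, n),
                                   "B": rng.normal(0, 1, n)})
        rejections += res.p_value < alpha
    return {"type_i_error": rejections / n_sim, "n_sim": n_sim}
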