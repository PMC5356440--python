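"""Config-driven orchestration: synthetic scenes -> measurements -> statistics.

A single declarative config (YAML or dict, validated by a pydantic schema
before any computation) selects stages and fixes every threshold and seed.
All thresholds are echoed verbatim into the run-metadata file, so any
number in any output CSV can be reproduced from the metadata plus the
inputs; one detection parameter set applies to every image of a comparison
group by construction.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__, io, profiles, stats, synthetic, targeting, tracks
from .detection import detect_comets, comets_per_box
from .targeting import CorticalBox

logger = logging.getLogger(__name__)

Stage = Literal["profiles", "targeting", "comets", "tracks", "stats"]


class SceneConfig(BaseModel):
    field: tuple[float, float] = (30.0, 30.0)
    pixel_size: float = Field(0.1, gt=0)
    n_cells: int = Field(8, ge=1)


class ProfilesConfig(BaseModel):
    n_positions: int = Field(10, ge=1)
    span: float = Field(2.0, gt=0)
    n_samples: int = Field(21, ge=2)
    junction_density: float = Field(3.0, ge=0)
    base_density: float = Field(0.05, ge=0)
    band_width: float = Field(0.4, gt=0)
    enrichment_control: float = Field(1.0, ge=0)
    enrichment_treated: float = Field(0.5, ge=0)
    noise_sd: float = Field(1.0, ge=0)


class TargetingConfig(BaseModel):
    n_filaments: int = Field(200, ge=0)
    target_angle: float = Field(70.0, ge=0, le=90)
    kappa: float = Field(4.0, ge=0)
    d_contact: float = Field(0.25, gt=0)
    box_side: float = Field(10.0, gt=0)


class CometsConfig(BaseModel):
    density: float = Field(5.0, ge=0)
    min_separation: float = Field(1.5, ge=0)
    area_min: float = Field(0.2, gt=0)
    area_max: float = Field(1.2, gt=0)
    noise_sd: float = Field(2.0, ge=0)
    background_method: str = "median"
    threshold_method: str = "otsu"

    @model_validator(mode="after")
    def _check_gate(self):
        if self.area_min >= self.area_max:
            raise ValueError("area_min must be smaller than area_max")
        return self


class TracksConfig(BaseModel):
    n_tracks: int = Field(100, ge=1)
    v_growth: float = Field(12.0, gt=0)
    v_sd: float = Field(2.0, ge=0)
    v_growth_treated: float = Field(6.0, gt=0)
    p_gp: float = Field(0.1, ge=0, le=1)
    p_pg: float = Field(0.3, ge=0, le=1)
    frame_interval: float = Field(2.0, gt=0)
    n_frames: int = Field(40, ge=2)
    pause_speed_max: float = Field(1.5, gt=0)
    min_pause_frames: int = Field(2, ge=1)
    theta_max: float = Field(30.0, gt=0)


class PipelineConfig(BaseModel):
    seed: int = 0
    stages: list[Stage] = ["profiles", "stats"]
    scene: SceneConfig = SceneConfig()
    profiles: ProfilesConfig = ProfilesConfig()
    targeting: TargetingConfig = TargetingConfig()
    comets: CometsConfig = CometsConfig()
    tracks: TracksConfig = TracksConfig()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.model_validate(yaml.safe_load(fh) or {})


def _profile_arm(cfg: PipelineConfig, enrichment: float, seed: int,
                 group: str) -> tuple[np.ndarray, list]:
    mosaic = synthetic.make_cell_mosaic(cfg.scene.n_cells, cfg.scene.field, seed)
    _, image = synthetic.place_cortical_puncta(
        mosaic, cfg.scene.field, base_density=cfg.profiles.base_density,
        junction_density=cfg.profiles.junction_density,
        band_width=cfg.profiles.band_width, enrichment_factor=enrichment,
        noise_sd=cfg.profiles.noise_sd, pixel_size=cfg.scene.pixel_size,
        seed=seed + 1)
    all_profiles = []
    for junction in mosaic:
        if junction.length < cfg.profiles.span:
            continue
        all_profiles.extend(profiles.extract_profiles(
            image, junction, cfg.profiles.n_positions,
            span=cfg.profiles.span, n_samples=cfg.profiles.n_samples))
    peaks, _, _ = profiles.peak_intensities(all_profiles)
    return peaks, all_profiles


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> Path:
    """Execute the configured stages and write all outputs to ``out_dir``.

    Returns the run directory.  Identical config + seed yields identical
    CSV contents.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mtcortex")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seed = config.seed
    results: dict = {}
    try:
        if "profiles" in config.stages:
            logger.info("stage profiles: enrichment %.3g vs %.3g",
                        config.profiles.enrichment_control,
                        config.profiles.enrichment_treated)
            peaks_c, profs_c = _profile_arm(
                config, config.profiles.enrichment_control, seed, "control")
            peaks_t, profs_t = _profile_arm(
                config, config.profiles.enrichment_treated, seed + 1000, "treated")
            io.write_profiles(out / "profiles_control.csv", profs_c, "control")
            io.write_profiles(out / "profiles_treated.csv", profs_t, "treated")
            io.write_peaks(out / "peaks_control.csv", peaks_c, "control")
            io.write_peaks(out / "peaks_treated.csv", peaks_t, "treated")
            change = profiles.relative_peak_change(peaks_c, peaks_t)
            results["profiles"] = {
                "ratio": change["ratio"],
                "percent_reduction": change["percent_reduction"],
                "n_control": len(peaks_c), "n_treated": len(peaks_t)}

        if "targeting" in config.stages:
            mosaic = synthetic.make_cell_mosaic(config.scene.n_cells,
                                                config.scene.field, seed)
            junction = max(mosaic, key=lambda p: p.length)
            filaments, image = synthetic.draw_filament_set(
                mosaic, config.scene.field, config.targeting.n_filaments,
                config.targeting.target_angle, config.targeting.kappa,
                pixel_size=config.scene.pixel_size, seed=seed + 2)
            boxcfg = targeting.box_on_junction(junction, config.targeting.box_side)
            score = targeting.perpendicular_fraction(filaments, junction, boxcfg)
            contacts = targeting.contacts_per_10um(
                filaments, junction, config.targeting.d_contact)
            orient = targeting.nematic_orientation(image)
            io.write_polypaths(out / "filaments.csv", filaments)
            rows = [{"box_id": "box0", "n_filaments": score.n_in_box,
                     "pct_perpendicular": score.percentage}]
            pd.DataFrame(rows).to_csv(out / "perpendicular_boxes.csv", index=False)
            results["targeting"] = {
                "pct_perpendicular": score.percentage,
                "contacts_per_10um": contacts,
                "orientation_deg": orient.orientation,
                "anisotropy": orient.anisotropy}

        if "comets" in config.stages:
            truth, image = synthetic.simulate_comet_frames(
                config.scene.field, config.comets.density,
                noise_sd=config.comets.noise_sd,
                min_separation=config.comets.min_separation,
                pixel_size=config.scene.pixel_size, seed=seed + 3)
            detections = detect_comets(
                image, config.comets.background_method,
                config.comets.threshold_method,
                config.comets.area_min, config.comets.area_max,
                image_id="synthetic0")
            io.write_detections(out / "detections.csv", detections)
            side = 10.0
            w, h = config.scene.field
            boxes = [CorticalBox(((i + 0.5) * side, (j + 0.5) * side), side,
                                 box_id=f"box_{i}_{j}")
                     for i in range(int(w // side)) for j in range(int(h // side))]
            counts = comets_per_box(detections, boxes)
            pd.DataFrame({"box_id": [b.box_id for b in boxes],
                          "n_comets": counts}).to_csv(out / "comet_counts.csv",
                                                      index=False)
            results["comets"] = {"n_true": len(truth[0]),
                                 "n_detected": len(detections)}

        if "tracks" in config.stages:
            tcfg = config.tracks
            sim = []
            for ci, (treat, v) in enumerate([("control", tcfg.v_growth),
                                             ("treated", tcfg.v_growth_treated)]):
                sim.extend(synthetic.simulate_dynamic_tracks(
                    tcfg.n_tracks, v, tcfg.v_sd, tcfg.p_gp, tcfg.p_pg,
                    tcfg.frame_interval, tcfg.n_frames,
                    cell_id=f"cell_{treat}", treatment=treat, seed=seed + 10 + ci))
            events = [tracks.segment_events(t, tcfg.pause_speed_max,
                                            tcfg.min_pause_frames) for t in sim]
            io.write_tracks(out / "tracks.csv", sim)
            ev_table = tracks.events_table(sim, events)
            ev_table.to_csv(out / "events.csv", index=False)
            per_cell, per_treatment = tracks.dynamics_summary(sim, events)
            per_cell.to_csv(out / "dynamics_per_cell.csv", index=False)
            per_treatment.to_csv(out / "dynamics_per_treatment.csv", index=False)
            growth = ev_table[ev_table.state == "growth"]
            sg = tracks.speed_groups(growth.rename(
                columns={"mean_speed_um_min": "speed"})[
                ["cell_id", "treatment", "speed"]])
            sg_rows = [{"treatment": t, "label": lab, "percentage": pct,
                        "vmax": tab.vmax}
                       for t, tab in sg.items()
                       for lab, pct in zip(tab.labels, tab.percentages)]
            pd.DataFrame(sg_rows).to_csv(out / "speed_groups.csv", index=False)
            results["tracks"] = {
                t: {"mean_growth_speed_um_min": float(
                    per_treatment.set_index("treatment")
                    .loc[t, "mean_growth_speed_um_min"])}
                for t in per_treatment.treatment}

        if "stats" in config.stages:
            if "profiles" not in config.stages:
                raise ValueError("stats stage needs the profiles stage outputs")
            groups = {"control": np.asarray(peaks_c), "treated": np.asarray(peaks_t)}
            comparison = stats.choose_and_run_test(groups)
            pd.DataFrame([{
                "groups": "control vs treated", "test": comparison.test,
                "statistic": comparison.statistic, "p_value": comparison.p_value,
            }]).to_csv(out / "comparison.csv", index=False)
            for line in comparison.trace:
                logger.info("decision: %s", line)
            results["stats"] = {"test": comparison.test,
                                "p_value": comparison.p_value}

        metadata = {
            "mtcortex_version": __version__,
            "python": platform.python_version(),
            "config": json.loads(config.model_dump_json()),
            "results": results,
        }
        (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
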