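"""End-to-end orchestration: simulate -> detect -> track -> classify.

Cells are detected and tracked on the constitutive fluorescence (GFP)
channel — which, unlike luminescence, does not vanish when the reporter is
suppressed — and the luminescence intensity is measured at the matched GFP
centroids in both sessions.  This mirrors the experimental practice of
locating reporter-dark cells through complementary imaging, and keeps the
tracked population unbiased with respect to response class.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .config import DetectParams, OpticsConfig, PopulationConfig
from .presets import Preset, load_preset
from .quantify import (
    ApertureError,
    Detection,
    LOD,
    aperture_area,
    compute_lod,
    detect_cells,
    detections_to_frame,
    estimate_background,
    measure_intensity,
    read_detections_csv,
)
from .response import (
    CellTrajectory,
    ResponseSummary,
    classify_cell,
    summarize_responses,
    trajectories_to_frame,
)
from .simgen import (
    CellTruth,
    render_field,
    sample_population,
    write_tiff,
    write_truth_csv,
)
from .trackcells import FateCounts, TrackRecord, match_cells, tally_fates, tracks_to_frame

__all__ = [
    "PipelineStageError",
    "ConditionResult",
    "simulate_condition",
    "analyze_images",
    "run_condition",
    "run_tracking_condition",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


@dataclass
class ConditionResult:
    preset: Preset
    seed: int
    cells: List[CellTruth]
    dets_t0: List[Detection]
    dets_t1: List[Detection]
    records: List[TrackRecord]
    counts: FateCounts
    lod: Optional[LOD]
    trajectories: List[CellTrajectory]
    summary: Optional[ResponseSummary]


def simulate_condition(
    preset: Preset,
    seed: int,
    channels: Sequence[str] = ("luminescence", "fluorescence"),
) -> tuple[List[CellTruth], Dict[str, np.ndarray]]:
    """Sample the preset's population and render all requested images.

    Returns the ground truth and a dict keyed ``{channel}_{timepoint}``.
    """
    pop = dataclasses.replace(preset.population, seed=seed)
    cells = sample_population(pop)
    images = {}
    for channel in channels:
        for timepoint in ("t0", "t1"):
            images[f"{channel}_{timepoint}"] = render_field(
                cells,
                channel,
                timepoint,
                preset.optics,
                seed=seed,
                field_size=pop.field_size,
            )
    return cells, images


def analyze_images(
    gfp_t0: np.ndarray,
    gfp_t1: np.ndarray,
    lum_t0: Optional[np.ndarray],
    lum_t1: Optional[np.ndarray],
    optics: OpticsConfig,
    params: Optional[DetectParams] = None,
    match_radius: float = 15.0,
    lod_k: float = 3.0,
    condition: str = "",
):
    """Detect on GFP, track, then measure and classify luminescence.

    With ``lum_t0``/``lum_t1`` set to None only detection and tracking run
    (the Matrigel mobility experiments need nothing else).
    """
    params = params or DetectParams.for_optics(optics)
    dets0 = detect_cells(gfp_t0, params, channel="fluorescence", timepoint="t0")
    dets1 = detect_cells(gfp_t1, params, channel="fluorescence", timepoint="t1")
    records = match_cells(dets0, dets1, match_radius)
    counts = tally_fates(records, len(dets0), len(dets1))

    if lum_t0 is None or lum_t1 is None:
        return dets0, dets1, records, counts, None, [], None

    lum_t0 = np.asarray(lum_t0, dtype=np.float64)
    lum_t1 = np.asarray(lum_t1, dtype=np.float64)
    bg_mean, bg_sd = estimate_background(lum_t1)
    lod = compute_lod(bg_mean, bg_sd, lod_k, aperture_area(params.aperture_radius))
    by0 = {d.det_id: d for d in dets0}
    by1 = {d.det_id: d for d in dets1}
    trajectories: List[CellTrajectory] = []
    for r in records:
        if r.det_t1 is None:
            continue
        try:
            i0 = measure_intensity(lum_t0, by0[r.det_t0].centroid, params)
            i1 = measure_intensity(lum_t1, by1[r.det_t1].centroid, params)
        except ApertureError:
            continue  # edge cells: excluded, independent of response class
        trajectories.append(classify_cell(i0, i1, lod, r.det_t0, r.det_t1))
    summary = summarize_responses(trajectories, condition)
    return dets0, dets1, records, counts, lod, trajectories, summary


def _load(preset_name: str, seed: int, n_cells, population_overrides) -> Preset:
    preset = load_preset(preset_name, seed=seed, n_cells=n_cells)
    if population_overrides:
        from .presets import override_population

        preset = dataclasses.replace(
            preset,
            population=override_population(preset.population, population_overrides),
        )
    return preset


def run_condition(
    preset_name: str,
    seed: int,
    n_cells: Optional[int] = None,
    lod_k: float = 3.0,
    population_overrides: Optional[dict] = None,
) -> ConditionResult:
    """Full in-memory pipeline for one named condition."""
    preset = _load(preset_name, seed, n_cells, population_overrides)
    cells, images = simulate_condition(preset, seed)
    dets0, dets1, records, counts, lod, traj, summary = analyze_images(
        images["fluorescence_t0"],
        images["fluorescence_t1"],
        images["luminescence_t0"],
        images["luminescence_t1"],
        preset.optics,
        match_radius=preset.population.mobility.match_radius,
        lod_k=lod_k,
        condition=preset.label,
    )
    return ConditionResult(
        preset=preset,
        seed=seed,
        cells=cells,
        dets_t0=dets0,
        dets_t1=dets1,
        records=records,
        counts=counts,
        lod=lod,
        trajectories=traj,
        summary=summary,
    )


def run_tracking_condition(
    preset_name: str,
    seed: int,
    n_cells: Optional[int] = None,
    population_overrides: Optional[dict] = None,
) -> ConditionResult:
    """Detection + tracking only (GFP channel), for the mobility contrasts."""
    preset = _load(preset_name, seed, n_cells, population_overrides)
    cells, images = simulate_condition(preset, seed, channels=("fluorescence",))
    dets0, dets1, records, counts, _, _, _ = analyze_images(
        images["fluorescence_t0"],
        images["fluorescence_t1"],
        None,
        None,
        preset.optics,
        match_radius=preset.population.mobility.match_radius,
    )
    return ConditionResult(
        preset=preset,
        seed=seed,
        cells=cells,
        dets_t0=dets0,
        dets_t1=dets1,
        records=records,
        counts=counts,
        lod=None,
        trajectories=[],
        summary=None,
    )


# ---------------------------------------------------------------------------
# file-based pipeline (CLI `run`)
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir) -> dict:
    """File-based simulate->detect->track->classify->summarize pipeline.

    ``config`` needs ``preset`` and ``seed``; optional ``n_cells``,
    ``match_radius`` and ``lod_k``.  Every stage writes CSV/TIFF outputs to
    ``out_dir`` and the returned manifest (also written as
    ``manifest.json``) records the config hash, seed, package version and
    per-stage output row counts.  Re-running with the same config and seed
    reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "preset" not in config or "seed" not in config:
        raise PipelineStageError("config", "config requires 'preset' and 'seed'")
    seed = int(config["seed"])
    lod_k = float(config.get("lod_k", 3.0))

    stages: List[dict] = []

    def record(stage: str, path: Path, rows: Optional[int]) -> None:
        stages.append({"stage": stage, "output": path.name, "rows": rows})

    # --- simulate -----------------------------------------------------
    try:
        preset = load_preset(
            config["preset"], seed=seed, n_cells=config.get("n_cells")
        )
        if config.get("population"):
            from .presets import override_population

            preset = dataclasses.replace(
                preset,
                population=override_population(
                    preset.population, config["population"]
                ),
            )
        cells, images = simulate_condition(preset, seed)
        for key, img in images.items():
            write_tiff(img, out / f"well01_{key}.tif")
        truth_path = out / "truth.csv"
        write_truth_csv(cells, truth_path)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError("simulate", str(exc)) from exc
    record("simulate", truth_path, len(cells))

    # --- detect -------------------------------------------------------
    try:
        params = DetectParams.for_optics(preset.optics)
        dets = {}
        for tp in ("t0", "t1"):
            key = f"fluorescence_{tp}"
            if key not in images:
                raise FileNotFoundError(f"missing image {key}")
            dets[tp] = detect_cells(
                images[key], params, channel="fluorescence", timepoint=tp
            )
            p = out / f"detections_{tp}.csv"
            detections_to_frame(dets[tp]).to_csv(p, index=False)
            record("detect", p, len(dets[tp]))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("detect", str(exc)) from exc

    # --- track --------------------------------------------------------
    try:
        radius = float(
            config.get("match_radius", preset.population.mobility.match_radius)
        )
        records_ = match_cells(dets["t0"], dets["t1"], radius)
        counts = tally_fates(records_, len(dets["t0"]), len(dets["t1"]))
        tracks_path = out / "tracks.csv"
        tracks_to_frame(records_).to_csv(tracks_path, index=False)
        fates_path = out / "fates.csv"
        import pandas as pd

        pd.DataFrame([dataclasses.asdict(counts)]).to_csv(fates_path, index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("track", str(exc)) from exc
    record("track", tracks_path, len(records_))
    record("track", fates_path, 1)

    # --- classify -----------------------------------------------------
    try:
        lum0 = np.asarray(images["luminescence_t0"], dtype=np.float64)
        lum1 = np.asarray(images["luminescence_t1"], dtype=np.float64)
        bg_mean, bg_sd = estimate_background(lum1)
        lod = compute_lod(
            bg_mean, bg_sd, lod_k, aperture_area(params.aperture_radius)
        )
        by0 = {d.det_id: d for d in dets["t0"]}
        by1 = {d.det_id: d for d in dets["t1"]}
        traj = []
        for r in records_:
            if r.det_t1 is None:
                continue
            try:
                i0 = measure_intensity(lum0, by0[r.det_t0].centroid, params)
                i1 = measure_intensity(lum1, by1[r.det_t1].centroid, params)
            except ApertureError:
                continue
            traj.append(classify_cell(i0, i1, lod, r.det_t0, r.det_t1))
        traj_path = out / "trajectories.csv"
        trajectories_to_frame(traj).to_csv(traj_path, index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("classify", str(exc)) from exc
    record("classify", traj_path, len(traj))

    # --- summarize ----------------------------------------------------
    try:
        import pandas as pd

        summary = summarize_responses(traj, preset.label)
        summary_path = out / "summary.csv"
        pd.DataFrame([dataclasses.asdict(summary)]).to_csv(summary_path, index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("summarize", str(exc)) from exc
    record("summarize", summary_path, 1)

    cfg_text = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": seed,
        "preset": config["preset"],
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "lod_value": lod.value,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
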