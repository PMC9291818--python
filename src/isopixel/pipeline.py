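"""Reproducible simulate -> ratios -> mosaic -> ROI stats -> coupling stats runs.

A run is driven by a single configuration (dict or YAML file). One global
seed deterministically derives a seed per stage through
``numpy.random.SeedSequence(global_seed).spawn``, so any stage can be rerun
in isolation and two runs with identical configuration are byte-identical.
Every stage records its outputs, parameters and input checksums in the run
manifest; a failing stage aborts the run with the stage named and leaves a
FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .maps import compute_isotope_pair_map
from .mosaic import MosaicLayout, adsorption_qc, assemble_mosaic
from .roi import roi_composition, tissue_summary
from .scene import (
    RootSystemConfig,
    SceneConfig,
    TileGrid,
    generate_root_system_table,
    generate_root_tip_scene,
    simulate_counts,
    truth_to_roiset,
)
from .stack_io import (
    ControlReference,
    load_control_reference,
    write_control_reference,
    write_ion_stack,
    write_roi_set,
)
from .stats import fit_segmented, root_side_analysis, select_model

__all__ = ["run_pipeline", "PipelineError", "default_config", "stage_seed"]

# Ratios are computed on the stitched count canvas (count stitching and
# ratio-after-stitch commute with per-tile ratios on non-overlap pixels).
STAGES = ("simulate", "mosaic", "ratios", "roi_stats", "segfit", "rootstats")


class PipelineError(RuntimeError):
    """A pipeline configuration or stage failure."""


def default_config() -> dict:
    """A small, fully synthetic end-to-end run configuration."""
    return {
        "seed": 0,
        "out_dir": "isopixel_run",
        "stages": list(STAGES),
        "scene": {"shape": [184, 184], "cell_size_px": 12, "n_hyphae": 25},
        "grid": {"rows": 2, "cols": 2, "tile_px": 96, "overlap_px": 8},
        "control": {"at13c_pct": 1.07, "at15n_pct": 0.37},
        "stats": {"criterion": "AIC", "alpha": 0.05, "n_boot": 199,
                  "min_rois_per_group": 12},
        "root_system": {},
    }


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed)
    return int(ss.spawn(len(STAGES))[idx].generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate(config: dict) -> list[str]:
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    deps = {"ratios": "mosaic", "mosaic": "simulate", "roi_stats": "mosaic",
            "segfit": "roi_stats"}
    for stage, needed in deps.items():
        if stage in stages and needed not in stages:
            raise PipelineError(f"stage '{stage}' requires stage '{needed}'")
    return stages


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = {**default_config(), **config}
    stages = _validate(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config": _jsonable(cfg), "seed": seed,
                      "version": __version__, "stages": {}}

    state: dict = {}
    for stage in (s for s in STAGES if s in stages):
        entry: dict = {"seed": stage_seed(seed, stage), "outputs": {}}
        try:
            _STAGE_FUNCS[stage](cfg, state, out_dir, entry)
        except Exception as exc:
            (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            manifest["stages"][stage] = {**entry, "status": "FAILED", "error": str(exc)}
            _write_manifest(out_dir, manifest)
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        for name, p in entry["outputs"].items():
            entry["outputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
        entry["status"] = "OK"
        manifest["stages"][stage] = entry
    failed = out_dir / "FAILED"
    if failed.exists():
        failed.unlink()
    _write_manifest(out_dir, manifest)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=1, sort_keys=True) + "\n"
    )


def _stage_simulate(cfg, state, out_dir, entry):
    scene_cfg = SceneConfig.from_dict({**cfg.get("scene", {}), "seed": entry["seed"]})
    truth = generate_root_tip_scene(scene_cfg)
    grid = TileGrid(**cfg["grid"])
    tiles = simulate_counts(truth, grid, seed=entry["seed"] + 1)
    tiles_dir = out_dir / "tiles"
    tiles_dir.mkdir(exist_ok=True)
    for i, tile in enumerate(tiles):
        p = write_ion_stack(tile, tiles_dir / f"tile_{i:02d}.tif")
        entry["outputs"][f"tile_{i:02d}"] = p
    tifffile.imwrite(out_dir / "truth_tissue.tif", truth.tissue.astype("<i2"))
    tifffile.imwrite(out_dir / "truth_p13c.tif", truth.p_c.astype("<f4"))
    tifffile.imwrite(out_dir / "truth_p15n.tif", truth.p_n.astype("<f4"))
    meta = {"seed": entry["seed"], "scene": _jsonable(scene_cfg.to_dict())}
    (out_dir / "truth_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    for name in ("truth_tissue.tif", "truth_p13c.tif", "truth_p15n.tif", "truth_meta.json"):
        entry["outputs"][name] = out_dir / name
    ctrl = ControlReference(**cfg["control"])
    write_control_reference(ctrl, out_dir / "control.csv")
    entry["outputs"]["control"] = out_dir / "control.csv"
    state.update(truth=truth, grid=grid, tiles=tiles, control=ctrl)


def _stage_mosaic(cfg, state, out_dir, entry):
    truth, grid = state["truth"], state["grid"]
    layout = MosaicLayout.from_grid(grid, truth.config.pixel_size_um)
    canvas, contrib = assemble_mosaic(state["tiles"], layout)
    p = write_ion_stack(canvas, out_dir / "canvas.tif")
    entry["outputs"]["canvas"] = p
    (out_dir / "layout.json").write_text(json.dumps(layout.to_dict(), indent=1, sort_keys=True) + "\n")
    entry["outputs"]["layout"] = out_dir / "layout.json"
    state.update(canvas=canvas, contrib=contrib, layout=layout)


def _stage_ratios(cfg, state, out_dir, entry):
    pair = compute_isotope_pair_map(state["canvas"], control=state["control"])
    tifffile.imwrite(out_dir / "at13c.tif", pair.at13c.at_pct.astype("<f4"))
    tifffile.imwrite(out_dir / "at15n.tif", pair.at15n.at_pct.astype("<f4"))
    tifffile.imwrite(out_dir / "total_cn.tif", pair.total_cn.astype("<f4"))
    for name in ("at13c.tif", "at15n.tif", "total_cn.tif"):
        entry["outputs"][name] = out_dir / name
    qc = adsorption_qc(pair.at15n.at_pct, state["layout"], contrib=state["contrib"],
                       alpha=cfg["stats"].get("alpha", 0.05))
    qc.to_csv(out_dir / "adsorption_qc.csv", index=False)
    entry["outputs"]["adsorption_qc"] = out_dir / "adsorption_qc.csv"
    state["pair"] = pair


def _stage_roi_stats(cfg, state, out_dir, entry):
    rois = truth_to_roiset(state["truth"])
    write_roi_set(rois, out_dir / "rois.tif", out_dir / "rois.csv")
    table = roi_composition(state["canvas"], rois, control=state["control"])
    table.to_csv(out_dir / "roi_table.csv", index=False)
    summary = tissue_summary(table)
    summary.to_csv(out_dir / "tissue_summary.csv", index=False)
    for name in ("rois.tif", "rois.csv", "roi_table.csv", "tissue_summary.csv"):
        entry["outputs"][name] = out_dir / name
    state["roi_table"] = table


def _stage_segfit(cfg, state, out_dir, entry):
    table = state["roi_table"]
    stats_cfg = cfg["stats"]
    rows = []
    for (tis, comp), grp in table.groupby(["tissue", "compartment"]):
        if len(grp) < stats_cfg.get("min_rois_per_group", 12):
            continue
        x = grp["ape13c_pct"].to_numpy(dtype=float)
        y = grp["ape15n_pct"].to_numpy(dtype=float)
        if np.unique(x).size < 5:
            continue
        sel = select_model(x, y, criterion=stats_cfg.get("criterion", "AIC"),
                           seed=entry["seed"])
        fit = fit_segmented(x, y, n_boot=stats_cfg.get("n_boot", 199),
                            alpha=stats_cfg.get("alpha", 0.05), seed=entry["seed"])
        rows.append({
            "tissue": tis, "compartment": comp, "n": fit.n,
            "selected_model": sel.selected, "segmented": fit.segmented,
            "breakpoint": fit.breakpoint, "se_breakpoint": fit.se_breakpoint,
            "slope_low": fit.slope_low, "slope_high": fit.slope_high,
            "intercept": fit.intercept, "r2": fit.r2,
            "r2_low": fit.r2_low, "r2_high": fit.r2_high,
            "p_low": fit.p_low, "p_high": fit.p_high,
            "p_existence": fit.p_existence,
        })
    pd.DataFrame(rows).to_csv(out_dir / "segmented_fits.csv", index=False)
    entry["outputs"]["segmented_fits"] = out_dir / "segmented_fits.csv"


def _stage_rootstats(cfg, state, out_dir, entry):
    rs_cfg = cfg.get("root_system", {}) or {}
    root_cfg = RootSystemConfig(**{**rs_cfg, "seed": entry["seed"]})
    table = generate_root_system_table(root_cfg)
    table.to_csv(out_dir / "root_system.csv", index=False)
    sides = root_side_analysis(table)
    rows = [vars(s) for s in sides.values()]
    pd.DataFrame(rows).to_csv(out_dir / "root_sides.csv", index=False)
    entry["outputs"]["root_system"] = out_dir / "root_system.csv"
    entry["outputs"]["root_sides"] = out_dir / "root_sides.csv"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "mosaic": _stage_mosaic,
    "ratios": _stage_ratios,
    "roi_stats": _stage_roi_stats,
    "segfit": _stage_segfit,
    "rootstats": _stage_rootstats,
}
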