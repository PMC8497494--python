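"""End-to-end pipeline runs: simulate fixtures, analyze dishes.

`run_simulate` writes fixture triplets (multi-page TIFF + ground-truth CSV +
scene JSON) and `run_high_content` executes the full high-content chain
(background subtraction -> nuclear segmentation -> extraction -> red and
cell-cycle gates -> ratio summary) per dish, emitting a cell-record CSV and
a JSON summary that embeds the config hash, seed, software version and
every threshold and count used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig, config_hash
from .gating import gate_by_cell_cycle, gate_by_red
from .imaging import (
    ChannelStack,
    extract_cells,
    segment_nuclei,
    subtract_background_stack,
)
from .models import DomainError, calibration_to_dict
from .popstats import summarize_ratios
from .synth import SceneSpec, render_field

__all__ = ["run_simulate", "run_high_content", "read_field", "write_field"]

logger = logging.getLogger("ratiovm")


def _log(event: str, **fields):
    logger.info(json.dumps({"event": event, **fields}, default=str))


def write_field(prefix: Path, stack: ChannelStack, truth, spec: SceneSpec) -> dict:
    """Write one field as TIFF (pages: blue, green x4, red) + CSV + JSON."""
    prefix = Path(prefix)
    pages = [stack.blue, *stack.green, stack.red]
    arr = np.stack([np.asarray(p) for p in pages]).astype(np.uint16)
    tiff_path = prefix.with_suffix(".tiff")
    tifffile.imwrite(tiff_path, arr)
    truth.cells.to_csv(prefix.parent / (prefix.name + "_truth.csv"), index=False)
    spec_dict = dataclasses.asdict(spec)
    spec_dict["calibration"] = calibration_to_dict("", spec.calibration)
    with open(prefix.parent / (prefix.name + "_scene.json"), "w") as fh:
        json.dump(spec_dict, fh, indent=1, default=str)
    return {"tiff": str(tiff_path)}


def read_field(path, config: RunConfig) -> ChannelStack:
    """Load a multi-page TIFF using the explicit channel-order mapping."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    order = config.channel_order
    if len(pages) < len(order):
        raise DomainError(
            f"{path}: {len(pages)} pages but channel order names {len(order)}"
        )
    by_channel: dict[str, list] = {}
    for name, page in zip(order, pages):
        by_channel.setdefault(name, []).append(np.asarray(page, dtype=float))
    if "blue" not in by_channel or "green" not in by_channel or "red" not in by_channel:
        raise DomainError(f"{path}: channel order must include blue, green, red")
    return ChannelStack(
        blue=by_channel["blue"][0],
        green=by_channel["green"],
        red=by_channel["red"][0],
        transmission=by_channel.get("transmission", [None])[0],
        pixel_size=config.pixel_size,
        bit_depth=config.bit_depth,
        camera_offset={
            "blue": config.camera_offset,
            "green": config.camera_offset,
            "red": config.camera_offset,
            "transmission": config.camera_offset,
        },
    )


def run_simulate(config: RunConfig) -> dict:
    """Render ``n_fields`` synthetic fields and write fixture triplets."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = dict(config.scene or {})
    if "shape" in overrides:
        overrides["shape"] = tuple(overrides["shape"])
    written = []
    for i in range(config.n_fields):
        spec = SceneSpec(seed=int(config.seed) + i, **overrides)
        stack, truth = render_field(spec)
        info = write_field(out / f"field_{i:03d}", stack, truth, spec)
        written.append(info["tiff"])
        _log("simulated_field", field=i, tiff=info["tiff"], n_cells=len(truth))
    manifest = {
        "mode": "simulate",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "fields": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def analyze_field(stack: ChannelStack, config: RunConfig) -> pd.DataFrame:
    """Background subtraction, segmentation and extraction for one field."""
    sub = subtract_background_stack(stack, config.ball_radius_um)
    labels = segment_nuclei(sub.blue, sub.pixel_size, threshold=config.threshold)
    return extract_cells(sub, labels)


def run_high_content(config: RunConfig) -> dict:
    """Analyze one or more dishes of high-content fields.

    Each input directory is treated as one dish; bare TIFF inputs form a
    single dish.  Unreadable files are reported per-file and the run
    continues.  Per dish, writes ``<dish>_cells.csv`` and
    ``<dish>_summary.json``.
    """
    inputs = [Path(p) for p in config.inputs]
    if not inputs:
        raise DomainError("no inputs configured")
    dishes: dict[str, list[Path]] = {}
    for p in inputs:
        if p.is_dir():
            tiffs = sorted(
                list(p.glob("*.tif")) + list(p.glob("*.tiff"))
            )
            dishes[p.name] = tiffs
        else:
            dishes.setdefault("dish0", []).append(p)
    if all(len(v) == 0 for v in dishes.values()):
        raise DomainError(f"no inputs: no TIFF files found in {config.inputs}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "mode": "high_content",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "dishes": {},
    }
    for dish, files in dishes.items():
        frames = []
        failures = []
        for f in files:
            try:
                stack = read_field(f, config)
                records = analyze_field(stack, config)
            except Exception as exc:  # noqa: BLE001 - per-file isolation
                failures.append({"file": str(f), "error": str(exc)})
                _log("field_failed", file=str(f), error=str(exc))
                continue
            records = records.assign(field=f.name)
            frames.append(records)
            _log("field_analyzed", file=str(f), n_rois=len(records))
        cells = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame()
        )
        summary: dict = {
            "dish": dish,
            "n_fields": len(files),
            "n_failures": len(failures),
            "failures": failures,
            "n_cells_extracted": int(len(cells)),
            "audits": [],
        }
        gated = cells
        if len(cells):
            gated, audit_red = gate_by_red(cells, config.gate)
            summary["audits"].append(audit_red)
            if config.gate.cc_gate_enabled and len(gated) >= 300:
                gated, audit_cc = gate_by_cell_cycle(
                    gated, config.gate.cc_half_width
                )
                summary["audits"].append(audit_cc)
        if len(gated) >= 2:
            ratios = (gated["f_green"] / gated["f_red"]).to_numpy()
            ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
            dist = summarize_ratios(
                ratios, n_boot=int(ratios.size >= 10), n_resamples=2000,
                seed=config.seed,
            )
            summary["ratio"] = {
                "median": dist.median,
                "geometric_sd": dist.geometric_sd,
                "bootstrap_sd_percent": dist.bootstrap_sd_percent,
                "n_cells": dist.n_cells,
            }
        cells_path = out / f"{dish}_cells.csv"
        cells.to_csv(cells_path, index=False)
        with open(out / f"{dish}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=str)
        report["dishes"][dish] = summary
        _log("dish_done", dish=dish, n_cells=len(cells))
    with open(out / "run_summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
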