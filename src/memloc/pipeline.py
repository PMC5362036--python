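"""Run orchestration: simulate -> (segment | ground-truth outlines) ->
quantify -> report, with reproducible seeding, structured logging, and a
canonical fixture generator.

A run directory always contains the resolved configuration that reproduces
it byte-for-byte (for the tabular/JSON outputs) and a JSON-lines log with
one record per executed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import MemlocError
from .outlines import (CellOutline, read_outline_document, rasterize,
                       segment_stand_in, write_outlines)
from .popstats import calibrate, ratio_vs_length, summarize
from .simcell import SimulationConfig, simulate
from .whisit import (CellMeasurement, CompartmentParams, measure_image,
                     membrane_ring, write_measurements)

__all__ = ["RunConfig", "run", "make_fixtures", "stage_seed"]

log = logging.getLogger("memloc")

_STAGES = ("simulate", "segment", "quantify", "report")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the single run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Fully serializable description of one reproducible run."""

    out_dir: str
    stages: tuple = _STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    compartments: CompartmentParams = field(
        default_factory=lambda: CompartmentParams(background_mode="constant",
                                                  background_value=100.0))
    use_ground_truth_outlines: bool = True
    segment_sigma: float = 2.0
    segment_min_area: int = 50
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "compartments" in d:
            d["compartments"] = CompartmentParams(**d["compartments"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _log_stage(handle, stage: str, t0: float, **info) -> None:
    record = {"stage": stage, "wall_s": round(time.perf_counter() - t0, 3),
              **info}
    handle.write(json.dumps(record) + "\n")
    log.info("stage %s done: %s", stage, info)


def run(config: RunConfig) -> Path:
    """Execute the requested stages in canonical order.

    Stage failures abort with the failing stage named; artifacts written
    before the failure are retained.  Re-running the same resolved config
    reproduces all CSV/JSON outputs byte-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    stages = [s for s in _STAGES if s in config.stages]
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1))

    sim = dataclasses.replace(config.simulation,
                              seed=stage_seed(config.seed, "simulate"))
    with open(out / "run_log.jsonl", "w") as logf:
        for stage in stages:
            t0 = time.perf_counter()
            try:
                if stage == "simulate":
                    simulate(sim, out)
                    _log_stage(logf, stage, t0, n_cells=sim.n_cells,
                               seed=sim.seed)
                elif stage == "segment":
                    image_path = out / "image.tif"
                    if not image_path.exists():
                        raise MemlocError("missing_input",
                                          "stage 'segment' needs image.tif")
                    img = tifffile.imread(image_path)
                    if img.ndim == 3:
                        img = img[0]
                    outlines = segment_stand_in(img, config.segment_sigma,
                                                config.segment_min_area)
                    write_outlines(outlines, out / "outlines_segmented.json",
                                   pixel_size_um=sim.pixel_size_um)
                    _log_stage(logf, stage, t0, n_outlines=len(outlines))
                elif stage == "quantify":
                    if config.use_ground_truth_outlines:
                        outline_path = out / "outlines.json"
                    else:
                        outline_path = out / "outlines_segmented.json"
                    image_path = out / "image.tif"
                    if not outline_path.exists() or not image_path.exists():
                        raise MemlocError(
                            "missing_input",
                            "stage 'quantify' needs image.tif and an "
                            "outlines source")
                    img = tifffile.imread(image_path)
                    if img.ndim == 3:
                        img = img[0]
                    outlines, px = read_outline_document(outline_path)
                    measurements = measure_image(img, outlines,
                                                 config.compartments, px)
                    write_measurements(measurements, out / "cells.csv")
                    n_flagged = sum(1 for m in measurements if not m.valid)
                    _log_stage(logf, stage, t0, n_cells=len(measurements),
                               n_flagged=n_flagged)
                elif stage == "report":
                    cells_path = out / "cells.csv"
                    if not cells_path.exists():
                        raise MemlocError("missing_input",
                                          "stage 'report' needs cells.csv")
                    from .whisit import read_measurements
                    measurements = read_measurements(cells_path)
                    summary = summarize(measurements,
                                        config.compartments.threshold)
                    (out / "summary.json").write_text(
                        json.dumps(summary.to_dict(), indent=1))
                    ratio_vs_length(measurements).to_csv(
                        out / "ratio_length.csv", index=False,
                        float_format="%.6f")
                    _log_stage(logf, stage, t0,
                               fraction_membrane=summary.fraction_membrane)
            except MemlocError:
                raise
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise MemlocError("stage_failed",
                                  f"stage '{stage}' failed: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

def _chebyshev_ring_bruteforce(mask: np.ndarray, width: int) -> np.ndarray:
    """Independent ring definition: per-pixel minimum Chebyshev distance to
    any exterior pixel (image edge counts as exterior), O(n*m) brute force.
    Used only to produce fixture sidecars and as a test oracle."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    ext = np.argwhere(~padded)
    ring = np.zeros_like(mask)
    for (r, c) in np.argwhere(padded):
        if not padded[r, c]:
            continue
        dist = np.max(np.abs(ext - (r, c)), axis=1).min()
        if dist <= width:
            ring[r - 1, c - 1] = True
    return ring


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the six canonical small fixtures with oracle sidecars.

    1. ``square_mask`` — 12x12 pixel square outline; sidecar holds the
       brute-force ring/interior pixel counts for a 4 px ring.
    2. ``uniform_image`` — constant image + one outline; sidecar ratio 1.0.
    3. ``membrane_cell`` — one noiseless membrane-mode cell at defaults.
    4. ``cytosolic_cell`` — one noiseless cytosolic-mode cell at defaults.
    5. ``mixed_cohort`` — 20-cell mixed-population snapshot.
    6. ``timelapse_trace`` — 7-frame ratio trace with its episode sidecar.
    """
    from .simcell import CellGeometry, apply_optics, outline_of, _render_cell

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise MemlocError("io_error", str(exc)) from exc
    paths: dict[str, Path] = {}

    # 1. square mask
    square = CellOutline("square", np.array(
        [[-0.5, -0.5], [11.5, -0.5], [11.5, 11.5], [-0.5, 11.5]]) + 4.0)
    write_outlines([square], out / "square_mask.json")
    mask = rasterize(square, (20, 20))
    ring = _chebyshev_ring_bruteforce(mask, 4)
    (out / "square_mask.expected.json").write_text(json.dumps({
        "mask_px": int(mask.sum()), "ring_px": int(ring.sum()),
        "interior_px": int(mask.sum() - ring.sum())}))
    paths["square_mask"] = out / "square_mask.json"

    # 2. uniform image
    uniform = np.full((40, 40), 7.0, dtype=np.float32)
    tifffile.imwrite(out / "uniform_image.tif", uniform)
    write_outlines([CellOutline("u1", np.array(
        [[5.0, 5.0], [30.0, 5.0], [30.0, 30.0], [5.0, 30.0]]))],
        out / "uniform_image.json")
    (out / "uniform_image.expected.json").write_text(
        json.dumps({"ratio": 1.0}))
    paths["uniform_image"] = out / "uniform_image.tif"

    # 3-4. single noiseless cells at default geometry/optics
    for name, mode in (("membrane_cell", "membrane"),
                       ("cytosolic_cell", "cytosolic")):
        geom = CellGeometry(name, center=(40.0, 40.0), length_px=45.0,
                            width_px=15.0, orientation_rad=0.3, mode=mode)
        canvas = np.zeros((80, 80))
        _render_cell(geom, 1000.0, 1.5, canvas)
        img = apply_optics(canvas, 2.0, 100.0, poisson=False, read_sd=0.0)
        tifffile.imwrite(out / f"{name}.tif", img.astype(np.float32))
        write_outlines([outline_of(geom)], out / f"{name}.json",
                       pixel_size_um=0.066)
        (out / f"{name}.expected.json").write_text(json.dumps(
            {"class": mode, "threshold": 0.7, "background": 100.0}))
        paths[name] = out / f"{name}.tif"

    # 5. 20-cell mixed cohort
    cohort_cfg = SimulationConfig(canvas_shape=(400, 400), n_cells=20,
                                  population_membrane_prob=0.5, seed=11)
    simulate(cohort_cfg, out / "mixed_cohort")
    paths["mixed_cohort"] = out / "mixed_cohort"

    # 6. 7-frame time-lapse ratio trace
    trace = [0.9, 0.9, 0.6, 0.65, 0.6, 0.9, 0.95]
    pd.DataFrame({"frame": range(len(trace)), "ratio": trace}).to_csv(
        out / "timelapse_trace.csv", index=False)
    (out / "timelapse_trace.expected.json").write_text(json.dumps({
        "frame_interval_min": 3.0, "n_episodes": 1,
        "onset_time_min": 6.0, "duration_min": 9.0}))
    paths["timelapse_trace"] = out / "timelapse_trace.csv"

    return paths
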