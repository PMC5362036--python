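"""Physics-based synthetic fluorescence microscopy of rod-shaped bacteria.

Cells are modelled as 3D spherocylinders (a cylinder of radius r capped by
two hemispheres) and a 2D image is the projection (line integral) through
the cell along the optical axis:

* a uniformly distributed cytosolic label projects the chord depth
  ``2 * sqrt(r^2 - d^2)`` at perpendicular distance ``d`` from the long axis
  (sphere-chord formula with the distance from the cap center near poles) —
  a center-peaked profile, dimmer near the silhouette edge;
* a membrane-confined label projects the path length through a thin shell
  of thickness ``t``, ``2 * (sqrt(r^2 - d^2) - sqrt(max(0, (r-t)^2 - d^2)))``
  — an edge-peaked profile.

This projection asymmetry is what a membrane/cytosol intensity-ratio
classifier exploits, so it is modelled explicitly rather than with flat
disks.  Optics are an isotropic Gaussian PSF; detection adds a constant
background, Poisson shot noise and Gaussian read noise, clamped at zero.

One :func:`simulate` call produces one cohort ("strain"): a fluorescence
TIFF (multi-page for time-lapse), ground-truth outlines JSON, a per-cell
label CSV, and the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import MemlocError
from .outlines import CellOutline, write_outlines, write_timelapse_outlines

__all__ = [
    "CellGeometry",
    "SimulationConfig",
    "Cohort",
    "sample_population",
    "render_cytosolic",
    "render_membrane",
    "shell_path_length",
    "apply_optics",
    "outline_of",
    "simulate",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CellGeometry:
    """Parametric spherocylinder in image coordinates.

    ``length_px`` is the total pole-to-pole length including both
    hemispherical caps; ``width_px`` is the diameter ``2r``.  ``mode``
    selects the label distribution; ``membrane_fraction`` is the fraction
    f of total label in the membrane shell (0 = purely cytosolic,
    1 = purely membrane; only meaningful for mode="mixed").
    """

    id: str
    center: tuple[float, float]  # (x, y)
    length_px: float
    width_px: float
    orientation_rad: float
    mode: str = "cytosolic"  # {cytosolic, membrane, mixed}
    membrane_fraction: float = 0.0

    def __post_init__(self):
        if not (self.length_px >= self.width_px > 0):
            raise MemlocError("invalid_geometry",
                              f"cell '{self.id}': need length_px >= width_px > 0")
        if not (0.0 <= self.membrane_fraction <= 1.0):
            raise MemlocError("invalid_geometry",
                              f"cell '{self.id}': membrane_fraction outside [0, 1]")
        if self.mode not in ("cytosolic", "membrane", "mixed"):
            raise MemlocError("invalid_geometry",
                              f"cell '{self.id}': unknown mode '{self.mode}'")
        # pure modes and the f = 0 / f = 1 extremes are the same physical model
        if self.mode == "cytosolic" and self.membrane_fraction != 0.0:
            object.__setattr__(self, "membrane_fraction", 0.0)
        if self.mode == "membrane":
            object.__setattr__(self, "membrane_fraction", 1.0)

    @property
    def radius_px(self) -> float:
        return self.width_px / 2.0

    @property
    def half_body_px(self) -> float:
        """Half-length of the cylindrical body (axial extent of the straight part)."""
        return (self.length_px - self.width_px) / 2.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate standard wide-field fluorescence snapshots of
    *C. crescentus*-like rods: 15 px cell width at 0.066 um/px (~1 um),
    lengths uniform in 30-60 px (~2-4 um), a 1.5 px membrane shell,
    a 2 px Gaussian PSF, constant background of 100 counts, Poisson shot
    noise and 20-count read noise.  250 cells per cohort matches typical
    per-strain sample sizes in single-cell localization studies.
    """

    canvas_shape: tuple[int, int] = (1200, 1200)  # (rows, cols)
    n_cells: int = 250
    length_dist: tuple = ("uniform", 30.0, 60.0)  # pixels, pole to pole
    width_px: float = 15.0
    pixel_size_um: float = 0.066
    shell_thickness_px: float = 1.5
    amplitude: float = 1000.0
    background: float = 100.0
    psf_sigma_px: float = 2.0
    poisson: bool = True
    read_sd: float = 20.0
    population_membrane_prob: float = 0.5
    seed: int = 0
    margin_px: float = 14.0       # keep silhouettes this far from the border
    spacing_px: float = 2.0       # minimum clearance between silhouettes
    max_attempts: int = 1000      # placement rejection cap, per cell
    outline_vertices: int = 64
    # time-lapse: if n_frames is set, every cell is rendered as a mixed-mode
    # cell whose membrane_fraction follows the per-frame schedule
    n_frames: int | None = None
    frame_interval_min: float = 3.0
    membrane_fraction_schedule: tuple | None = None

    def __post_init__(self):
        if self.width_px <= 8:
            raise MemlocError("invalid_config",
                              "width_px must exceed 8 so the cytosolic "
                              "compartment is non-empty after a 4 px ring")
        if not (0 < self.shell_thickness_px < self.width_px / 2):
            raise MemlocError("shell_too_thick",
                              "need 0 < shell_thickness_px < width_px / 2")
        if self.n_frames is not None:
            sched = self.membrane_fraction_schedule
            if sched is None or len(sched) != self.n_frames:
                raise MemlocError(
                    "invalid_config",
                    "time-lapse runs need a membrane_fraction_schedule with "
                    "one value per frame")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas_shape"] = list(self.canvas_shape)
        d["length_dist"] = list(self.length_dist)
        if self.membrane_fraction_schedule is not None:
            d["membrane_fraction_schedule"] = list(self.membrane_fraction_schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "canvas_shape" in d:
            d["canvas_shape"] = tuple(d["canvas_shape"])
        if "length_dist" in d:
            d["length_dist"] = tuple(d["length_dist"])
        if d.get("membrane_fraction_schedule") is not None:
            d["membrane_fraction_schedule"] = tuple(d["membrane_fraction_schedule"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _effective_distance(geom: CellGeometry, xs: np.ndarray,
                        ys: np.ndarray) -> np.ndarray:
    """Distance governing the projection formulas at pixel centers (xs, ys).

    Within the cylindrical body this is the perpendicular distance to the
    long axis; beyond the body/cap boundary (axial distance half_body from
    the center) it is the distance to the nearest cap center, so the
    sphere-chord formula applies seamlessly at the poles.
    """
    dx = xs - geom.center[0]
    dy = ys - geom.center[1]
    c, s = np.cos(geom.orientation_rad), np.sin(geom.orientation_rad)
    axial = dx * c + dy * s
    perp = -dx * s + dy * c
    over = np.maximum(np.abs(axial) - geom.half_body_px, 0.0)
    return np.hypot(over, perp)


def _bbox(geom: CellGeometry, shape: tuple[int, int],
          pad: float = 0.0) -> tuple[int, int, int, int] | None:
    """Integer pixel bounding box of the silhouette (+pad); None if clipped."""
    c, s = np.cos(geom.orientation_rad), np.sin(geom.orientation_rad)
    hx = geom.half_body_px * abs(c) + geom.radius_px + pad
    hy = geom.half_body_px * abs(s) + geom.radius_px + pad
    x0 = int(np.floor(geom.center[0] - hx))
    x1 = int(np.ceil(geom.center[0] + hx))
    y0 = int(np.floor(geom.center[1] - hy))
    y1 = int(np.ceil(geom.center[1] + hy))
    rows, cols = shape
    if x0 < 0 or y0 < 0 or x1 > cols - 1 or y1 > rows - 1:
        return None
    return x0, x1, y0, y1


def _window(geom: CellGeometry, shape: tuple[int, int]):
    box = _bbox(geom, shape, pad=1.0)
    if box is None:
        raise MemlocError("cell_out_of_bounds",
                          f"cell '{geom.id}' footprint exceeds the canvas")
    x0, x1, y0, y1 = box
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float),
                         np.arange(y0, y1 + 1, dtype=float))
    return (slice(y0, y1 + 1), slice(x0, x1 + 1)), xs, ys


def footprint_mask(geom: CellGeometry, shape: tuple[int, int],
                   dilate_px: float = 0.0) -> np.ndarray:
    """Boolean silhouette mask (pixel centers within distance r + dilate_px)."""
    win, xs, ys = _window_padded(geom, shape, dilate_px)
    d = _effective_distance(geom, xs, ys)
    mask = np.zeros(shape, dtype=bool)
    mask[win] = d <= geom.radius_px + dilate_px
    return mask


def _window_padded(geom: CellGeometry, shape: tuple[int, int], pad: float):
    box = _bbox(geom, shape, pad=pad + 1.0)
    if box is None:
        raise MemlocError("cell_out_of_bounds",
                          f"cell '{geom.id}' footprint exceeds the canvas")
    x0, x1, y0, y1 = box
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1, dtype=float),
                         np.arange(y0, y1 + 1, dtype=float))
    return (slice(y0, y1 + 1), slice(x0, x1 + 1)), xs, ys


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_cytosolic(geom: CellGeometry, amplitude: float,
                     canvas: np.ndarray) -> np.ndarray:
    """Add the projection of a uniformly labelled solid spherocylinder.

    The chord depth ``2*sqrt(r^2 - d^2)`` is normalized so the value on the
    long axis at mid-cell equals ``amplitude``; zero outside the silhouette.
    Modifies ``canvas`` in place and returns it.
    """
    win, xs, ys = _window(geom, canvas.shape)
    d = _effective_distance(geom, xs, ys)
    r = geom.radius_px
    chord = 2.0 * np.sqrt(np.maximum(r * r - d * d, 0.0))
    canvas[win] += amplitude * chord / (2.0 * r)
    return canvas


def shell_path_length(geom: CellGeometry, d: np.ndarray,
                      shell_thickness_px: float) -> np.ndarray:
    """Unscaled projected path length through the membrane shell at distance d.

    ``2 * (sqrt(r^2 - d^2) - sqrt(max(0, (r-t)^2 - d^2)))``: equals ``2t`` on
    the axis (two wall crossings), peaks at ``d = r - t`` with value
    ``2*sqrt(2 r t - t^2)``, and is zero outside the silhouette.
    """
    r = geom.radius_px
    t = shell_thickness_px
    if not (0 < t < r):
        raise MemlocError("shell_too_thick", "need 0 < thickness < radius")
    outer = np.sqrt(np.maximum(r * r - d * d, 0.0))
    inner = np.sqrt(np.maximum((r - t) ** 2 - d * d, 0.0))
    return 2.0 * (outer - inner)


def render_membrane(geom: CellGeometry, amplitude: float,
                    shell_thickness_px: float, canvas: np.ndarray) -> np.ndarray:
    """Add the projection of a membrane-shell label.

    The shell path-length profile is scaled so the cell's total integrated
    signal equals that of :func:`render_cytosolic` at the same ``amplitude``
    (the cytosolic footprint normalization).  Equal totals make the
    ``membrane_fraction`` knob of mixed cells mean "fraction of label in
    the membrane".  Modifies ``canvas`` in place and returns it.
    """
    win, xs, ys = _window(geom, canvas.shape)
    d = _effective_distance(geom, xs, ys)
    r = geom.radius_px
    shell = shell_path_length(geom, d, shell_thickness_px)
    chord_total = float((amplitude * 2.0 * np.sqrt(
        np.maximum(r * r - d * d, 0.0)) / (2.0 * r)).sum())
    shell_total = float(shell.sum())
    canvas[win] += shell * (chord_total / shell_total)
    return canvas


def _render_cell(geom: CellGeometry, amplitude: float, shell_thickness_px: float,
                 canvas: np.ndarray, membrane_fraction: float | None = None
                 ) -> np.ndarray:
    """Render one cell according to its mode (or an explicit override of f)."""
    f = geom.membrane_fraction if membrane_fraction is None else membrane_fraction
    if f > 0.0:
        render_membrane(geom, amplitude * f, shell_thickness_px, canvas)
    if f < 1.0:
        render_cytosolic(geom, amplitude * (1.0 - f), canvas)
    return canvas


def apply_optics(image: np.ndarray, psf_sigma_px: float, background: float,
                 poisson: bool = False, read_sd: float = 0.0,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Gaussian PSF blur, constant background, shot/read noise, clamp at zero.

    Order mimics image formation: photons blur through the optics, the
    detector adds a constant offset, photon counting is Poisson, read-out
    adds Gaussian noise, and negative counts are clamped to zero.
    """
    from scipy import ndimage

    if psf_sigma_px < 0 or background < 0:
        raise MemlocError("invalid_optics_param",
                          "psf_sigma_px and background must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = np.asarray(image, dtype=float)
    if psf_sigma_px > 0:
        out = ndimage.gaussian_filter(out, psf_sigma_px, mode="constant")
    out = out + background
    if poisson:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if read_sd > 0:
        out = out + rng.normal(0.0, read_sd, size=out.shape)
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# Ground-truth outlines
# ---------------------------------------------------------------------------

def outline_of(geom: CellGeometry, n_vertices: int = 64) -> CellOutline:
    """Closed polygon tracing the spherocylinder silhouette.

    Vertices are spaced uniformly in arc length along the boundary (two
    straight edges plus two semicircular caps), in order, so the polygon is
    simple and its Feret diameter equals the cell length to sub-pixel
    accuracy for reasonable ``n_vertices``.
    """
    if n_vertices < 8:
        raise MemlocError("invalid_outline", "need n_vertices >= 8")
    r = geom.radius_px
    h = geom.half_body_px
    edge = 2.0 * h
    arc = np.pi * r
    perimeter = 2.0 * edge + 2.0 * arc
    s = np.linspace(0.0, perimeter, n_vertices, endpoint=False)
    pts = np.empty((n_vertices, 2))
    for i, si in enumerate(s):
        if si < arc:  # right cap, from (h, -r) around to (h, +r)
            ang = -np.pi / 2 + si / r
            pts[i] = (h + r * np.cos(ang), r * np.sin(ang))
        elif si < arc + edge:  # top edge, right to left
            pts[i] = (h - (si - arc), r)
        elif si < 2 * arc + edge:  # left cap
            ang = np.pi / 2 + (si - arc - edge) / r
            pts[i] = (-h + r * np.cos(ang), r * np.sin(ang))
        else:  # bottom edge, left to right
            pts[i] = (-h + (si - 2 * arc - edge), -r)
    c, sn = np.cos(geom.orientation_rad), np.sin(geom.orientation_rad)
    rot = np.array([[c, -sn], [sn, c]])
    pts = pts @ rot.T + np.asarray(geom.center)
    return CellOutline(geom.id, pts)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, dist: tuple, width_px: float) -> float:
    name = dist[0]
    if name == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        val = rng.uniform(lo, hi)
    elif name == "normal":
        val = rng.normal(float(dist[1]), float(dist[2]))
    elif name == "constant":
        val = float(dist[1])
    else:
        raise MemlocError("invalid_config", f"unknown length_dist '{name}'")
    return max(val, width_px)


def sample_population(config: SimulationConfig) -> list[CellGeometry]:
    """Draw non-overlapping cell geometries on the canvas.

    Placement is rejection sampling against an occupancy grid: a candidate
    is accepted only if its silhouette, dilated by ``spacing_px``, is
    disjoint from all previously accepted cells and at least ``margin_px``
    from the canvas border.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.canvas_shape
    occupied = np.zeros(shape, dtype=bool)
    cells: list[CellGeometry] = []
    rows, cols = shape
    for i in range(config.n_cells):
        length = _draw_length(rng, config.length_dist, config.width_px)
        theta = rng.uniform(0.0, np.pi)
        membrane = bool(rng.random() < config.population_membrane_prob)
        placed = False
        for _ in range(config.max_attempts):
            cx = rng.uniform(0, cols - 1)
            cy = rng.uniform(0, rows - 1)
            geom = CellGeometry(
                id=f"cell_{i:04d}", center=(cx, cy), length_px=length,
                width_px=config.width_px, orientation_rad=theta,
                mode="membrane" if membrane else "cytosolic",
                membrane_fraction=1.0 if membrane else 0.0)
            if _bbox(geom, shape, pad=config.margin_px) is None:
                continue
            fp = footprint_mask(geom, shape, dilate_px=config.spacing_px)
            if np.any(occupied & fp):
                continue
            occupied |= fp
            cells.append(geom)
            placed = True
            break
        if not placed:
            raise MemlocError(
                "canvas_too_crowded",
                f"could not place cell {i} after {config.max_attempts} attempts")
    return cells


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory result of one simulation: frames, outlines, ground truth."""

    config: SimulationConfig
    frames: list[np.ndarray]                  # one ImageGrid per frame
    outlines: list[list[CellOutline]]         # per frame, id-matched
    ground_truth: pd.DataFrame                # cell_id, mode, membrane_fraction, length_px
    geometries: list[CellGeometry]

    @property
    def image(self) -> np.ndarray:
        """The single frame of a snapshot cohort."""
        return self.frames[0]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the forward model in memory: sample, render, apply optics."""
    geoms = sample_population(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0F]))
    shape = config.canvas_shape

    if config.n_frames is None:
        schedule = [None]
    else:
        schedule = list(config.membrane_fraction_schedule)

    frames = []
    for f in schedule:
        canvas = np.zeros(shape, dtype=float)
        for g in geoms:
            _render_cell(g, config.amplitude, config.shell_thickness_px,
                         canvas, membrane_fraction=f)
        frames.append(apply_optics(canvas, config.psf_sigma_px,
                                   config.background, config.poisson,
                                   config.read_sd, rng))

    outlines_per_frame = [
        [outline_of(g, config.outline_vertices) for g in geoms]
        for _ in frames
    ]
    gt = pd.DataFrame({
        "cell_id": [g.id for g in geoms],
        "mode": [g.mode for g in geoms],
        "membrane_fraction": [g.membrane_fraction for g in geoms],
        "length_px": [g.length_px for g in geoms],
    })
    return Cohort(config, frames, outlines_per_frame, gt, geoms)


def simulate(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Simulate one cohort and write it to ``out_dir``.

    Writes ``image.tif`` (float32; multi-page for time-lapse),
    ``outlines.json``, ``labels.csv`` and ``config.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(config)
        stack = np.stack(cohort.frames).astype(np.float32)
        tifffile.imwrite(out / "image.tif",
                         stack if config.n_frames is not None else stack[0],
                         photometric="minisblack")
        if config.n_frames is not None:
            write_timelapse_outlines(cohort.outlines, out / "outlines.json",
                                     pixel_size_um=config.pixel_size_um)
        else:
            write_outlines(cohort.outlines[0], out / "outlines.json",
                           pixel_size_um=config.pixel_size_um, frame=None)
        cohort.ground_truth.to_csv(out / "labels.csv", index=False,
                                   float_format="%.6f")
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1))
    except OSError as exc:
        raise MemlocError("io_error", f"cannot write to {out}: {exc}") from exc
    return out
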