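"""Per-cell membrane/cytosol intensity-ratio quantification.

For each cell outline the pixel mask is split into two compartments:

* **membrane ring** — the first ``ring_width_px`` (default 4) intracellular
  pixels flanking the outline, formalized as the mask pixels with Chebyshev
  distance <= ring_width_px to the nearest exterior pixel (equivalently the
  mask minus that many successive 8-connected erosions);
* **cytosol** — the remaining interior pixels.

The per-cell statistic is the ratio of mean fluorescence in the ring to
mean fluorescence in the interior (``ratio_membrane_cytosol``).  Cells with
ratio strictly above a threshold (default 0.7) are classified
membrane-associated; at or below it, cytosolic.  A time-lapse trace of
ratios is scanned for dispersal episodes: maximal runs of at least two
consecutive cytosolic-classified frames (a debounce against single-frame
noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MemlocError
from .outlines import CellOutline, cell_length, rasterize

__all__ = [
    "CompartmentParams",
    "CompartmentMasks",
    "CellMeasurement",
    "DispersalEpisode",
    "membrane_ring",
    "cytosol_interior",
    "split_compartments",
    "mean_intensity",
    "measure_cell",
    "measure_image",
    "classify",
    "dispersal_episodes",
    "measure_timeseries",
    "measurements_to_frame",
    "write_measurements",
    "read_measurements",
]

MEMBRANE = "membrane"
CYTOSOLIC = "cytosolic"

_8CONN = np.ones((3, 3), dtype=bool)


@dataclass
class CompartmentParams:
    """Parameters of the compartment split and classification.

    ``background_mode="constant"`` subtracts ``background_value`` from both
    compartment means before the ratio (use when the imaging background is
    known, e.g. simulated data); ``"none"`` uses raw means.
    """

    ring_width_px: int = 4
    background_mode: str = "none"  # {none, constant}
    background_value: float = 0.0
    threshold: float = 0.7
    saturation_level: float | None = None

    def __post_init__(self):
        if self.ring_width_px < 1:
            raise MemlocError("invalid_params", "ring_width_px must be >= 1")
        if self.threshold <= 0:
            raise MemlocError("invalid_params", "threshold must be > 0")
        if self.background_mode not in ("none", "constant"):
            raise MemlocError("invalid_params",
                              f"unknown background_mode '{self.background_mode}'")


@dataclass
class CompartmentMasks:
    """Exact partition of a cell mask into membrane ring and cytosol interior."""

    membrane: np.ndarray
    cytosol: np.ndarray


@dataclass
class CellMeasurement:
    """Per-cell record; ``ratio`` and ``label`` are None when unmeasurable."""

    cell_id: str
    mean_membrane: float | None
    mean_cytosol: float | None
    ratio: float | None
    length_um: float
    label: str | None  # {membrane, cytosolic} or None
    flags: set = field(default_factory=set)
    frame: int | None = None

    @property
    def valid(self) -> bool:
        return not self.flags and self.ratio is not None


@dataclass(frozen=True)
class DispersalEpisode:
    """A maximal run of consecutive cytosolic-classified frames."""

    onset_time_min: float
    duration_min: float
    frame_span: tuple[int, int]  # (first, last), inclusive


# ---------------------------------------------------------------------------
# Compartment masks
# ---------------------------------------------------------------------------

def membrane_ring(mask: np.ndarray, ring_width_px: int = 4) -> np.ndarray:
    """Mask pixels with Chebyshev distance <= ring_width_px to the exterior.

    Implemented as ``ring_width_px`` successive erosions with the 3x3
    (8-connected) structuring element; pixels beyond the image edge count
    as exterior.  ``ring_width_px = 0`` returns an empty ring; for thin
    cells the ring may be the entire mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if ring_width_px <= 0:
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=_8CONN,
                                    iterations=ring_width_px, border_value=0)
    return mask & ~eroded


def cytosol_interior(mask: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Cell mask minus the membrane ring; raises ``cell_too_thin`` if empty."""
    mask = np.asarray(mask, dtype=bool)
    ring = np.asarray(ring, dtype=bool)
    if np.any(ring & ~mask):
        raise MemlocError("invalid_params", "ring is not a subset of the mask")
    interior = mask & ~ring
    if not interior.any():
        raise MemlocError("cell_too_thin",
                          "ring swallows the whole cell; no cytosol left")
    return interior


def split_compartments(mask: np.ndarray, ring_width_px: int = 4) -> CompartmentMasks:
    """Partition a cell mask into ring and interior (membrane U cytosol = mask)."""
    ring = membrane_ring(mask, ring_width_px)
    return CompartmentMasks(ring, cytosol_interior(mask, ring))


# ---------------------------------------------------------------------------
# Intensities and classification
# ---------------------------------------------------------------------------

def mean_intensity(image: np.ndarray, mask: np.ndarray,
                   params: CompartmentParams | None = None) -> float:
    """Mean image value over the mask, after any background subtraction."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MemlocError("empty_compartment", "mask selects no pixels")
    m = float(np.asarray(image, dtype=float)[mask].mean())
    if params is not None and params.background_mode == "constant":
        m -= params.background_value
    return m


def classify(ratio: float, threshold: float = 0.7) -> str:
    """Strictly above the threshold -> membrane; at or below -> cytosolic."""
    return MEMBRANE if ratio > threshold else CYTOSOLIC


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any()
                or mask[:, 0].any() or mask[:, -1].any())


def measure_cell(image: np.ndarray, outline: CellOutline,
                 params: CompartmentParams, pixel_size_um: float = 1.0,
                 frame: int | None = None) -> CellMeasurement:
    """Full per-cell quantification: rasterize, split, means, ratio, class.

    Unmeasurable cells are returned flagged (``too_thin`` when the ring
    swallows the interior, ``border`` when the mask touches the image edge,
    ``undefined_ratio`` when the background-subtracted cytosol mean is not
    positive) rather than dropped; flagged cells are excluded from
    population summaries downstream.
    """
    image = np.asarray(image, dtype=float)
    mask = rasterize(outline, image.shape)
    length = cell_length(outline, pixel_size_um)
    flags: set = set()
    if _touches_border(mask):
        flags.add("border")
    if params.saturation_level is not None and \
            np.any(image[mask] >= params.saturation_level):
        flags.add("saturated")
    ring = membrane_ring(mask, params.ring_width_px)
    try:
        interior = cytosol_interior(mask, ring)
    except MemlocError:
        flags.add("too_thin")
        return CellMeasurement(outline.id, None, None, None, length, None,
                               flags, frame)
    mean_m = mean_intensity(image, ring, params)
    mean_c = mean_intensity(image, interior, params)
    if mean_c <= 0:
        flags.add("undefined_ratio")
        return CellMeasurement(outline.id, mean_m, mean_c, None, length, None,
                               flags, frame)
    ratio = mean_m / mean_c
    return CellMeasurement(outline.id, mean_m, mean_c, ratio, length,
                           classify(ratio, params.threshold), flags, frame)


def measure_image(image: np.ndarray, outlines: Sequence[CellOutline],
                  params: CompartmentParams, pixel_size_um: float = 1.0,
                  frame: int | None = None) -> list[CellMeasurement]:
    """Quantify every outline against one image."""
    return [measure_cell(image, o, params, pixel_size_um, frame)
            for o in outlines]


# ---------------------------------------------------------------------------
# Time-lapse
# ---------------------------------------------------------------------------

def dispersal_episodes(ratios: Sequence[float | None],
                       frame_interval_min: float,
                       threshold: float = 0.7,
                       min_frames: int = 2) -> list[DispersalEpisode]:
    """Detect dispersal episodes in a per-frame ratio trace.

    An episode is a maximal run of >= ``min_frames`` consecutive frames
    classified cytosolic (ratio <= threshold).  ``None`` entries (missing
    or unmeasurable frames) break runs.  Onset is the first frame of the
    run times the frame interval; duration is the run length times the
    interval.
    """
    episodes: list[DispersalEpisode] = []
    start = None
    n = len(ratios)
    for i in range(n + 1):
        cyto = (i < n and ratios[i] is not None
                and classify(ratios[i], threshold) == CYTOSOLIC)
        if cyto and start is None:
            start = i
        elif not cyto and start is not None:
            run = i - start
            if run >= min_frames:
                episodes.append(DispersalEpisode(
                    onset_time_min=start * frame_interval_min,
                    duration_min=run * frame_interval_min,
                    frame_span=(start, i - 1)))
            start = None
    return episodes


def measure_timeseries(frames: Sequence[np.ndarray],
                       outlines_per_frame: Sequence[Sequence[CellOutline]],
                       params: CompartmentParams,
                       frame_interval_min: float,
                       pixel_size_um: float = 1.0
                       ) -> tuple[list[CellMeasurement],
                                  dict[str, list[DispersalEpisode]]]:
    """Quantify an id-tracked time lapse and detect per-cell dispersal.

    Outlines must share cell ids across frames (tracking is the caller's
    responsibility).  A cell missing from a frame, or unmeasurable in it,
    contributes a ``None`` ratio for that frame, which breaks episode runs;
    such cells carry a ``gap`` flag on their measured records.
    """
    if len(frames) != len(outlines_per_frame):
        raise MemlocError("invalid_params",
                          "one outline set per frame is required")
    measurements: list[CellMeasurement] = []
    traces: dict[str, dict[int, float | None]] = {}
    for fi, (img, outs) in enumerate(zip(frames, outlines_per_frame)):
        for m in measure_image(img, outs, params, pixel_size_um, frame=fi):
            measurements.append(m)
            traces.setdefault(m.cell_id, {})[fi] = m.ratio
    n_frames = len(frames)
    episodes: dict[str, list[DispersalEpisode]] = {}
    gappy = {cid for cid, tr in traces.items()
             if len(tr) < n_frames or any(v is None for v in tr.values())}
    for m in measurements:
        if m.cell_id in gappy:
            m.flags.add("gap")
    for cid, tr in traces.items():
        full = [tr.get(fi) for fi in range(n_frames)]
        episodes[cid] = dispersal_episodes(full, frame_interval_min,
                                           params.threshold)
    return measurements, episodes


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["cell_id", "frame", "length_um", "mean_membrane",
                "mean_cytosol", "ratio", "class", "flags"]


def measurements_to_frame(measurements: Sequence[CellMeasurement]) -> pd.DataFrame:
    """Measurements as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame([{
        "cell_id": m.cell_id,
        "frame": 0 if m.frame is None else m.frame,
        "length_um": m.length_um,
        "mean_membrane": m.mean_membrane,
        "mean_cytosol": m.mean_cytosol,
        "ratio": m.ratio,
        "class": m.label if m.label is not None else "",
        "flags": ";".join(sorted(m.flags)),
    } for m in measurements], columns=_CSV_COLUMNS)


def write_measurements(measurements: Sequence[CellMeasurement],
                       path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False,
                                               float_format="%.6f")


def read_measurements(path: str | Path) -> list[CellMeasurement]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = []
    for _, row in df.iterrows():
        flags = set(str(row["flags"]).split(";")) - {"", "nan"} \
            if not pd.isna(row["flags"]) else set()
        ratio = None if pd.isna(row["ratio"]) else float(row["ratio"])
        out.append(CellMeasurement(
            cell_id=str(row["cell_id"]),
            mean_membrane=None if pd.isna(row["mean_membrane"])
            else float(row["mean_membrane"]),
            mean_cytosol=None if pd.isna(row["mean_cytosol"])
            else float(row["mean_cytosol"]),
            ratio=ratio,
            length_um=float(row["length_um"]),
            label=str(row["class"]) if row["class"] else None,
            flags=flags,
            frame=int(row["frame"]),
        ))
    return out
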