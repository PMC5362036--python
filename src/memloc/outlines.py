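"""Cell outlines: data model, JSON I/O, rasterization, length, segmentation.

A cell outline is a closed simple polygon in continuous image coordinates
(x = column, y = row, 0-based, pixel centers at integer coordinates); it is
the unit of quantification downstream.  Outlines normally come from the
synthetic-data generator's ground truth; a minimal intensity-based segmenter
is provided as a stand-in for dedicated phase-contrast segmentation tools.

JSON schema (one frame)::

    {"pixel_size_um": 0.066, "frame": 0,
     "cells": [{"id": "c1", "vertices": [[x, y], ...]}, ...]}

A time-lapse file is a JSON list of such documents, ordered by frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import MemlocError

__all__ = [
    "CellOutline",
    "read_outlines",
    "write_outlines",
    "read_outline_document",
    "read_timelapse_outlines",
    "write_timelapse_outlines",
    "rasterize",
    "cell_length",
    "segment_stand_in",
]


@dataclass
class CellOutline:
    """Closed polygon (implicitly closed: last vertex connects to first)."""

    id: str
    vertices: np.ndarray = field(repr=False)  # (n, 2) float64, columns (x, y)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise MemlocError(
                "invalid_outline_file",
                f"cell '{self.id}': outline needs >= 3 (x, y) vertices",
            )
        # drop an explicit closing vertex so the implicit-closure convention holds
        if np.allclose(v[0], v[-1]) and v.shape[0] > 3:
            v = v[:-1]
        self.vertices = v

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def validate(self) -> None:
        """Raise ``invalid_outline_file`` if not simple with positive area."""
        poly = self.polygon()
        if (not poly.is_valid) or poly.area <= 0:
            raise MemlocError(
                "invalid_outline_file",
                f"cell '{self.id}': polygon is self-intersecting or has zero area",
            )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _document(outlines: Sequence[CellOutline], pixel_size_um: float,
              frame: int | None) -> dict:
    doc = {
        "pixel_size_um": float(pixel_size_um),
        "cells": [
            {"id": o.id, "vertices": [[round(float(x), 6), round(float(y), 6)]
                                      for x, y in o.vertices]}
            for o in outlines
        ],
    }
    if frame is not None:
        doc["frame"] = int(frame)
    return doc


def _parse_document(doc: dict, source: str = "") -> tuple[list[CellOutline], float]:
    if not isinstance(doc, dict) or "cells" not in doc:
        raise MemlocError("invalid_outline_file",
                          f"{source}: missing 'cells' key")
    seen: set[str] = set()
    outlines = []
    for cell in doc["cells"]:
        cid = str(cell["id"])
        if cid in seen:
            raise MemlocError("invalid_outline_file",
                              f"duplicate cell id '{cid}'")
        seen.add(cid)
        o = CellOutline(cid, np.asarray(cell["vertices"], dtype=float))
        o.validate()
        outlines.append(o)
    return outlines, float(doc.get("pixel_size_um", 1.0))


def write_outlines(outlines: Sequence[CellOutline], path: str | Path,
                   pixel_size_um: float = 1.0, frame: int | None = None) -> None:
    """Write one frame of outlines as JSON (vertices rounded to 6 decimals)."""
    ids = [o.id for o in outlines]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise MemlocError("invalid_outline_file", f"duplicate cell id '{dup}'")
    for o in outlines:
        o.validate()
    Path(path).write_text(
        json.dumps(_document(outlines, pixel_size_um, frame), indent=1))


def read_outlines(path: str | Path) -> list[CellOutline]:
    """Read a single-frame outline file; validates ids and polygon simplicity."""
    return read_outline_document(path)[0]


def read_outline_document(path: str | Path) -> tuple[list[CellOutline], float]:
    """Read one frame, returning ``(outlines, pixel_size_um)``."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MemlocError("invalid_outline_file",
                          f"{path}: malformed JSON ({exc})") from exc
    return _parse_document(doc, str(path))


def write_timelapse_outlines(frames: Sequence[Sequence[CellOutline]],
                             path: str | Path,
                             pixel_size_um: float = 1.0) -> None:
    docs = [_document(frame, pixel_size_um, i) for i, frame in enumerate(frames)]
    for frame in frames:
        for o in frame:
            o.validate()
    Path(path).write_text(json.dumps(docs, indent=1))


def read_timelapse_outlines(path: str | Path) -> tuple[list[list[CellOutline]], float]:
    """Read a multi-frame outline file: JSON list of per-frame documents."""
    try:
        docs = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise MemlocError("invalid_outline_file",
                          f"{path}: malformed JSON ({exc})") from exc
    if isinstance(docs, dict):  # single frame written with write_outlines
        docs = [docs]
    frames = []
    px = 1.0
    for doc in sorted(docs, key=lambda d: d.get("frame", 0)):
        outlines, px = _parse_document(doc, str(path))
        frames.append(outlines)
    return frames, px


# ---------------------------------------------------------------------------
# Rasterization and geometry
# ---------------------------------------------------------------------------

def rasterize(outline: CellOutline, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose *center* lies inside or on the polygon.

    Boundary-inclusive: a pixel center exactly on an edge or vertex belongs
    to the mask.  Raises ``outline_out_of_bounds`` if the polygon extends
    past the pixel-area extent ``[-0.5, cols-0.5] x [-0.5, rows-0.5]``.
    """
    rows, cols = shape
    poly = outline.polygon()
    minx, miny, maxx, maxy = poly.bounds
    eps = 1e-9
    if minx < -0.5 - eps or miny < -0.5 - eps or \
            maxx > cols - 0.5 + eps or maxy > rows - 0.5 + eps:
        raise MemlocError("outline_out_of_bounds",
                          f"cell '{outline.id}' extends outside a {rows}x{cols} image")
    x0 = max(0, int(np.floor(minx)))
    x1 = min(cols - 1, int(np.ceil(maxx)))
    y0 = max(0, int(np.floor(miny)))
    y1 = min(rows - 1, int(np.ceil(maxy)))
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.covers(poly, pts).reshape(xs.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1 + 1, x0:x1 + 1] = inside
    return mask


def cell_length(outline: CellOutline, pixel_size_um: float = 1.0) -> float:
    """Cell length as the maximum pairwise vertex distance (Feret diameter).

    For a near-straight rod this equals the pole-to-pole length; it is
    returned in micrometres (``pixel_size_um = 1`` gives pixel units).
    """
    v = outline.vertices
    if len(v) > 12:
        v = v[ConvexHull(v).vertices]
    return float(pdist(v).max() * pixel_size_um)


# ---------------------------------------------------------------------------
# Stand-in segmenter
# ---------------------------------------------------------------------------

def segment_stand_in(image: np.ndarray, sigma: float = 2.0,
                     min_area: int = 50, max_vertices: int = 200) -> list[CellOutline]:
    """Simple intensity segmenter for synthetic fluorescence images.

    Gaussian smooth -> global Otsu threshold -> 8-connected labelling ->
    discard components below ``min_area`` -> trace each component's outer
    boundary as a polygon.  Intended only as a stand-in on synthetic data;
    it makes no attempt at sub-pixel accuracy or cell splitting.
    """
    img = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    if smooth.max() <= smooth.min():
        return []
    thresh = threshold_otsu(smooth)
    binary = smooth > thresh
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    outlines: list[CellOutline] = []
    k = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_area:
            continue
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary is the longest
        # (row, col) in padded frame -> (x, y) in image frame
        verts = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) > max_vertices:
            step = int(np.ceil(len(verts) / max_vertices))
            verts = verts[::step]
        if len(verts) < 3:
            continue
        k += 1
        o = CellOutline(f"cell_{k:04d}", verts)
        try:
            o.validate()
        except MemlocError:
            # rare staircase self-touch: fall back to the convex hull
            o = CellOutline(f"cell_{k:04d}", verts[ConvexHull(verts).vertices])
        outlines.append(o)
    return outlines
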