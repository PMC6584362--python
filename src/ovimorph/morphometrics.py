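"""Per-cell and per-plate morphometrics for segmented epithelia.

The quantities computed here are the cellular parameters used to describe
an ovipositor plate: apical cell area *a*, the moment-equivalent ellipse of
each cell (short axis *l1*, long axis *l2*, shape ratio ``s = l2/l1``),
the axial orientation of the long axis relative to the proximo-distal (PD)
axis, the density-corrected total cell count *N*, the mean number of cells
per row *n* and per column *m*, and the tissue anisotropy ``sigma = n/m``.

Conventions
-----------
* Coordinates are continuous micrometres in a right-handed frame.
* The PD axis is a per-plate unit vector (``(1, 0)`` by default); rows run
  along PD, columns along the orthogonal dorso-ventral (DV) axis.
* All orientations are axial (headless), reported in degrees in [0, 180).
* Counts are kept as real numbers; rounding is left to report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

from .errors import GeometryError, ParameterError

__all__ = [
    "CellPolygon",
    "CellMetrics",
    "TissuePlate",
    "TissueSummary",
    "polygon_area",
    "fit_ellipse",
    "classify_alignment",
    "corrected_total_count",
    "transect_counts",
    "summarize_plate",
    "cell_metrics",
    "cell_density",
]

#: Acute-angle threshold (degrees) below which a cell counts as PD-aligned.
ALIGNMENT_THRESHOLD_DEG = 45.0

#: Default fractional positions of the three row/column transects.
DEFAULT_TRANSECT_FRACTIONS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class CellPolygon:
    """One segmented apical cell outline.

    Parameters
    ----------
    cell_id:
        Identity of the cell (stable within a plate).
    vertices:
        ``(k, 2)`` array of ring vertices in micrometres, ordered along a
        simple (non self-intersecting) closed ring; the closing edge is
        implicit.
    """

    cell_id: int
    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError(
                f"cell {self.cell_id}: need >=3 planar vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    def shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def centroid(self) -> np.ndarray:
        _, c, _ = _polygon_moments(self.vertices)
        return c


@dataclass(frozen=True)
class CellMetrics:
    """Derived per-cell quantities (areas in um^2, axes in um)."""

    cell_id: int
    area: float
    short_axis: float
    long_axis: float
    shape_ratio: float
    orientation: float  # axial degrees from the PD axis, in [0, 180)
    aligned: bool


@dataclass(frozen=True)
class TissuePlate:
    """A plate's segmented cells plus its axis convention.

    ``total_area`` is the demarcated plate area; it defaults to the summed
    segmented area (fully segmented plate). ``segmented_area`` may not
    exceed ``total_area`` beyond a 0.5% slack.
    """

    cells: tuple[CellPolygon, ...]
    pd_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    total_area: float | None = None

    def __post_init__(self):
        cells = tuple(self.cells)
        axis = np.asarray(self.pd_axis, dtype=float)
        norm = float(np.hypot(*axis))
        if norm == 0.0:
            raise ParameterError("pd_axis must be nonzero")
        object.__setattr__(self, "cells", cells)
        object.__setattr__(self, "pd_axis", axis / norm)
        seg = sum(polygon_area(c) for c in cells)
        total = self.total_area if self.total_area is not None else seg
        if seg > total * 1.005:
            raise ParameterError(
                f"segmented area {seg:.4g} exceeds total area {total:.4g}"
            )
        object.__setattr__(self, "total_area", float(total))

    @property
    def segmented_area(self) -> float:
        return sum(polygon_area(c) for c in self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class TissueSummary:
    """Plate-level summary: the parameters of the length model plus the
    orientation statistics."""

    n_total: float  # density-corrected total cell count N
    cells_per_row: float  # mean n over three PD transects
    cells_per_column: float  # mean m over three DV transects
    anisotropy: float  # sigma = cells_per_row / cells_per_column
    mean_area: float  # um^2
    mean_shape: float  # mean s = l2/l1
    aligned_fraction: float


# ---------------------------------------------------------------------------
# exact polygon moments (Green's theorem over the interior)

def _polygon_moments(vertices: np.ndarray):
    """Signed area, centroid and second central moments of a simple ring.

    Returns ``(area, centroid, cov)`` where ``cov`` is the per-unit-area
    covariance of the uniform measure on the polygon interior. Area is
    returned positive regardless of ring orientation.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-300:
        raise GeometryError("degenerate polygon: zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    # second moments about the origin
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    mxx = ixx / area - cx * cx
    myy = iyy / area - cy * cy
    mxy = ixy / area - cx * cy
    return abs(area), np.array([cx, cy]), np.array([[mxx, mxy], [mxy, myy]])


def polygon_area(polygon: CellPolygon | np.ndarray) -> float:
    """Exact area of a simple polygon (surveyor's formula), um^2.

    Orientation-independent and exact in floating point up to rounding.
    """
    verts = polygon.vertices if isinstance(polygon, CellPolygon) else polygon
    area, _, _ = _polygon_moments(verts)
    return float(area)


def _axis_angle_deg(axis: Sequence[float]) -> float:
    a = np.asarray(axis, dtype=float)
    return math.degrees(math.atan2(a[1], a[0]))


def fit_ellipse(
    polygon: CellPolygon | np.ndarray,
    pd_axis: Sequence[float] = (1.0, 0.0),
) -> tuple[float, float, float]:
    """Moment-equivalent ellipse of a polygon: ``(l1, l2, orientation)``.

    The ellipse shares the polygon's exact second central area moments
    (computed over the interior, not the vertex scatter): a uniform ellipse
    with full axes ``l = 4 sqrt(lambda)`` for each covariance eigenvalue
    ``lambda`` reproduces them. ``l2 >= l1``; the orientation is the axial
    angle (degrees, [0, 180)) of the long axis measured from ``pd_axis``.
    For a polygon that is itself an ellipse this recovers its axes and, with
    them, its area.
    """
    verts = polygon.vertices if isinstance(polygon, CellPolygon) else polygon
    _, _, cov = _polygon_moments(verts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise GeometryError("degenerate polygon: collinear vertices")
    l1 = 4.0 * math.sqrt(evals[0])
    l2 = 4.0 * math.sqrt(evals[1])
    major = evecs[:, 1]
    theta = _axis_angle_deg(major) - _axis_angle_deg(pd_axis)
    return l1, l2, theta % 180.0


def classify_alignment(
    orientation_deg: float, threshold_deg: float = ALIGNMENT_THRESHOLD_DEG
) -> bool:
    """True iff the acute angle between the long axis and PD is < threshold.

    The boundary (exactly ``threshold_deg``) counts as non-aligned.
    """
    theta = orientation_deg % 180.0
    acute = min(theta, 180.0 - theta)
    return acute < threshold_deg


def cell_metrics(
    cell: CellPolygon,
    pd_axis: Sequence[float] = (1.0, 0.0),
    threshold_deg: float = ALIGNMENT_THRESHOLD_DEG,
) -> CellMetrics:
    """All per-cell quantities in one pass."""
    area = polygon_area(cell)
    l1, l2, theta = fit_ellipse(cell, pd_axis)
    return CellMetrics(
        cell_id=cell.cell_id,
        area=area,
        short_axis=l1,
        long_axis=l2,
        shape_ratio=l2 / l1,
        orientation=theta,
        aligned=classify_alignment(theta, threshold_deg),
    )


def corrected_total_count(
    n_segmented: float, segmented_area: float, total_area: float
) -> float:
    """Density-corrected total cell count.

    The raw segmented count is extrapolated into the un-segmented remainder
    of the plate at the mean segmented density:
    ``N = n + (A_total - A_seg) * n / A_seg``.
    """
    if segmented_area <= 0:
        raise ParameterError("segmented_area must be positive")
    if total_area < segmented_area:
        raise ParameterError("total_area must be >= segmented_area")
    return n_segmented + (total_area - segmented_area) * (n_segmented / segmented_area)


def cell_density(n_cells: float, area: float) -> float:
    """Cells per um^2: ``n / area``. Inverse of count = density * area."""
    if area <= 0:
        raise ParameterError("area must be positive")
    return n_cells / area


def _pd_frame(plate: TissuePlate) -> np.ndarray:
    """Rotation taking plate coordinates into the frame with PD along +x."""
    ux, uy = plate.pd_axis
    return np.array([[ux, uy], [-uy, ux]])


def transect_counts(
    plate: TissuePlate,
    axis: str,
    fractions: Sequence[float] = DEFAULT_TRANSECT_FRACTIONS,
    min_chord_frac: float = 0.15,
) -> float:
    """Mean cell count over three transect lines across the plate.

    ``axis='row'`` counts cells along lines parallel to PD placed at
    fractional positions of the plate's DV extent (dorsal/medial/ventral);
    ``axis='column'`` uses lines parallel to DV across the PD extent.
    Each line is snapped to the nearest cell-centroid coordinate so that it
    runs through a genuine row (column) of cells rather than grazing the
    shared vertices of a regular tessellation, and a cell counts if the
    line crosses its interior with a chord longer than ``min_chord_frac``
    of the typical cell diameter ``sqrt(mean area)`` — grazing contacts at
    cell junctions do not count as row/column membership.
    """
    if axis not in ("row", "column"):
        raise ParameterError(f"axis must be 'row' or 'column', got {axis!r}")
    if plate.n_cells == 0:
        raise ParameterError("plate has no cells")
    if not all(0.0 < f < 1.0 for f in fractions):
        raise ParameterError("transect fractions must lie strictly inside (0, 1)")

    rot = _pd_frame(plate)
    polys = [Polygon(c.vertices @ rot.T) for c in plate.cells]
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    allxy = np.vstack([np.asarray(p.exterior.coords) for p in polys])
    (xmin, ymin), (xmax, ymax) = allxy.min(axis=0), allxy.max(axis=0)

    # rows: horizontal lines, position along y; columns: vertical, along x
    if axis == "row":
        lo, hi, coord = ymin, ymax, cents[:, 1]
    else:
        lo, hi, coord = xmin, xmax, cents[:, 0]
    extent = hi - lo
    nudge = 1e-9 * max(extent, 1.0)
    mean_area = float(np.mean([p.area for p in polys]))
    min_chord = max(1e-9, min_chord_frac * math.sqrt(mean_area))

    tree = STRtree(polys)
    counts = []
    for f in fractions:
        pos = lo + f * extent
        pos = coord[np.argmin(np.abs(coord - pos))] + nudge
        if axis == "row":
            line = LineString([(xmin - extent, pos), (xmax + extent, pos)])
        else:
            line = LineString([(pos, ymin - extent), (pos, ymax + extent)])
        hits = 0
        for idx in tree.query(line):
            if line.intersection(polys[idx]).length > min_chord:
                hits += 1
        counts.append(hits)
    return float(np.mean(counts))


def summarize_plate(
    plate: TissuePlate,
    fractions: Sequence[float] = DEFAULT_TRANSECT_FRACTIONS,
    threshold_deg: float = ALIGNMENT_THRESHOLD_DEG,
) -> TissueSummary:
    """Full plate summary: N, n, m, sigma, mean a, mean s, aligned fraction."""
    if plate.n_cells == 0:
        raise ParameterError("plate has no cells")
    metrics = [cell_metrics(c, plate.pd_axis, threshold_deg) for c in plate.cells]
    seg = plate.segmented_area
    n_total = corrected_total_count(plate.n_cells, seg, plate.total_area)
    n_row = transect_counts(plate, "row", fractions)
    n_col = transect_counts(plate, "column", fractions)
    return TissueSummary(
        n_total=n_total,
        cells_per_row=n_row,
        cells_per_column=n_col,
        anisotropy=n_row / n_col,
        mean_area=float(np.mean([m.area for m in metrics])),
        mean_shape=float(np.mean([m.shape_ratio for m in metrics])),
        aligned_fraction=float(np.mean([m.aligned for m in metrics])),
    )
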