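"""Readers and writers for the package's on-disk formats.

All tabular formats are UTF-8 CSV with fixed column order; nested
summaries are JSON. Labeled masks are 16-bit TIFFs with background 0 and
one positive label per cell (multi-page for movies). Mask pixels are
converted to micrometres at read time: pixel (0, 0) is the image top-left
and the y axis is flipped into a right-handed frame, so downstream code
sees a single continuous-coordinate convention.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from .errors import FormatError, ParameterError
from .intercalation import NematicSummary, T1Event
from .morphometrics import CellPolygon, TissuePlate, TissueSummary, cell_metrics

__all__ = [
    "RunConfig",
    "write_polygon_csv",
    "read_polygon_csv",
    "write_labeled_mask",
    "read_labeled_mask",
    "write_mask_stack",
    "read_mask_stack",
    "write_tracking_csv",
    "read_tracking_csv",
    "write_metrics_csv",
    "write_summary_json",
    "read_summary_json",
    "write_events_csv",
    "read_events_csv",
    "write_nematic_json",
    "write_provenance",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the pipeline stages."""

    pixel_size: float = 1.0  # um per pixel
    pd_axis_deg: float = 0.0  # PD direction in the image frame, degrees
    transect_fractions: tuple[float, float, float] = (0.25, 0.5, 0.75)
    alignment_threshold: float = 45.0  # degrees
    confidence: float = 0.95
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if not all(0.0 < f < 1.0 for f in self.transect_fractions):
            raise ParameterError("transect fractions must lie in (0, 1)")
        if not 0.0 < self.alignment_threshold <= 90.0:
            raise ParameterError("alignment_threshold must lie in (0, 90]")

    def pd_axis(self) -> tuple[float, float]:
        rad = np.radians(self.pd_axis_deg)
        return (float(np.cos(rad)), float(np.sin(rad)))


# ---------------------------------------------------------------------------
# polygons

def write_polygon_csv(
    plates: Mapping[object, TissuePlate] | TissuePlate, path
) -> None:
    """Columns: plate_id, cell_id, vertex_index, x_um, y_um."""
    if isinstance(plates, TissuePlate):
        plates = {0: plates}
    rows = []
    for plate_id, plate in plates.items():
        for cell in plate.cells:
            for k, (x, y) in enumerate(cell.vertices):
                rows.append((plate_id, cell.cell_id, k, x, y))
    pd.DataFrame(
        rows, columns=["plate_id", "cell_id", "vertex_index", "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_polygon_csv(path, pd_axis=(1.0, 0.0)) -> dict[object, TissuePlate]:
    df = pd.read_csv(path)
    required = {"plate_id", "cell_id", "vertex_index", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise FormatError(f"polygon CSV must have columns {sorted(required)}")
    plates = {}
    for plate_id, sub in df.groupby("plate_id", sort=True):
        cells = []
        for cell_id, ring in sub.groupby("cell_id", sort=True):
            ring = ring.sort_values("vertex_index")
            cells.append(CellPolygon(int(cell_id), ring[["x_um", "y_um"]].to_numpy()))
        plates[plate_id] = TissuePlate(cells=tuple(cells), pd_axis=pd_axis)
    return plates


# ---------------------------------------------------------------------------
# labeled masks

def write_labeled_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def write_mask_stack(masks: Sequence[np.ndarray], path) -> None:
    stack = np.stack([np.asarray(m, dtype=np.uint16) for m in masks])
    tifffile.imwrite(path, stack)


def _mask_to_plate(mask: np.ndarray, pixel_size: float, pd_axis) -> TissuePlate:
    if not np.issubdtype(mask.dtype, np.integer):
        raise FormatError(f"labeled mask must be integer-typed, got {mask.dtype}")
    height = mask.shape[0]
    cells = []
    for label in np.unique(mask):
        if label == 0:
            continue
        binary = mask == label
        n_blobs = measure.label(binary, connectivity=1).max()
        if n_blobs != 1:
            raise FormatError(
                f"label {int(label)} appears as {n_blobs} disconnected regions"
            )
        padded = np.pad(binary.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        outer = max(contours, key=len)  # outer contour; holes ignored
        rows = outer[:, 0] - 1.0
        cols = outer[:, 1] - 1.0
        verts = np.column_stack([cols * pixel_size, (height - rows) * pixel_size])
        cells.append(CellPolygon(int(label), verts[:-1]))
    return TissuePlate(cells=tuple(cells), pd_axis=pd_axis)


def read_labeled_mask(path, pixel_size: float, pd_axis=(1.0, 0.0)) -> TissuePlate:
    """One polygon per positive label (outer contour, converted to um)."""
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise FormatError(f"expected a single-page labeled mask, got shape {mask.shape}")
    return _mask_to_plate(mask, pixel_size, pd_axis)


def read_mask_stack(path, pixel_size: float, pd_axis=(1.0, 0.0)) -> list[TissuePlate]:
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return [_mask_to_plate(frame, pixel_size, pd_axis) for frame in stack]


# ---------------------------------------------------------------------------
# tracking

def write_tracking_csv(identity_map: Mapping[tuple[int, int], int], path) -> None:
    """Columns: frame, cell_label, track_id."""
    rows = sorted((f, lbl, tid) for (f, lbl), tid in identity_map.items())
    pd.DataFrame(rows, columns=["frame", "cell_label", "track_id"]).to_csv(
        path, index=False
    )


def read_tracking_csv(path) -> dict[tuple[int, int], int]:
    df = pd.read_csv(path)
    required = {"frame", "cell_label", "track_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"tracking CSV must have columns {sorted(required)}")
    return {
        (int(r.frame), int(r.cell_label)): int(r.track_id)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# derived tables and summaries

def write_metrics_csv(plate: TissuePlate, path, threshold_deg: float = 45.0) -> None:
    """Per-cell metrics: cell_id, area_um2, l1_um, l2_um, shape_ratio,
    orientation_deg, aligned."""
    rows = []
    for cell in plate.cells:
        m = cell_metrics(cell, plate.pd_axis, threshold_deg)
        rows.append((m.cell_id, m.area, m.short_axis, m.long_axis,
                     m.shape_ratio, m.orientation, m.aligned))
    pd.DataFrame(rows, columns=[
        "cell_id", "area_um2", "l1_um", "l2_um", "shape_ratio",
        "orientation_deg", "aligned",
    ]).to_csv(path, index=False)


def write_summary_json(summary: TissueSummary, path) -> None:
    Path(path).write_text(json.dumps(asdict(summary), indent=2, sort_keys=True))


def read_summary_json(path) -> TissueSummary:
    return TissueSummary(**json.loads(Path(path).read_text()))


def write_events_csv(events: Sequence[T1Event], path) -> None:
    """Columns: frame, cell_a, cell_b, cell_c, cell_d, conv_deg, div_deg, stable."""
    rows = [
        (e.frame, *e.quartet, e.convergence_angle, e.divergence_angle, e.stable)
        for e in events
    ]
    pd.DataFrame(rows, columns=[
        "frame", "cell_a", "cell_b", "cell_c", "cell_d",
        "conv_deg", "div_deg", "stable",
    ]).to_csv(path, index=False)


def read_events_csv(path) -> list[T1Event]:
    df = pd.read_csv(path)
    return [
        T1Event(
            quartet=(int(r.cell_a), int(r.cell_b), int(r.cell_c), int(r.cell_d)),
            frame=int(r.frame),
            convergence_angle=float(r.conv_deg),
            divergence_angle=float(r.div_deg),
            stable=bool(r.stable),
        )
        for r in df.itertuples()
    ]


def write_nematic_json(summary: NematicSummary, path) -> None:
    Path(path).write_text(json.dumps(asdict(summary), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# provenance

def write_provenance(path, *, command: str, inputs: Mapping, config: Mapping) -> None:
    """Reproducibility record: inputs, config and a stable config hash."""
    payload = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": {k: config[k] for k in sorted(config)},
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_hash"] = digest
    from . import __version__

    payload["version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
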