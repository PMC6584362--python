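"""Synthetic epithelial tissue with known ground truth.

Everything downstream (morphometrics, intercalation statistics, allometry,
the length model) is exercised on tissues generated here, so real images
are never required. The generator produces:

* near-hexagonal tessellations with controllable cell number, mean apical
  area, shape ratio and PD-aligned fraction (:func:`generate_hex_plate`);
* growth series with scheduled area expansion and row/column count changes
  (:func:`generate_growth_series`);
* tracked frame series containing scripted stable and oscillating T1
  neighbor exchanges (:func:`generate_tracked_series`);
* two-group log-log allometry tables (:func:`generate_allometry_dataset`);
* labeled raster masks bridging polygon ground truth to the mask reader
  (:func:`rasterize_plate`).

Tessellation construction
-------------------------
Cells are hexagons arranged in ``m`` brick-offset rows of ``n`` cells.
Each hexagon has two vertical edges (length ``e``, per row), a fixed width
``w`` and zigzag caps of amplitude ``delta``; rows share a single vertex
pool, so the tiling is exact by construction and stays exact under vertex
jitter. A row is drawn "PD-aligned" with probability ``aligned_fraction``;
its vertical-edge length is solved so the row's hexagons have second-moment
ratio ``s`` along the PD axis (aligned) or the DV axis (non-aligned). One
global isotropic rescale pins the realized mean cell area to ``cell_area``.

All randomness flows from the integer ``seed`` of the spec/schedule/script;
identical inputs give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Polygon
from skimage.draw import polygon as _draw_polygon

from .errors import GeometryError, ParameterError
from .intercalation import T1Event, TrackedTissue, event_angles
from .morphometrics import CellPolygon, TissuePlate, _polygon_moments

__all__ = [
    "PlateSpec",
    "GrowthPhase",
    "GrowthSchedule",
    "GrowthSeries",
    "T1Script",
    "generate_hex_plate",
    "generate_growth_series",
    "generate_tracked_series",
    "generate_allometry_dataset",
    "rasterize_plate",
    "sample_axial_angles",
    "MEL_54H_PLATE",
]


@dataclass(frozen=True)
class PlateSpec:
    """Ground-truth parameters of one synthetic plate.

    ``n_per_row`` cells along PD x ``m_per_column`` cells along DV;
    ``cell_area`` is the target mean apical area (um^2); ``shape_ratio``
    the target long/short moment-ellipse ratio (>= 1); ``aligned_fraction``
    the probability that a row of cells is elongated along PD rather than
    DV; ``orientation_noise`` (degrees) scales the shared-vertex jitter.
    """

    n_per_row: int
    m_per_column: int
    cell_area: float = 1.0
    shape_ratio: float = 1.0
    aligned_fraction: float = 1.0
    orientation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_row < 1 or self.m_per_column < 1:
            raise ParameterError("n_per_row and m_per_column must be >= 1")
        if self.cell_area <= 0:
            raise ParameterError("cell_area must be positive")
        if self.shape_ratio < 1:
            raise ParameterError("shape_ratio must be >= 1")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ParameterError("aligned_fraction must be in [0, 1]")
        if self.orientation_noise < 0:
            raise ParameterError("orientation_noise must be >= 0")


#: D. melanogaster 54 h APF study conditions: 45 cells per row, 29 per
#: column, mean apical area 11.68 um^2, shape ratio 1.57, ~52% PD-aligned.
MEL_54H_PLATE = PlateSpec(
    n_per_row=45,
    m_per_column=29,
    cell_area=11.68,
    shape_ratio=1.57,
    aligned_fraction=0.52,
    orientation_noise=3.0,
    seed=0,
)


@dataclass(frozen=True)
class GrowthPhase:
    duration_frames: int
    area_multiplier: float = 1.0
    row_count_delta: int = 0
    column_count_delta: int = 0
    t1_rate: float = 0.0  # transient interior edge flips per frame

    def __post_init__(self):
        if self.duration_frames < 1:
            raise ParameterError("phase duration must be >= 1 frame")
        if self.area_multiplier <= 0:
            raise ParameterError("area_multiplier must be positive")
        if self.t1_rate < 0:
            raise ParameterError("t1_rate must be >= 0")


@dataclass(frozen=True)
class GrowthSchedule:
    phases: tuple[GrowthPhase, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "phases", tuple(self.phases))


@dataclass(frozen=True)
class GrowthSeries:
    """Frames plus the scheduled per-frame ground truth."""

    plates: tuple[TissuePlate, ...]
    truth: pd.DataFrame  # frame, n_per_row, m_per_column, sigma, cell_area


@dataclass(frozen=True)
class T1Script:
    """Scripted neighbor exchanges for a tracked series.

    ``n_stable`` quartets flip once and keep the new configuration to the
    final frame; ``n_oscillating`` quartets flip and revert. Convergence
    axes are drawn from an axial von Mises distribution (``mode_deg``
    degrees, ``concentration`` kappa on the doubled angle) and realized on
    the nearest admissible lattice axis.
    """

    n_stable: int
    n_oscillating: int = 0
    mode_deg: float = 0.0
    concentration: float = 2.0
    frames: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_stable < 0 or self.n_oscillating < 0:
            raise ParameterError("event counts must be >= 0")
        if not 0.0 <= self.mode_deg < 180.0:
            raise ParameterError("mode_deg must lie in [0, 180)")
        if self.frames < 2 or (self.n_oscillating > 0 and self.frames < 3):
            raise ParameterError("not enough frames for the scripted events")


# ---------------------------------------------------------------------------
# hexagon row geometry

def _hexagon(w: float, e: float, delta: float) -> np.ndarray:
    """Centered brick-row hexagon: width w, vertical edges e, caps delta."""
    return np.array(
        [
            (-w / 2, -e / 2),
            (0.0, -e / 2 - delta),
            (w / 2, -e / 2),
            (w / 2, e / 2),
            (0.0, e / 2 + delta),
            (-w / 2, e / 2),
        ]
    )


def _variance_ratio(w: float, e: float, delta: float) -> float:
    _, _, cov = _polygon_moments(_hexagon(w, e, delta))
    return cov[0, 0] / cov[1, 1]


def _solve_edge_length(w: float, delta: float, rho: float) -> float:
    """Vertical-edge length giving var_x/var_y = rho (monotone in e)."""
    f = lambda e: _variance_ratio(w, e, delta) - rho
    return brentq(f, 1e-4, 1e4, xtol=1e-12, rtol=1e-14)


class _HexLattice:
    """Shared-vertex brick-row hexagonal tessellation.

    Cells are keyed ``cell_id = 1 + j * n + i`` (row j, column i). Vertex
    keys are ``(k, level)`` with ``x = k * w / 2`` and ``level`` indexing
    the per-row y-levels; T1 surgery adds event-local keys.
    """

    def __init__(self, spec: PlateSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        n, m, s = spec.n_per_row, spec.m_per_column, spec.shape_ratio
        w = math.sqrt(3.0)
        # keep the regular-hexagon cap when it leaves headroom for s
        delta = min(0.5, w / (2.5 * s))
        # quota assignment: exactly round(f * m) aligned rows, shuffled, so
        # the realized aligned fraction matches the spec even at small m
        n_aligned = int(round(spec.aligned_fraction * m))
        aligned = np.zeros(m, dtype=bool)
        aligned[:n_aligned] = True
        self.aligned_rows = rng.permutation(aligned)
        if s == 1.0:
            e_aligned = e_cross = _solve_edge_length(w, delta, 1.0)
        else:
            e_aligned = _solve_edge_length(w, delta, s * s)
            e_cross = _solve_edge_length(w, delta, 1.0 / (s * s))
        edges = np.where(self.aligned_rows, e_aligned, e_cross)

        # y-levels: [-delta, B_0, T_0, B_1, T_1, ..., T_{m-1}, T_{m-1}+delta]
        levels = [-delta, 0.0]
        for j in range(m):
            levels.append(levels[-1] + edges[j])  # T_j
            if j < m - 1:
                levels.append(levels[-1] + delta)  # B_{j+1}
        levels.append(levels[-1] + delta)
        self._levels = np.array(levels)

        self.cells: dict[int, list] = {}
        for j in range(m):
            for i in range(n):
                kc = 2 * i + (j % 2)
                b, t = 2 * j + 1, 2 * j + 2
                self.cells[1 + j * n + i] = [
                    (kc - 1, b), (kc, b - 1), (kc + 1, b),
                    (kc + 1, t), (kc, t + 1), (kc - 1, t),
                ]

        keys = sorted({k for ring in self.cells.values() for k in ring})
        coords = {k: np.array([k[0] * w / 2.0, self._levels[k[1]]]) for k in keys}
        if spec.orientation_noise > 0:
            # vertex displacement ~ angular noise x cell half-size (lattice units);
            # capped so rings stay simple and the shared tiling stays exact
            sd = math.radians(spec.orientation_noise) * 0.8
            cap = 0.45 * min(delta, float(edges.min()) / 2.0, w / 4.0)
            disp = rng.normal(0.0, sd, size=(len(keys), 2))
            norms = np.hypot(disp[:, 0], disp[:, 1])
            over = norms > cap
            disp[over] *= (cap / norms[over])[:, None]
            for k, d in zip(keys, disp):
                coords[k] = coords[k] + d
        self.coords = coords
        self._normalize_area()

    def _normalize_area(self):
        areas = [abs(Polygon(self._ring(c)).area) for c in self.cells]
        lam = math.sqrt(self.spec.cell_area / float(np.mean(areas)))
        self.coords = {k: v * lam for k, v in self.coords.items()}

    def _ring(self, cell_id: int) -> np.ndarray:
        return np.array([self.coords[k] for k in self.cells[cell_id]])

    def scale(self, factor: float):
        self.coords = {k: v * factor for k, v in self.coords.items()}

    def plate(self) -> TissuePlate:
        cells = tuple(
            CellPolygon(cid, self._ring(cid)) for cid in sorted(self.cells)
        )
        return TissuePlate(cells=cells, pd_axis=(1.0, 0.0))

    # -- T1 machinery ------------------------------------------------------

    def interior_edges(self):
        """Edges shared by two cells whose endpoints each border a third,
        distinct cell: the quartets on which a T1 is well defined.

        Yields ``(p, q, a, b, c, d)``: the edge endpoints, the losing pair
        (a, b) and the gaining pair (c at p, d at q).
        """
        edge_cells: dict[frozenset, list[int]] = {}
        vertex_cells: dict[tuple, set[int]] = {}
        for cid, ring in self.cells.items():
            for u, v in zip(ring, ring[1:] + ring[:1]):
                edge_cells.setdefault(frozenset((u, v)), []).append(cid)
            for u in ring:
                vertex_cells.setdefault(u, set()).add(cid)
        out = []
        for edge, owners in edge_cells.items():
            if len(owners) != 2:
                continue
            a, b = owners
            p, q = tuple(edge)
            cs = vertex_cells[p] - {a, b}
            ds = vertex_cells[q] - {a, b}
            if len(cs) == 1 and len(ds) == 1 and cs != ds:
                out.append((p, q, a, b, cs.pop(), ds.pop()))
        return out

    def centroid(self, cell_id: int) -> np.ndarray:
        _, c, _ = _polygon_moments(self._ring(cell_id))
        return c

    def flip_edge(self, p, q, a, b, c, d, tag) -> None:
        """T1 surgery: collapse edge p-q (between cells a, b) and extend a
        new edge between c and d along the a-b centroid axis. The shared
        tiling stays exact; a and b retain single-point contact with the
        new edge's endpoints only."""
        mid = 0.5 * (self.coords[p] + self.coords[q])
        ab = self.centroid(b) - self.centroid(a)
        ab = ab / np.hypot(*ab)
        t = 0.3 * float(np.hypot(*(self.coords[p] - self.coords[q])))
        ua, ub = ("t1", tag, 0), ("t1", tag, 1)
        self.coords[ua] = mid - 0.5 * t * ab
        self.coords[ub] = mid + 0.5 * t * ab

        def _sub(cell, old, new):
            ring = self.cells[cell]
            idx = ring.index(old)
            self.cells[cell] = ring[:idx] + list(new) + ring[idx + 1:]

        # losing cells: contiguous pair (p, q) -> single point
        for cell, keep in ((a, ua), (b, ub)):
            ring = self.cells[cell]
            ii = ring.index(p)
            jj = ring.index(q)
            if (ii + 1) % len(ring) == jj:
                first = ii
            elif (jj + 1) % len(ring) == ii:
                first = jj
            else:  # pragma: no cover - lattice guarantees adjacency
                raise GeometryError("edge vertices not adjacent in losing cell")
            if first + 1 < len(ring):
                self.cells[cell] = ring[:first] + [keep] + ring[first + 2:]
            else:  # pair wraps around the ring end
                self.cells[cell] = [keep] + ring[1:first]
        # gaining cells: single point -> the new edge, order fixed by validity
        for cell, old in ((c, p), (d, q)):
            base = list(self.cells[cell])
            best = None
            for order in ((ua, ub), (ub, ua)):
                self.cells[cell] = base
                _sub(cell, old, order)
                poly = Polygon(self._ring(cell))
                if poly.is_valid and (best is None or poly.area > best[0]):
                    best = (poly.area, list(self.cells[cell]))
            if best is None:  # pragma: no cover
                raise GeometryError("T1 surgery produced invalid polygon")
            self.cells[cell] = best[1]

    def snapshot(self):
        return {cid: list(r) for cid, r in self.cells.items()}, dict(self.coords)

    def restore(self, snap):
        cells, coords = snap
        self.cells = {cid: list(r) for cid, r in cells.items()}
        self.coords = dict(coords)


def generate_hex_plate(spec: PlateSpec) -> TissuePlate:
    """Generate one tessellated plate matching the spec's ground truth.

    The returned plate tiles a simply connected region with
    ``n_per_row x m_per_column`` interior-disjoint hexagons whose measured
    mean area is ``cell_area`` (exact up to rounding) and whose mean
    moment-ellipse shape ratio is ``shape_ratio``; deterministic per seed.
    """
    return _HexLattice(spec).plate()


# ---------------------------------------------------------------------------
# growth series

def _spread_counts(start: int, delta: int, frames: int) -> list[int]:
    """Monotone per-frame integer counts from start to start+delta."""
    return [start + round(delta * (t + 1) / frames) for t in range(frames)]


def generate_growth_series(spec: PlateSpec, schedule: GrowthSchedule) -> GrowthSeries:
    """Evolve a plate through scheduled expansion and count changes.

    Within a phase the per-cell area is scaled isotropically each frame by
    ``area_multiplier ** (1/duration)``; scheduled row/column count changes
    are applied at the tissue margin (the lattice is rebuilt at the new
    counts and current area, preserving the global geometry). The returned
    ground truth carries the scheduled n, m, sigma = n/m and cell area per
    frame.
    """
    n, m, a = spec.n_per_row, spec.m_per_column, spec.cell_area
    plates = [generate_hex_plate(spec)]
    rows = [(0, n, m, n / m, a)]
    frame = 0
    current = plates[0]
    for phase in schedule.phases:
        ns = _spread_counts(n, phase.row_count_delta, phase.duration_frames)
        ms = _spread_counts(m, phase.column_count_delta, phase.duration_frames)
        if min(ns) < 1 or min(ms) < 1:
            raise ParameterError("schedule drives row/column counts below 1")
        g = phase.area_multiplier ** (1.0 / phase.duration_frames)
        for t in range(phase.duration_frames):
            frame += 1
            a *= g
            if ns[t] == n and ms[t] == m:
                scaled = tuple(
                    CellPolygon(c.cell_id, c.vertices * math.sqrt(g))
                    for c in current.cells
                )
                current = TissuePlate(cells=scaled, pd_axis=current.pd_axis)
            else:
                n, m = ns[t], ms[t]
                sub_seed = (schedule.seed * 100003 + frame) % (2**31)
                lat = _HexLattice(replace(spec, n_per_row=n, m_per_column=m,
                                          cell_area=a, seed=sub_seed))
                if phase.t1_rate > 0:
                    rng = np.random.default_rng(sub_seed + 1)
                    cands = lat.interior_edges()
                    k = min(int(round(phase.t1_rate)), len(cands))
                    for ei in rng.choice(len(cands), size=k, replace=False):
                        lat.flip_edge(*cands[ei], tag=int(ei))
                current = lat.plate()
            plates.append(current)
            rows.append((frame, n, m, n / m, a))
    truth = pd.DataFrame(
        rows, columns=["frame", "n_per_row", "m_per_column", "sigma", "cell_area"]
    )
    return GrowthSeries(plates=tuple(plates), truth=truth)


# ---------------------------------------------------------------------------
# tracked series with scripted T1 events

def sample_axial_angles(
    n: int, mode_deg: float, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Axial von Mises sample, degrees in [0, 180).

    The von Mises is placed on the doubled angle (the standard axial
    construction), so ``concentration`` is the kappa of ``2 theta``.
    """
    phi = rng.vonmises(math.radians(2.0 * mode_deg), concentration, size=n)
    return (np.degrees(phi) / 2.0) % 180.0


def _axial_delta(a: float, b: float) -> float:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def generate_tracked_series(spec: PlateSpec, script: T1Script) -> TrackedTissue:
    """Frame series with persistent identities and scripted T1 events.

    Stable events flip a quartet's shared edge at a scheduled frame and
    persist to the end; oscillating events revert before the final frame.
    Scripted convergence axes are drawn from the script's axial von Mises
    distribution and realized on the admissible lattice axis closest to
    each draw. The ground-truth event list (with realized angles) is
    attached as ``TrackedTissue.ground_truth``.
    """
    lat = _HexLattice(spec)
    rng = np.random.default_rng(script.seed)
    total = script.n_stable + script.n_oscillating

    candidates = lat.interior_edges()
    axes = []
    for p, q, a, b, c, d in candidates:
        v = lat.centroid(d) - lat.centroid(c)
        axes.append(math.degrees(math.atan2(v[1], v[0])) % 180.0)

    draws = sample_axial_angles(total, script.mode_deg, script.concentration, rng)
    used_cells: set[int] = set()
    chosen = []
    for k in range(total):
        best, best_d = None, None
        for ci, (p, q, a, b, c, d) in enumerate(candidates):
            if {a, b, c, d} & used_cells:
                continue
            dd = _axial_delta(axes[ci], draws[k])
            if best_d is None or dd < best_d:
                best, best_d = ci, dd
        if best is None:
            raise ParameterError(
                f"only {k} disjoint interior quartets available for "
                f"{total} scripted events"
            )
        chosen.append(candidates[best])
        used_cells |= set(candidates[best][2:])

    last = script.frames - 1
    events = []
    for k, cand in enumerate(chosen):
        stable = k < script.n_stable
        if stable:
            f_on = int(rng.integers(1, last + 1))
            f_off = None
        else:
            f_on = int(rng.integers(1, last))
            f_off = int(rng.integers(f_on + 1, last + 1))
        events.append((cand, f_on, f_off, stable))

    frames: list[TissuePlate] = []
    truth: list[T1Event] = []
    base = lat.snapshot()
    for f in range(script.frames):
        lat.restore(base)
        for k, (cand, f_on, f_off, stable) in enumerate(events):
            if f >= f_on and (f_off is None or f < f_off):
                lat.flip_edge(*cand, tag=k)
        frames.append(lat.plate())
        for k, (cand, f_on, f_off, stable) in enumerate(events):
            if f == f_on:
                p, q, a, b, c, d = cand
                conv, div = event_angles(
                    lat.centroid(c), lat.centroid(d),
                    lat.centroid(a), lat.centroid(b), (1.0, 0.0),
                )
                truth.append(T1Event(
                    quartet=(a, b, c, d), frame=f,
                    convergence_angle=conv, divergence_angle=div,
                    stable=stable,
                ))
    identity = {
        (f, c.cell_id): c.cell_id for f, pl in enumerate(frames) for c in pl.cells
    }
    return TrackedTissue(
        frames=tuple(frames),
        identity_map=identity,
        reference_axis=(1.0, 0.0),
        ground_truth=tuple(truth),
    )


# ---------------------------------------------------------------------------
# allometry data

def generate_allometry_dataset(
    slopes: Mapping[str, float],
    intercepts: Mapping[str, float],
    n_per_group: int,
    noise_sd: float,
    seed: int = 0,
    x_range: tuple[float, float] = (0.0, 0.4),
) -> pd.DataFrame:
    """Log-log allometry table ``(group, x, y)``.

    Per group, a latent size t is uniform on ``x_range`` (decades of body
    size; the default 0.4-decade span emulates a diet-manipulated
    ~2.5-fold range of pupal area) and the observed point scatters about
    the line ``y = intercept + slope * t`` with total vertical deviation
    of sd ``noise_sd``, split between the two coordinates with error-sd
    ratio equal to the slope (``sd_y_err = |slope| * sd_x_err``) — the
    error structure under which the SMA slope is the consistent estimator,
    mirroring trait/size data where both axes are measured.
    """
    if n_per_group < 3:
        raise ParameterError("n_per_group must be >= 3")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if set(slopes) != set(intercepts):
        raise ParameterError("slopes and intercepts must cover the same groups")
    rng = np.random.default_rng(seed)
    parts = []
    for group in slopes:
        b = slopes[group]
        t = rng.uniform(x_range[0], x_range[1], size=n_per_group)
        x = t.copy()
        y = intercepts[group] + b * t
        if noise_sd > 0:
            if b == 0:
                raise ParameterError("noisy data need a nonzero slope")
            x = x + rng.normal(0.0, noise_sd / (math.sqrt(2.0) * abs(b)),
                               size=n_per_group)
            y = y + rng.normal(0.0, noise_sd / math.sqrt(2.0), size=n_per_group)
        parts.append(pd.DataFrame({"group": group, "x": x, "y": y}))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# rasterization

def rasterize_plate(plate: TissuePlate, pixel_size: float) -> np.ndarray:
    """Integer-labeled raster of a plate, background 0, one label per cell.

    The y axis is flipped (pixel row 0 at the top) to match image
    conventions; labels are the cell ids (uint16).
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    if plate.n_cells == 0:
        return np.zeros((1, 1), dtype=np.uint16)
    allxy = np.vstack([c.vertices for c in plate.cells])
    xmin, ymin = allxy.min(axis=0)
    xmax, ymax = allxy.max(axis=0)
    width = max(1, int(math.ceil((xmax - xmin) / pixel_size)) + 1)
    height = max(1, int(math.ceil((ymax - ymin) / pixel_size)) + 1)
    mask = np.zeros((height, width), dtype=np.uint16)
    for cell in plate.cells:
        if not 0 < cell.cell_id < 65536:
            raise ParameterError(f"cell id {cell.cell_id} not rasterizable as uint16")
        rows = (ymax - cell.vertices[:, 1]) / pixel_size
        cols = (cell.vertices[:, 0] - xmin) / pixel_size
        rr, cc = _draw_polygon(rows, cols, shape=mask.shape)
        if rr.size == 0:
            raise GeometryError(
                f"cell {cell.cell_id} vanishes at pixel size {pixel_size}"
            )
        mask[rr, cc] = cell.cell_id
    present = set(np.unique(mask)) - {0}
    missing = {c.cell_id for c in plate.cells} - present
    if missing:
        raise GeometryError(
            f"cells {sorted(missing)} vanish at pixel size {pixel_size}"
        )
    return mask
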