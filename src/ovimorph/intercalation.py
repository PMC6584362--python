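"""T1 neighbor-exchange detection and nematic summary statistics.

A T1 transition is a neighbor exchange among exactly four cells: a pair
(A, B) that was in contact loses it, while the pair (C, D) that A and B
separated gains a contact. Exchanges whose quartet has returned to its
starting configuration by the final frame are "oscillating" and carry no
net contribution; the remaining, "stable", exchanges are the ones
summarized. Each event's convergence (gaining pair) and divergence (losing
pair) axes are the centroid-joining lines at the exchange frame, measured
as axial angles against a reference axis (the PD / bristle-row line).

The population of event axes is summarized by the average unit nematic:
``Q1 = mean cos 2theta``, ``Q2 = mean sin 2theta``, with mean axis
``theta_n = 0.5 * atan2(Q2, Q1)`` and alignment magnitude
``sqrt(Q1^2 + Q2^2)`` in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.strtree import STRtree

from .errors import GeometryError, ParameterError, TrackingError
from .morphometrics import TissuePlate, _polygon_moments

__all__ = [
    "TrackedTissue",
    "T1Event",
    "NematicSummary",
    "build_neighbor_graph",
    "detect_t1_events",
    "event_angles",
    "nematic_average",
    "angular_histogram",
    "SHARED_BOUNDARY_TOL",
]

#: Minimum shared boundary length (um) for two cells to count as neighbors;
#: separates edge contact from four-cell point junctions.
SHARED_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class T1Event:
    """One neighbor exchange: (A, B) lose contact, (C, D) gain it."""

    quartet: tuple  # (A, B, C, D) track ids
    frame: int  # first frame where the new C-D contact exists
    convergence_angle: float  # axial degrees of the C-D centroid line
    divergence_angle: float  # axial degrees of the A-B centroid line
    stable: bool

    @property
    def losing_pair(self):
        return frozenset(self.quartet[:2])

    @property
    def gaining_pair(self):
        return frozenset(self.quartet[2:])


@dataclass(frozen=True)
class TrackedTissue:
    """Frame series with persistent track identities.

    ``identity_map`` sends ``(frame_index, cell_label)`` to a track id;
    generator output also carries its scripted events in ``ground_truth``.
    """

    frames: tuple[TissuePlate, ...]
    identity_map: Mapping[tuple[int, int], int]
    reference_axis: tuple[float, float] = (1.0, 0.0)
    ground_truth: tuple[T1Event, ...] = ()

    def __post_init__(self):
        ax = np.asarray(self.reference_axis, dtype=float)
        if float(np.hypot(*ax)) == 0.0:
            raise ParameterError("reference_axis must be nonzero")
        for f, plate in enumerate(self.frames):
            for cell in plate.cells:
                if (f, cell.cell_id) not in self.identity_map:
                    raise TrackingError(
                        f"cell {cell.cell_id} in frame {f} has no track id"
                    )


@dataclass(frozen=True)
class NematicSummary:
    q1: float
    q2: float
    axis: float  # theta_n, axial degrees in [0, 180); meaningless if magnitude ~ 0
    magnitude: float
    n_events: int


def build_neighbor_graph(
    plate: TissuePlate,
    identity_map: Mapping[int, int] | None = None,
    tol: float = SHARED_BOUNDARY_TOL,
) -> nx.Graph:
    """Adjacency over track ids: edge iff shared boundary length > tol.

    Cells meeting only at a point (four-cell junctions) are not neighbors.
    ``identity_map`` translates cell labels to track ids (identity if None).
    """
    ident = identity_map or {}
    graph = nx.Graph()
    polys = [cell.shapely() for cell in plate.cells]
    ids = [ident.get(cell.cell_id, cell.cell_id) for cell in plate.cells]
    graph.add_nodes_from(ids)
    tree = STRtree(polys)
    for i, poly in enumerate(polys):
        for j in tree.query(poly):
            if j <= i:
                continue
            inter = poly.intersection(polys[j])
            if inter.is_empty:
                continue
            if getattr(inter, "area", 0.0) > tol * tol:
                raise GeometryError(
                    f"cells {ids[i]} and {ids[j]} overlap (area {inter.area:.3g})"
                )
            if inter.length > tol:
                graph.add_edge(ids[i], ids[j])
    return graph


def event_angles(
    gaining_1: Sequence[float],
    gaining_2: Sequence[float],
    losing_1: Sequence[float],
    losing_2: Sequence[float],
    reference_axis: Sequence[float] = (1.0, 0.0),
) -> tuple[float, float]:
    """Convergence and divergence axes (axial degrees in [0, 180)).

    Convergence is the line joining the gaining pair's centroids,
    divergence the losing pair's, both measured from ``reference_axis``.
    """
    ref = math.degrees(math.atan2(reference_axis[1], reference_axis[0]))
    out = []
    for p1, p2 in ((gaining_1, gaining_2), (losing_1, losing_2)):
        d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
        if float(np.hypot(*d)) < 1e-12:
            raise GeometryError("coincident centroids: angle undefined")
        out.append((math.degrees(math.atan2(d[1], d[0])) - ref) % 180.0)
    return out[0], out[1]


def _centroids(plate: TissuePlate, ident: Mapping) -> dict:
    cents = {}
    for cell in plate.cells:
        _, c, _ = _polygon_moments(cell.vertices)
        cents[ident.get(cell.cell_id, cell.cell_id)] = c
    return cents


def detect_t1_events(
    tissue: TrackedTissue, tol: float = SHARED_BOUNDARY_TOL
) -> list[T1Event]:
    """Find all T1 exchanges in a tracked series.

    Between consecutive frames, a lost contact A-B paired with a gained
    contact C-D forms a T1 when the four tracks are distinct and C and D
    were both neighbors of both A and B before the exchange. The exchange
    is attributed to the first frame showing the new contact. Stability is
    judged per quartet against the start of the acquisition: if the
    quartet's final-frame configuration equals its initial one, all its
    exchanges are oscillating (``stable=False``); otherwise the last
    exchange is the stable one.
    """
    if len(tissue.frames) < 2:
        raise ParameterError("need at least 2 frames to detect exchanges")
    per_frame_ident = [
        {c.cell_id: tissue.identity_map[(f, c.cell_id)] for c in plate.cells}
        for f, plate in enumerate(tissue.frames)
    ]
    graphs = [
        build_neighbor_graph(plate, per_frame_ident[f], tol)
        for f, plate in enumerate(tissue.frames)
    ]

    events: list[T1Event] = []
    for f in range(1, len(graphs)):
        prev, curr = graphs[f - 1], graphs[f]
        lost = [e for e in prev.edges if not curr.has_edge(*e)]
        gained = [e for e in curr.edges if not prev.has_edge(*e)]
        cents = _centroids(tissue.frames[f], per_frame_ident[f])
        for c, d in gained:
            for a, b in lost:
                if {a, b} & {c, d}:
                    continue
                if not (prev.has_edge(a, c) and prev.has_edge(a, d)
                        and prev.has_edge(b, c) and prev.has_edge(b, d)):
                    continue
                if any(x not in cents for x in (a, b, c, d)):
                    continue  # tracking gap across the exchange: skip event
                conv, div = event_angles(
                    cents[c], cents[d], cents[a], cents[b], tissue.reference_axis
                )
                events.append(T1Event(
                    quartet=(a, b, c, d), frame=f,
                    convergence_angle=conv, divergence_angle=div, stable=True,
                ))
                break

    # quartet-level stability against the start of the acquisition
    first, final = graphs[0], graphs[-1]
    by_quartet: dict[frozenset, list[int]] = {}
    for i, ev in enumerate(events):
        by_quartet.setdefault(frozenset(ev.quartet), []).append(i)
    resolved = list(events)
    for quartet, idxs in by_quartet.items():
        ev0 = events[idxs[0]]
        a, b = ev0.quartet[:2]
        reverted = final.has_edge(a, b) == first.has_edge(a, b)
        for rank, i in enumerate(sorted(idxs, key=lambda i: events[i].frame)):
            ev = events[i]
            stable = (not reverted) and rank == len(idxs) - 1
            resolved[i] = T1Event(ev.quartet, ev.frame, ev.convergence_angle,
                                  ev.divergence_angle, stable)
    return sorted(resolved, key=lambda e: (e.frame, e.quartet))


def nematic_average(angles_deg: Iterable[float]) -> NematicSummary:
    """Average unit nematic of a set of axial angles.

    ``magnitude`` is 1 iff all angles coincide (mod 180) and 0 for
    perfectly cancelling axes, in which case ``axis`` is reported but
    carries no information.
    """
    theta = np.asarray(list(angles_deg), dtype=float)
    if theta.size == 0:
        raise ParameterError("nematic average of an empty angle set")
    rad2 = np.radians(2.0 * theta)
    q1 = float(np.mean(np.cos(rad2)))
    q2 = float(np.mean(np.sin(rad2)))
    axis = math.degrees(0.5 * math.atan2(q2, q1)) % 180.0
    return NematicSummary(
        q1=q1, q2=q2, axis=axis,
        magnitude=float(math.hypot(q1, q2)), n_events=int(theta.size),
    )


def angular_histogram(
    angles_deg: Iterable[float], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Counts over equal-width axial bins spanning [0, 180).

    Returns ``(counts, bin_edges)``; counts always sum to the number of
    input angles.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    theta = np.asarray(list(angles_deg), dtype=float) % 180.0
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(theta, bins=edges)
    return counts, edges
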