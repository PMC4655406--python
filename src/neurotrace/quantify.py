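"""Neuron assembly and measurement.

Combines detected somata with traced sequences into validated neurons:
sequences shorter than 20 μm are dropped, somata without any retained
sequence are dropped ("a soma without a neurite is not a soma"), the longest
retained sequence per soma is labeled the axon and the rest dendrites.
Total neurite length adds L*, the Euclidean offset from the tracing initial
point (on the 40-μm circle) to the soma boundary, to the traced path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.ops import nearest_points

from .image_io import ScaleInfo
from .soma_detection import Soma
from .neurite_tracing import TraceSequence

__all__ = [
    "QuantParams",
    "NeuriteRecord",
    "Neuron",
    "lstar",
    "total_length",
    "orientation",
    "assemble_neurons",
    "evaluate",
    "records_frame",
]


@dataclass
class QuantParams:
    min_neurite_len_um: float = 20.0
    match_radius_um: float = 10.0
    #: "path" = traced arc length (default); "euclidean" = straight-line
    #: initial-to-end distance, for the figure-style axon criterion.
    axon_criterion: str = "path"
    #: traces from the same soma ending within this radius are duplicates of
    #: one neurite (adjacent initial points latching onto the same ridge);
    #: the most direct (shortest) one is kept
    endpoint_dedup_um: float = 10.0

    def __post_init__(self) -> None:
        if self.min_neurite_len_um <= 0 or self.match_radius_um <= 0:
            raise ValueError("lengths must be positive")


@dataclass
class NeuriteRecord:
    soma_id: int
    label: str  # "axon" | "dendrite"
    total_length_um: float
    orientation_deg: float
    n_points: int
    terminated: bool
    flagged: bool = False
    sequence: TraceSequence | None = field(default=None, repr=False)


@dataclass
class Neuron:
    soma: Soma
    soma_id: int
    neurites: list


def _boundary_polygon(soma: Soma) -> Polygon:
    poly = Polygon([(c, r) for r, c in soma.boundary])
    if not poly.is_valid:
        poly = poly.buffer(0)  # may split a self-touching contour
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def lstar(initial_point, soma: Soma, scale: ScaleInfo) -> float:
    """Euclidean distance (μm) from the tracing initial point to the nearest
    vertex-interpolated point of the soma boundary; 0 (with a warning) if the
    initial point lies inside the boundary."""
    poly = _boundary_polygon(soma)
    p = Point(initial_point[1], initial_point[0])
    if poly.contains(p):
        warnings.warn("initial point inside the soma boundary: L* = 0", stacklevel=2)
        return 0.0
    return float(p.distance(poly.exterior)) * scale.microns_per_pixel


def total_length(sequence: TraceSequence, soma: Soma | None, scale: ScaleInfo) -> float:
    """Total neurite length: traced path length (μm) plus L*."""
    L = sequence.path_length_px() * scale.microns_per_pixel
    if soma is not None:
        L += lstar(sequence.initial_point, soma, scale)
    return L


def sprouting_point(sequence: TraceSequence, soma: Soma) -> np.ndarray:
    """The soma-boundary point nearest the tracing initial point, (row, col)."""
    poly = _boundary_polygon(soma)
    p = Point(sequence.initial_point[1], sequence.initial_point[0])
    q = nearest_points(poly.exterior, p)[0]
    return np.array([q.y, q.x])


def orientation(sequence: TraceSequence, soma: Soma) -> float:
    """Neurite orientation: angle of the vector from the sprouting point on
    the soma to the final traced point, degrees CCW from +x (col axis),
    in (-180, 180]; NaN when the vector is degenerate."""
    if len(sequence.points) < 2:
        return float("nan")
    start = sprouting_point(sequence, soma)
    end = np.asarray(sequence.points[-1].position, dtype=float)[:2]
    d = end - start
    if np.allclose(d, 0):
        return float("nan")
    ang = float(np.degrees(np.arctan2(-d[0], d[1])))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _euclid_len(sequence: TraceSequence, scale: ScaleInfo) -> float:
    a = np.asarray(sequence.points[0].position, float)
    b = np.asarray(sequence.points[-1].position, float)
    return float(np.linalg.norm(b - a)) * scale.microns_per_pixel


def assemble_neurons(
    somata,
    sequences,
    qparams: QuantParams | None = None,
    scale: ScaleInfo | None = None,
) -> list[Neuron]:
    """Validate and label: drop sequences shorter than the 20-μm filter, drop
    somata left without sequences, label the longest sequence per soma as the
    axon (a lone retained sequence is the axon) and the rest dendrites."""
    qparams = qparams or QuantParams()
    neurons: list[Neuron] = []
    for sid, soma in enumerate(somata):
        mine = [s for s in sequences if s.soma_id == sid]
        sc = scale or soma.scale
        measured = []
        for s in mine:
            L = total_length(s, soma, sc)
            if L < qparams.min_neurite_len_um:
                continue
            measured.append((L, s))
        # collapse duplicate routes to the same tip, keeping the most direct
        dedup_px = qparams.endpoint_dedup_um / sc.microns_per_pixel
        measured.sort(key=lambda item: item[0])
        kept: list = []
        for L, s in measured:
            end = np.asarray(s.points[-1].position, float)[:2]
            if all(
                np.linalg.norm(end - np.asarray(k.points[-1].position, float)[:2])
                >= dedup_px
                for _, k in kept
            ):
                kept.append((L, s))
        measured = kept
        if not measured:
            continue
        soma.has_neurite = True

        def sort_key(item):
            L, s = item
            rank = L if qparams.axon_criterion == "path" else _euclid_len(s, sc)
            end = tuple(np.asarray(s.points[-1].position, float))
            return (-rank, -len(s.points), end)

        measured.sort(key=sort_key)
        records = []
        for k, (L, s) in enumerate(measured):
            label = "axon" if k == 0 else "dendrite"
            s.label = label
            ang = orientation(s, soma)
            records.append(
                NeuriteRecord(
                    soma_id=sid,
                    label=label,
                    total_length_um=L,
                    orientation_deg=ang,
                    n_points=len(s.points),
                    terminated=s.terminated,
                    flagged=bool(np.isnan(ang)),
                    sequence=s,
                )
            )
        neurons.append(Neuron(soma=soma, soma_id=sid, neurites=records))
    return neurons


def records_frame(neurons) -> pd.DataFrame:
    rows = [
        {
            "soma_id": rec.soma_id,
            "label": rec.label,
            "length_um": rec.total_length_um,
            "orientation_deg": rec.orientation_deg,
            "n_points": rec.n_points,
            "terminated": rec.terminated,
        }
        for n in neurons
        for rec in n.neurites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "soma_id",
            "label",
            "length_um",
            "orientation_deg",
            "n_points",
            "terminated",
        ],
    )


def match_detections(detected_centers, true_centers, match_radius_px: float):
    """Greedy one-to-one matching, closest pairs first, within the radius.
    Returns the number of matched pairs."""
    if len(detected_centers) == 0 or len(true_centers) == 0:
        return 0
    det = np.asarray(detected_centers, dtype=float)
    tru = np.asarray(true_centers, dtype=float)
    d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = [
        (d[i, j], i, j)
        for i in range(len(det))
        for j in range(len(tru))
        if d[i, j] <= match_radius_px
    ]
    pairs.sort(key=lambda t: t[0])
    used_d, used_t = set(), set()
    matched = 0
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return matched


def evaluate(detected_centers, true_centers, qparams: QuantParams, scale: ScaleInfo):
    """Precision and recall of center detection under greedy one-to-one
    matching within ``match_radius_um``.  Zero detections report precision
    1.0 (convention) with the corresponding recall."""
    radius_px = qparams.match_radius_um / scale.microns_per_pixel
    matched = match_detections(detected_centers, true_centers, radius_px)
    n_det, n_true = len(detected_centers), len(true_centers)
    precision = 1.0 if n_det == 0 else matched / n_det
    recall = 0.0 if n_true == 0 else matched / n_true
    return precision, recall
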