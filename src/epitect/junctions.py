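"""Voronoi-referenced geometric signatures of active junction shrinkage.

Actual junction geometry is compared against a neutral reference: the
Voronoi tessellation seeded with the actual cell centroids. Actively
shortened junctions are shorter than their Voronoi counterpart (negative
length deviation), the vertex angles of the cells at their ends are more
acute than Voronoi angles (negative angle deviation), and the end-pair
cells elongate along the junction-shrinkage axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.ops import linemerge

from ._geometry import interior_angle, polygon_centroid, shape_matrix

__all__ = [
    "VoronoiReference",
    "voronoi_reference",
    "junction_deviations",
    "endpair_elongation",
    "classify_junction_status",
    "junction_metrics_table",
]


class VoronoiReference:
    """Voronoi tessellation of cell centroids (plus a guard corona).

    Cells whose Voronoi region is unbounded (no guard corona around
    them) are excluded from metrics via :attr:`bounded`.
    """

    def __init__(self, centroids: dict[int, np.ndarray]):
        self.ids = sorted(centroids)
        pts = np.array([centroids[i] for i in self.ids], float)
        if len(pts) < 4:
            raise ValueError("need at least 4 centroids")
        spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if spread[1] < 1e-9 * max(spread[0], 1.0):
            raise ValueError("centroids are collinear")
        self.vor = Voronoi(pts)
        self._ridge: dict[frozenset, tuple[int, int]] = {}
        for (p, q), verts in zip(self.vor.ridge_points, self.vor.ridge_vertices):
            self._ridge[frozenset((self.ids[p], self.ids[q]))] = tuple(verts)
        self.bounded = {
            cid for cid, p in zip(self.ids, self.vor.point_region)
            if -1 not in self.vor.regions[p] and len(self.vor.regions[p]) > 0
        }

    def has_edge(self, a, b) -> bool:
        v = self._ridge.get(frozenset((a, b)))
        return v is not None and -1 not in v

    def edge_length(self, a, b) -> float:
        v = self._ridge[frozenset((a, b))]
        if -1 in v:
            raise ValueError(f"Voronoi edge ({a},{b}) is unbounded")
        p, q = self.vor.vertices[v[0]], self.vor.vertices[v[1]]
        return float(np.linalg.norm(p - q))

    def triple_vertex(self, a, b, c) -> np.ndarray:
        """Voronoi vertex where the regions of cells a, b and c meet."""
        sets = []
        for pair in ((a, b), (a, c), (b, c)):
            v = self._ridge.get(frozenset(pair))
            if v is None:
                raise ValueError(f"cells {pair} share no Voronoi ridge")
            sets.append(set(v) - {-1})
        common = sets[0] & sets[1] & sets[2]
        if len(common) != 1:
            raise ValueError(f"no unique triple vertex for cells ({a},{b},{c})")
        return self.vor.vertices[common.pop()]

    def angle_at(self, a, b, opposite) -> float:
        """Interior angle (degrees) of the opposite cell's Voronoi region at
        the vertex it shares with cells a and b — the two incident ridges
        are (a, opposite) and (b, opposite)."""
        v = self.triple_vertex(a, b, opposite)
        arms = []
        for other in (a, b):
            vv = self._ridge[frozenset((other, opposite))]
            ends = [self.vor.vertices[k] for k in vv if k != -1]
            far = max(ends, key=lambda e: np.linalg.norm(e - v))
            arms.append(far - v)
        nu = np.linalg.norm(arms[0]) * np.linalg.norm(arms[1])
        if nu == 0:
            raise ValueError("degenerate Voronoi ridge")
        cos = np.clip(np.dot(arms[0], arms[1]) / nu, -1.0, 1.0)
        return float(np.degrees(np.arccos(cos)))


def voronoi_reference(centroids: dict[int, np.ndarray]) -> VoronoiReference:
    """Build the neutral-geometry reference from cell centroids.

    Include a guard corona of centroids outside the placode so that all
    placode cells of interest have bounded regions.
    """
    return VoronoiReference(centroids)


def _junction_endpoints(polyline) -> tuple[np.ndarray, np.ndarray] | None:
    geom = polyline
    if geom is None or geom.is_empty:
        return None
    if geom.geom_type == "MultiLineString":
        geom = linemerge(geom)
    if geom.geom_type == "MultiLineString":
        # pick the overall extremes of the longest component
        geom = max(geom.geoms, key=lambda g: g.length)
    if geom.geom_type != "LineString" or len(geom.coords) < 2:
        return None
    c = np.asarray(geom.coords)
    return c[0], c[-1]


def _opposite_cell(endpoint, a, b, polygons: dict, tol: float):
    """The third cell at a junction end vertex, or None when the vertex is
    not a clean 3-way meeting point."""
    cands = []
    for cid, poly in polygons.items():
        if cid in (a, b):
            continue
        p = np.asarray(poly, float)
        if np.min(np.linalg.norm(p - endpoint, axis=1)) < tol:
            cands.append(cid)
    if len(cands) == 1:
        return cands[0]
    return None


@dataclass
class JunctionDeviation:
    length_um: float
    voronoi_length_um: float
    length_deviation_um: float
    angle_deviation_deg: float  # NaN when both ends are not 3-way
    opposite_cells: tuple
    flag: str = ""


def junction_deviations(
    pair: tuple[int, int],
    polygons: dict[int, np.ndarray],
    adjacency,
    ref: VoronoiReference,
    vertex_tol_um: float = 0.3,
) -> JunctionDeviation:
    """Length and vertex-angle deviation of one junction from Voronoi.

    Length deviation = actual − Voronoi (µm; negative suggests active
    shortening). Angle deviation = mean over the two end vertices of the
    opposite (third) cell's interior angle minus the corresponding
    Voronoi-region angle (degrees).
    """
    a, b = pair
    actual = adjacency.length(a, b)
    vlen = ref.edge_length(a, b)
    ends = _junction_endpoints(adjacency.polyline(a, b))
    devs, opps, flag = [], [], ""
    if ends is None:
        flag = "no polyline"
    else:
        for endpoint in ends:
            opp = _opposite_cell(endpoint, a, b, polygons, vertex_tol_um)
            if opp is None:
                flag = "non-3-way end"
                continue
            try:
                v_angle = ref.angle_at(a, b, opp)
            except ValueError:
                flag = "no Voronoi triple vertex"
                continue
            r_angle = interior_angle(polygons[opp], endpoint)
            devs.append(r_angle - v_angle)
            opps.append(opp)
    angle_dev = float(np.mean(devs)) if devs else float("nan")
    return JunctionDeviation(actual, vlen, actual - vlen, angle_dev, tuple(opps), flag)


def endpair_elongation(
    end_cells: tuple[int, int] | list[int],
    polygons: dict[int, np.ndarray],
    rframe,
    frame: int,
) -> float:
    """Signed elongation of the cells at the two junction ends.

    Per cell: e = ln(λ₁/λ₂) of the shape tensor, projected with
    cos(2·(major axis − local circumferential direction)); positive means
    circumferentially elongated. Returns the mean over the end cells.
    """
    contribs = []
    for cid in end_cells:
        q = shape_matrix(polygons[cid])
        w, v = np.linalg.eigh(q)
        lam1, lam2 = w[1], w[0]
        if lam2 <= 0:
            raise ValueError("degenerate shape tensor")
        e = float(np.log(lam1 / lam2))
        if e == 0.0:
            contribs.append(0.0)
            continue
        major = v[:, 1]
        cen = polygon_centroid(polygons[cid])
        _, e_c = rframe.unit_vectors(cen, frame)
        phi = np.arctan2(major[1], major[0])
        phic = np.arctan2(e_c[1], e_c[0])
        contribs.append(e * float(np.cos(2 * (phi - phic))))
    return float(np.mean(contribs)) if contribs else 0.0


def classify_junction_status(
    pair: tuple[int, int],
    frame: int,
    events,
    frame_interval_min: float,
    t1_offset_min: float = -3.0,
    exclusion_frames: int = 5,
) -> tuple[str, float | None]:
    """("T1", time-to-exchange min) when the pair is a losing pair sampled
    at the configured lead time before its exchange (the gain frame);
    ("baseline", None) when the pair is in no event within
    ``exclusion_frames``; otherwise ("excluded", None)."""
    key = frozenset(pair)
    t1_frames = [e.frame_gain for e in events if e.losing_pair and frozenset(e.losing_pair) == key]
    if t1_frames:
        f_ex = min(t1_frames, key=lambda f: abs(f - frame))
        tte = (frame - f_ex) * frame_interval_min
        target = round(t1_offset_min / frame_interval_min)
        if frame - f_ex == target:
            return "T1", tte
        return "excluded", tte
    near = [
        e for e in events
        if abs(e.frame_gain - frame) <= exclusion_frames
        and (key & set(e.gaining_pair) or (e.losing_pair and key & set(e.losing_pair)))
    ]
    if near:
        return "excluded", None
    return "baseline", None


def junction_metrics_table(
    cells: pd.DataFrame,
    adjacency,
    rframe,
    events,
    frame: int,
    layer: str = "apical",
    guard_ids=(),
    frame_interval_min: float = 2.0,
    t1_offset_min: float = -3.0,
) -> pd.DataFrame:
    """Per-junction signature metrics for one frame.

    Border cells and cells without a bounded Voronoi region are excluded;
    ``guard_ids`` marks centroids used only to bound the tessellation.
    """
    sub = cells[(cells["frame"] == frame) & (cells["layer"] == layer)].set_index("cell_id")
    centroids = {cid: sub.loc[cid, ["x", "y"]].values.astype(float) for cid in sub.index}
    polygons = {cid: np.asarray(sub.loc[cid, "polygon"], float) for cid in sub.index}
    ref = voronoi_reference(centroids)
    adj = adjacency[frame]
    good = {
        cid for cid in sub.index
        if cid in ref.bounded and cid not in guard_ids and not sub.loc[cid, "is_border"]
    }
    rows = []
    for a, b in adj.pairs():
        if a not in good or b not in good or not ref.has_edge(a, b):
            continue
        dev = junction_deviations((a, b), polygons, adj, ref)
        status, tte = classify_junction_status((a, b), frame, events,
                                               frame_interval_min, t1_offset_min)
        mid = (centroids[a] + centroids[b]) / 2.0
        axis = centroids[b] - centroids[a]
        # junction orientation is the interface axis, perpendicular to the
        # centroid-centroid line of its two cells
        perp = np.array([-axis[1], axis[0]])
        orient = rframe.classify_orientation(perp, mid, frame)
        elong = (endpair_elongation(dev.opposite_cells, polygons, rframe, frame)
                 if dev.opposite_cells else np.nan)
        rows.append({
            "cell_a": a, "cell_b": b, "frame": frame,
            "length_um": dev.length_um, "voronoi_length_um": dev.voronoi_length_um,
            "length_deviation_um": dev.length_deviation_um,
            "angle_deviation_deg": dev.angle_deviation_deg,
            "endpair_elongation": elong,
            "orientation": orient, "status": status, "time_to_exchange_min": tte,
            "flag": dev.flag,
        })
    return pd.DataFrame(rows)
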