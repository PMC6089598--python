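"""Read/write tracked-cell data and build per-frame cell adjacency.

The in-memory container for tracked cells is a pandas DataFrame (the
"cell table") with one row per cell per frame per layer and columns::

    movie_id, frame, time_min, layer, cell_id, x, y, polygon,
    is_placode, is_border, track_gap

``polygon`` holds an (n, 2) float array of vertices in µm; ``x, y`` is the
polygon's area centroid. Layers are "apical" or "midbasal". The tabular
on-disk format is CSV with the polygon encoded as semicolon-separated
"x,y" pairs, which round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from ._geometry import polygon_area, polygon_centroid

CELL_COLUMNS = [
    "movie_id",
    "frame",
    "time_min",
    "layer",
    "cell_id",
    "x",
    "y",
    "polygon",
    "is_placode",
    "is_border",
    "track_gap",
]


@dataclass
class RunMetadata:
    """Per-movie acquisition and analysis metadata.

    pixel_size_um : image pixel size (µm / px)
    frame_interval_min : time between frames (min)
    dz_um : depth separation between the apical and mid-basal layers (µm)
    side : "left" or "right" embryo side (sets the angle handedness)
    posterior : unit vector pointing towards posterior in image coords
    pit_cell_ids : track ids of the cells forming the invagination pit
    t0_frame : frame index taken as t = 0 (first tissue bending)
    layer_depths_um : nominal depth bands of the two extracted layers
    background : constant background intensity, or None to estimate
    """

    pixel_size_um: float = 0.22
    frame_interval_min: float = 2.0
    dz_um: float = 7.0
    side: str = "left"
    posterior: tuple[float, float] = (1.0, 0.0)
    pit_cell_ids: list[int] = field(default_factory=list)
    t0_frame: int = 0
    layer_depths_um: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 3.0), (7.0, 8.0))
    background: float | None = None
    movie_id: str = "movie"

    def __post_init__(self):
        if self.dz_um <= 0:
            raise ValueError("dz_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def to_json(self, path):
        d = dict(self.__dict__)
        d["posterior"] = list(self.posterior)
        d["pit_cell_ids"] = [int(i) for i in self.pit_cell_ids]
        d["layer_depths_um"] = [list(b) for b in self.layer_depths_um]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunMetadata":
        with open(path) as fh:
            d = json.load(fh)
        d["posterior"] = tuple(d["posterior"])
        d["layer_depths_um"] = tuple(tuple(b) for b in d["layer_depths_um"])
        return cls(**d)


@dataclass
class CellRecord:
    """One cell at one frame in one layer."""

    movie_id: str
    frame: int
    time_min: float
    layer: str
    cell_id: int
    polygon: np.ndarray
    is_placode: bool = True
    is_border: bool = False
    track_gap: bool = False

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.polygon)

    @property
    def area(self) -> float:
        return polygon_area(self.polygon)


def make_cell_table(records) -> pd.DataFrame:
    """Assemble a cell table from an iterable of CellRecord."""
    rows = []
    seen = set()
    for r in records:
        key = (r.frame, r.layer, r.cell_id)
        if key in seen:
            raise ValueError(f"duplicate cell_id {r.cell_id} in frame {r.frame}, layer {r.layer}")
        seen.add(key)
        c = r.centroid
        rows.append(
            (r.movie_id, r.frame, r.time_min, r.layer, r.cell_id, c[0], c[1],
             np.asarray(r.polygon, float), r.is_placode, r.is_border, r.track_gap)
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    """Write a cell table to CSV; polygons become "x,y;x,y;…" strings."""
    out = cells.copy()
    out["polygon"] = [
        ";".join(f"{float(v[0])!r},{float(v[1])!r}" for v in np.asarray(p, float))
        for p in out["polygon"]
    ]
    out.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cells_csv`."""
    df = pd.read_csv(path)
    polys = []
    for s in df["polygon"]:
        pts = [tuple(float(t) for t in pair.split(",")) for pair in s.split(";")]
        polys.append(np.array(pts, float))
    df["polygon"] = polys
    for col in ("is_placode", "is_border", "track_gap"):
        df[col] = df[col].astype(bool)
    return df[CELL_COLUMNS]


# ---------------------------------------------------------------------------
# label-image loading


def _trace_label(label_img: np.ndarray, lab: int, pixel_size: float) -> np.ndarray:
    from skimage import measure

    mask = label_img == lab
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError(f"label {lab} has no boundary")
    contour = max(contours, key=len)  # (row, col) sub-pixel trace
    poly = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def _overlap_links(stack: list[np.ndarray]) -> pd.DataFrame:
    """Maximal-overlap frame-to-frame linking (convenience tracker).

    Not the original study's tracker: labels are chained greedily by the
    largest pixel overlap between consecutive frames.
    """
    rows = []
    next_id = 1
    prev_map: dict[int, int] = {}
    for f, img in enumerate(stack):
        labs = [int(l) for l in np.unique(img) if l != 0]
        cur_map: dict[int, int] = {}
        for lab in labs:
            tid = None
            if f > 0:
                under = stack[f - 1][img == lab]
                under = under[under != 0]
                if len(under):
                    best = int(np.bincount(under).argmax())
                    cand = prev_map.get(best)
                    if cand is not None and cand not in cur_map.values():
                        tid = cand
            if tid is None:
                tid = next_id
                next_id += 1
            cur_map[lab] = tid
            rows.append((f, lab, tid))
        prev_map = cur_map
    return pd.DataFrame(rows, columns=["frame", "label", "cell_id"])


def load_tracked_layers(
    label_stack,
    links: pd.DataFrame | None,
    meta: RunMetadata,
    layer: str = "apical",
    placode_outline: np.ndarray | None = None,
    border_tol_um: float | None = None,
) -> pd.DataFrame:
    """Build a cell table from integer-labelled images plus tracking links.

    Parameters
    ----------
    label_stack : sequence of 2D integer arrays (one per frame) or paths to
        TIFF files readable by tifffile. Background is 0.
    links : DataFrame with columns (frame, label, cell_id) mapping image
        labels to track ids, or None to use maximal-overlap linking.
    placode_outline : optional (n, 2) polygon in µm; cells with centroid
        inside are flagged ``is_placode`` and cells whose polygon comes
        within ``border_tol_um`` of the outline are flagged ``is_border``.
    """
    import tifffile

    stack = []
    for item in label_stack:
        if isinstance(item, (str, bytes)) or hasattr(item, "__fspath__"):
            stack.append(np.asarray(tifffile.imread(item)))
        else:
            stack.append(np.asarray(item))
    if not stack:
        raise ValueError("empty label stack")

    if links is None:
        links = _overlap_links(stack)
    dup = links.duplicated(subset=["frame", "label"])
    if dup.any():
        raise ValueError("duplicated label in a frame in the link table")
    link_map = {(int(r.frame), int(r.label)): int(r.cell_id) for r in links.itertuples()}

    frames_present = sorted({int(f) for f, _ in link_map})
    expected = list(range(frames_present[0], frames_present[-1] + 1))
    missing = sorted(set(expected) - set(frames_present))
    if missing:
        raise ValueError(f"missing frame(s) in link table: {missing}")
    if len(stack) <= frames_present[-1]:
        raise ValueError(f"missing frame {frames_present[-1]} in label stack")

    if border_tol_um is None:
        border_tol_um = 2.0 * meta.pixel_size_um
    outline = Polygon(placode_outline) if placode_outline is not None else None

    records = []
    frames_of_track: dict[int, list[int]] = {}
    for f, img in enumerate(stack):
        labs = [int(l) for l in np.unique(img) if l != 0]
        for lab in labs:
            if (f, lab) not in link_map:
                continue
            tid = link_map[(f, lab)]
            poly = _trace_label(img, lab, meta.pixel_size_um)
            cen = polygon_centroid(poly)
            is_pl = True
            is_bd = False
            if outline is not None:
                from shapely.geometry import Point

                is_pl = outline.contains(Point(cen))
                is_bd = is_pl and Polygon(poly).distance(outline.exterior) < border_tol_um
            records.append(
                CellRecord(meta.movie_id, f, (f - meta.t0_frame) * meta.frame_interval_min,
                           layer, tid, poly, is_pl, is_bd)
            )
            frames_of_track.setdefault(tid, []).append(f)

    table = make_cell_table(records)
    # flag tracks with frame gaps or that do not span the whole stack
    gappy = set()
    for tid, fl in frames_of_track.items():
        fl = sorted(fl)
        if fl[-1] - fl[0] + 1 != len(fl) or len(fl) < len(stack):
            gappy.add(tid)
    table["track_gap"] = table["cell_id"].isin(gappy)
    return table


# ---------------------------------------------------------------------------
# adjacency


class AdjacencyMap:
    """Symmetric cell adjacency for one (frame, layer).

    Maps unordered cell-id pairs to the shared-interface length (µm) and the
    shared-boundary polyline (a shapely geometry).
    """

    def __init__(self, frame: int, layer: str):
        self.frame = frame
        self.layer = layer
        self._edges: dict[frozenset, tuple[float, object]] = {}

    def add(self, a, b, length: float, polyline=None) -> None:
        if a == b:
            raise ValueError("a cell cannot neighbour itself")
        if length < 0:
            raise ValueError("interface length must be >= 0")
        self._edges[frozenset((a, b))] = (float(length), polyline)

    def pairs(self):
        return [tuple(sorted(p)) for p in self._edges]

    def has(self, a, b) -> bool:
        return frozenset((a, b)) in self._edges

    def length(self, a, b) -> float:
        return self._edges[frozenset((a, b))][0]

    def polyline(self, a, b):
        return self._edges[frozenset((a, b))][1]

    def neighbors(self, a):
        return sorted({x for p in self._edges for x in p if a in p and x != a})

    def __len__(self):
        return len(self._edges)

    def __iter__(self):
        return iter(self.pairs())


def build_adjacency(
    cells: pd.DataFrame,
    frame: int,
    layer: str,
    contact_tol_um: float = 0.44,
) -> AdjacencyMap:
    """Cell adjacency from polygon contact.

    Two cells are adjacent iff their boundaries share a polyline longer
    than ``contact_tol_um`` (default 2 px at 0.22 µm/px), either exactly
    (meshes with shared vertices) or within that distance (raster traces
    separated by a 1-px watershed ridge).
    """
    sub = cells[(cells["frame"] == frame) & (cells["layer"] == layer)]
    ids = list(sub["cell_id"])
    polys = [Polygon(p) for p in sub["polygon"]]
    adj = AdjacencyMap(frame, layer)
    if not ids:
        return adj
    tree = STRtree(polys)
    for i, pi in enumerate(polys):
        hits = tree.query(pi.buffer(contact_tol_um))
        for j in hits:
            j = int(j)
            if j <= i:
                continue
            pj = polys[j]
            inter = pi.boundary.intersection(pj.boundary)
            length = inter.length
            polyline = inter
            if length <= 1e-6:  # no exact shared segment (raster traces)
                # raster case: no exact shared segment; measure the stretch of
                # boundary i running within contact_tol of boundary j, less the
                # ~2·tol a mere shared corner contributes
                near = pi.boundary.intersection(pj.boundary.buffer(contact_tol_um))
                near_len = near.length - 2.0 * contact_tol_um
                if near_len > length:
                    length = near_len
                    polyline = near
            if length > contact_tol_um:
                adj.add(ids[i], ids[j], length, polyline)
    return adj


def build_adjacency_over(cells: pd.DataFrame, layer: str, contact_tol_um: float = 0.44):
    """Adjacency maps for every frame of a layer, keyed by frame."""
    frames = sorted(cells.loc[cells["layer"] == layer, "frame"].unique())
    return {int(f): build_adjacency(cells, int(f), layer, contact_tol_um) for f in frames}


# ---------------------------------------------------------------------------
# track quality filters


def filter_tracks(
    cells: pd.DataFrame,
    min_lineage: int = 1,
    area_range_um2: tuple[float, float] = (0.5, 300.0),
    max_aspect: float = 10.0,
    max_rel_velocity_um_min: float = 5.0,
    frame_interval_min: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove incorrectly tracked cells; returns (filtered, rejection log).

    A track failing any filter (lineage length, area range, aspect ratio,
    or velocity relative to the per-frame median cell motion) is removed
    for all its frames, and one log row records the first reason.
    """
    from ._geometry import shape_matrix

    log = []
    bad: dict[int, str] = {}
    for (layer, tid), grp in cells.groupby(["layer", "cell_id"]):
        if len(grp) < min_lineage:
            bad[tid] = "lineage"
            continue
        areas = np.array([polygon_area(p) for p in grp["polygon"]])
        if areas.min() < area_range_um2[0] or areas.max() > area_range_um2[1]:
            bad[tid] = "area"
            continue
        aspects = []
        for p in grp["polygon"]:
            w = np.linalg.eigvalsh(shape_matrix(p))
            aspects.append(w[1] / max(w[0], 1e-12))
        if max(aspects) > max_aspect:
            bad[tid] = "aspect"

    # relative velocity: per consecutive frame pair, compare each track's step
    # to the median step of all tracks present in both frames
    for layer in cells["layer"].unique():
        sub = cells[cells["layer"] == layer]
        frames = sorted(sub["frame"].unique())
        for f0, f1 in zip(frames[:-1], frames[1:]):
            a = sub[sub["frame"] == f0].set_index("cell_id")
            b = sub[sub["frame"] == f1].set_index("cell_id")
            common = a.index.intersection(b.index)
            if len(common) < 2:
                continue
            disp = (b.loc[common, ["x", "y"]].values - a.loc[common, ["x", "y"]].values)
            med = np.median(disp, axis=0)
            rel = np.linalg.norm(disp - med, axis=1) / ((f1 - f0) * frame_interval_min)
            for tid, rv in zip(common, rel):
                if rv > max_rel_velocity_um_min and tid not in bad:
                    bad[tid] = "relative velocity"

    for tid, reason in bad.items():
        log.append((tid, reason))
    filtered = cells[~cells["cell_id"].isin(bad)].reset_index(drop=True)
    if len(cells) and not len(filtered):
        raise ValueError("all cells removed by track filters; review thresholds")
    return filtered, pd.DataFrame(log, columns=["cell_id", "reason"])
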