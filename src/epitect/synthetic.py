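"""Ground-truthed synthetic placodes and analytic unit fixtures.

The generator is kinematic, not mechanical: a polygonal cell mesh
(centroidal-Voronoi relaxed) is advected by prescribed smooth vertex
displacement fields, and topology changes (T1 flips, rosette collapses)
are scripted events applied to the mesh, so every imposed quantity is
known exactly. It emulates the study system: a roughly circular ~100
cell placode with an off-centre pit, a radial apical-constriction field
clustered at the pit, circumferentially biased neighbour gains far from
the pit, a second (mid-basal) layer derived by imposed wedging and tilt
fields ~7 µm deeper, and junctional myosin images with imposed
circumferential enrichment plus Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from ._geometry import polygon_centroid
from .tracking_io import CellRecord, RunMetadata, make_cell_table

__all__ = ["PlacodeParams", "GroundTruth", "SyntheticPlacode", "generate_placode", "generate_fixture"]


# ---------------------------------------------------------------------------
# polygonal mesh with scripted topology changes


class Mesh:
    """Planar cell mesh: shared vertices, cells as CCW vertex-id loops."""

    def __init__(self, vertices: dict[int, np.ndarray], cells: dict[int, list[int]],
                 border: set[int] | None = None):
        self.vertices = {k: np.asarray(v, float).copy() for k, v in vertices.items()}
        self.cells = {k: list(v) for k, v in cells.items()}
        self.border = set(border or ())

    def copy(self) -> "Mesh":
        return Mesh(self.vertices, self.cells, self.border)

    def polygon(self, cid) -> np.ndarray:
        return np.array([self.vertices[v] for v in self.cells[cid]])

    def centroid(self, cid) -> np.ndarray:
        return polygon_centroid(self.polygon(cid))

    def edges(self) -> dict[frozenset, list]:
        """Map vertex-pair -> cell ids sharing that edge."""
        out: dict[frozenset, list] = {}
        for cid, loop in self.cells.items():
            for v1, v2 in zip(loop, loop[1:] + loop[:1]):
                out.setdefault(frozenset((v1, v2)), []).append(cid)
        return out

    def contact_pairs(self, min_len: float = 0.44) -> set[frozenset]:
        """Ground-truth contact graph: cell pairs sharing an edge longer
        than the contact tolerance."""
        pairs = set()
        for vk, cids in self.edges().items():
            if len(cids) == 2:
                v1, v2 = tuple(vk)
                if np.linalg.norm(self.vertices[v1] - self.vertices[v2]) > min_len:
                    pairs.add(frozenset(cids))
        return pairs

    def cells_at_vertex(self, v) -> list:
        return sorted(c for c, loop in self.cells.items() if v in loop)

    def shared_edge(self, a, b):
        for vk, cids in self.edges().items():
            if len(cids) == 2 and set(cids) == {a, b}:
                return tuple(vk)
        return None

    def edge_vector(self, v1, v2) -> np.ndarray:
        return self.vertices[v2] - self.vertices[v1]

    def shrink_edge(self, v1, v2, factor: float) -> None:
        """Pull the edge's endpoints towards its midpoint (length × factor)."""
        m = (self.vertices[v1] + self.vertices[v2]) / 2.0
        self.vertices[v1] = m + (self.vertices[v1] - m) * factor
        self.vertices[v2] = m + (self.vertices[v2] - m) * factor

    def _replace_pair(self, cid, v1, v2, keep):
        loop = self.cells[cid]
        n = len(loop)
        for i in range(n):
            if {loop[i], loop[(i + 1) % n]} == {v1, v2}:
                drop = v2 if keep == v1 else v1
                self.cells[cid] = [v for v in loop if v != drop]
                return
        raise ValueError(f"cells {cid}: edge ({v1},{v2}) not found")

    def _insert_at(self, cid, v_old, v_new, after: bool):
        """Insert v_new next to v_old in the cell's loop (after or before)."""
        loop = self.cells[cid]
        i = loop.index(v_old)
        j = i + 1 if after else i
        self.cells[cid] = loop[:j] + [v_new] + loop[j:]

    @staticmethod
    def _has_edge(loop, v1, v2) -> bool:
        n = len(loop)
        return any({loop[k], loop[(k + 1) % n]} == {v1, v2} for k in range(n))

    def t1_flip(self, a, b, gap: float = 1.2):
        """Neighbour exchange on the edge shared by cells a and b.

        The losing pair (a, b) disconnects; the two cells at the edge's
        end vertices (c at one end, d at the other) gain a new interface
        of length ``gap`` perpendicular to the old edge. Returns (c, d).
        """
        ev = self.shared_edge(a, b)
        if ev is None:
            raise ValueError(f"cells {a} and {b} share no edge")
        v1, v2 = ev
        at1 = set(self.cells_at_vertex(v1)) - {a, b}
        at2 = set(self.cells_at_vertex(v2)) - {a, b}
        if len(at1) != 1 or len(at2) != 1:
            raise ValueError("T1 requires 3-way vertices at both edge ends")
        c, d = at1.pop(), at2.pop()
        if c == d or self.shared_edge(c, d) is not None:
            raise ValueError("gaining cells already share an edge")
        p1, p2 = self.vertices[v1], self.vertices[v2]
        m = (p1 + p2) / 2.0
        u = p2 - p1
        u = u / np.linalg.norm(u)
        perp = np.array([-u[1], u[0]])
        sgn = np.sign(perp @ (self.centroid(a) - m)) or 1.0
        # v1 becomes a's vertex, v2 becomes b's; the gaining cells keep both.
        # Topology fixes the insertion order: in c the new v2 sits on b's
        # side of v1 (the loop neighbour whose edge c shared with b), and in
        # d the new v1 sits on a's side of v2.
        loop_c, loop_d = self.cells[c], self.cells[d]
        i_c, i_d = loop_c.index(v1), loop_d.index(v2)
        nxt_c = loop_c[(i_c + 1) % len(loop_c)]
        nxt_d = loop_d[(i_d + 1) % len(loop_d)]
        c_after = self._has_edge(self.cells[b], v1, nxt_c)
        d_after = self._has_edge(self.cells[a], v2, nxt_d)
        self.vertices[v1] = m + sgn * perp * gap / 2.0
        self.vertices[v2] = m - sgn * perp * gap / 2.0
        self._replace_pair(a, v1, v2, keep=v1)
        self._replace_pair(b, v1, v2, keep=v2)
        self._insert_at(c, v1, v2, after=c_after)
        self._insert_at(d, v2, v1, after=d_after)
        quartet = {a, b, c, d}
        polys = {}
        for cid in quartet:
            poly = Polygon([self.vertices[v] for v in self.cells[cid]])
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"T1 flip produced an invalid polygon for cell {cid}")
            polys[cid] = poly
        # the repositioned vertices must not push quartet cells over onlookers
        onlookers = {cid for cid, loop in self.cells.items()
                     if cid not in quartet and ({v1, v2} & set(loop)
                                                or any(v in loop for q in quartet
                                                       for v in self.cells[q]))}
        for cid in onlookers:
            other = Polygon([self.vertices[v] for v in self.cells[cid]])
            for q, poly in polys.items():
                if poly.intersection(other).area > 1e-6:
                    raise ValueError(f"T1 flip overlaps cell {cid}")
        return c, d

    def collapse_to_rosette(self, v, offset: float = 0.02):
        """Pull the far endpoints of two edges of vertex ``v`` onto it,
        creating a >=5-cell meeting point. Returns the member cell ids."""
        nbrs = []
        for vk, cids in self.edges().items():
            if v in vk and len(cids) == 2:
                w = next(x for x in vk if x != v)
                nbrs.append(w)
        if len(nbrs) < 2:
            raise ValueError("vertex has fewer than 2 interior edges")
        w1, w2 = sorted(nbrs, key=lambda w: np.linalg.norm(self.vertices[w] - self.vertices[v]))[:2]
        base = self.vertices[v]
        saved = {w: self.vertices[w].copy() for w in (w1, w2)}
        # slide each far endpoint down its own edge to keep polygons simple
        for w in (w1, w2):
            d = self.vertices[w] - base
            n = np.linalg.norm(d)
            self.vertices[w] = base + (d / n * offset if n > 0 else np.array([offset, 0.0]))
        members = set(self.cells_at_vertex(v)) | set(self.cells_at_vertex(w1)) | set(
            self.cells_at_vertex(w2))
        touched = {c for w in (v, w1, w2) for c in self.cells_at_vertex(w)}
        if any(not Polygon(self.polygon(c)).is_valid or Polygon(self.polygon(c)).area <= 0
               for c in touched):
            for w, pos in saved.items():
                self.vertices[w] = pos
            raise ValueError("rosette collapse produced an invalid polygon")
        return sorted(members)


def _voronoi_mesh(seeds: np.ndarray, n_interior: int) -> Mesh:
    """Mesh of the first ``n_interior`` seeds' (finite) Voronoi regions;
    regions touching the remaining guard seeds are marked border."""
    vor = Voronoi(seeds)
    guard_idx = set(range(n_interior, len(seeds)))
    border = set()
    for (p, q) in vor.ridge_points:
        if p < n_interior and q in guard_idx:
            border.add(p + 1)
        if q < n_interior and p in guard_idx:
            border.add(q + 1)
    vertices = {i: vor.vertices[i] for i in range(len(vor.vertices))}
    cells = {}
    for i in range(n_interior):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise ValueError("interior cell has an unbounded region; add guard seeds")
        pts = np.array([vor.vertices[v] for v in region])
        ang = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
        cells[i + 1] = [region[k] for k in np.argsort(ang)]
    return Mesh(vertices, cells, border)


def _separate_vertices(mesh: Mesh, min_d: float = 0.5, exempt: set | None = None) -> None:
    """Push non-exempt vertex pairs closer than ``min_d`` apart so vertex
    coincidences (rosettes) happen only where scripted."""
    from scipy.spatial import cKDTree

    exempt = exempt or set()
    vids = list(mesh.vertices)
    pos = np.array([mesh.vertices[v] for v in vids])
    tree = cKDTree(pos)
    for i, j in sorted(tree.query_pairs(min_d)):
        vi, vj = vids[i], vids[j]
        if vi in exempt and vj in exempt:
            continue
        pi, pj = mesh.vertices[vi].copy(), mesh.vertices[vj].copy()
        d = pj - pi
        n = np.linalg.norm(d)
        u = d / n if n > 1e-9 else np.array([1.0, 0.0])
        m = (pi + pj) / 2.0
        mesh.vertices[vi] = m - u * min_d / 2.0
        mesh.vertices[vj] = m + u * min_d / 2.0
        touched = set(mesh.cells_at_vertex(vi)) | set(mesh.cells_at_vertex(vj))
        if any(not Polygon(mesh.polygon(c)).is_valid
               or Polygon(mesh.polygon(c)).area <= 0 for c in touched):
            mesh.vertices[vi], mesh.vertices[vj] = pi, pj


def _enforce_min_edge(mesh: Mesh, min_len: float = 0.9, passes: int = 4) -> None:
    """Stretch interior edges shorter than ``min_len`` so no cell-cell
    interface sits near the contact tolerance: scripted topology changes
    then remain the only adjacency transitions in the movie."""
    for _ in range(passes):
        short = []
        for vk, cids in mesh.edges().items():
            if len(cids) != 2:
                continue
            v1, v2 = tuple(vk)
            L = np.linalg.norm(mesh.vertices[v2] - mesh.vertices[v1])
            if L < min_len:
                short.append((L, v1, v2))
        if not short:
            return
        short.sort()
        for L, v1, v2 in short:
            p1, p2 = mesh.vertices[v1].copy(), mesh.vertices[v2].copy()
            m = (p1 + p2) / 2.0
            d = p2 - p1
            n = np.linalg.norm(d)
            u = d / n if n > 1e-9 else np.array([1.0, 0.0])
            mesh.vertices[v1] = m - u * min_len / 2.0
            mesh.vertices[v2] = m + u * min_len / 2.0
            touched = set(mesh.cells_at_vertex(v1)) | set(mesh.cells_at_vertex(v2))
            if any(not Polygon(mesh.polygon(c)).is_valid
                   or Polygon(mesh.polygon(c)).area <= 0 for c in touched):
                mesh.vertices[v1], mesh.vertices[v2] = p1, p2


def _lloyd(seeds: np.ndarray, n_interior: int, iterations: int = 4) -> np.ndarray:
    seeds = seeds.copy()
    for _ in range(iterations):
        vor = Voronoi(seeds)
        for i in range(n_interior):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or not region:
                continue
            pts = np.array([vor.vertices[v] for v in region])
            ang = np.arctan2(pts[:, 1] - pts[:, 1].mean(), pts[:, 0] - pts[:, 0].mean())
            seeds[i] = polygon_centroid(pts[np.argsort(ang)])
    return seeds


# ---------------------------------------------------------------------------
# parameters and ground truth


@dataclass
class PlacodeParams:
    """Study-condition defaults: ~100-cell disc, off-centre pit, 2-min
    frames over ±18 min, two layers 7 µm apart, constriction clustered at
    the pit, and a two-thirds-circumferential neighbour-gain script."""

    n_cells: int = 100
    radius_um: float = 22.0
    pit_offset_um: tuple[float, float] = (11.0, 0.0)
    n_pit_cells: int = 3
    n_frames: int = 20
    frame_interval_min: float = 2.0
    t0_frame: int = 9
    pixel_size_um: float = 0.22
    dz_um: float = 7.0
    side: str = "left"
    posterior: tuple[float, float] = (1.0, 0.0)
    drift_um_frame: tuple[float, float] = (0.10, 0.05)
    # apical constriction field (area-loss rate near the pit)
    constriction_rate_min: float = 0.01
    constriction_scale_um: float = 7.0
    # neighbour-exchange script: junctions shrink for t1_shrink_frames,
    # flip, then the gained junction grows to t1_resolved_um (a typical
    # interface length) so each scripted exchange runs to completion
    n_circ_gains: int = 12
    n_rad_gains: int = 4
    t1_first_frame: int = 5
    t1_last_frame: int = 16
    t1_shrink_frames: int = 3
    t1_gap_um: float = 1.2
    t1_resolved_um: float = 2.4
    t1_grow_frames: int = 3
    t1_min_radius_um: float = 12.0
    # rosettes
    n_rosettes: int = 2
    rosette_frame: int = 18
    # optional tissue-wide active shortening of circumferential junctions
    # (proportional length loss per minute, weighted by cos² alignment);
    # off by default — enable to emulate junctional-motor contraction
    circ_shrink_rate_min: float = 0.0
    # depth fields (basal -> apical convention)
    wedging_amp_per_um: float = 0.01
    wedging_scale_um: float = 7.0
    tilt_um_per_um: tuple[float, float] = (0.02, 0.0)
    # myosin rendering
    myosin_base: float = 100.0
    myosin_interior: float = 20.0
    circ_enrichment: float = 1.5
    myosin_noise_sd: float = 5.0
    centroid_jitter_um: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator imposed, for closed-loop verification."""

    pit_path: dict[int, np.ndarray]
    events: list[dict]  # frame_gain, losing, gaining, orientation
    contacts: dict[int, set[frozenset]]  # apical contact graph per frame
    matches: dict[int, int]  # apical id -> basal id (identity here)
    rosettes: list[dict]
    junction_factor: dict[frozenset, float]  # imposed myosin enrichment
    area_rate_min: dict[int, float]  # imposed near-pit area-loss rate per cell
    wedging_amp_per_um: float
    tilt_um_per_um: tuple[float, float]
    circ_enrichment: float


def _radial_field(points: np.ndarray, centre: np.ndarray, amp: float, scale: float) -> np.ndarray:
    """Displacement with divergence −amp·exp(−r²/2ℓ²): u = −amp·ℓ²(1−e^(−r²/2ℓ²))/r · e_r."""
    d = points - centre
    r = np.linalg.norm(d, axis=1)
    r = np.where(r < 1e-9, 1e-9, r)
    mag = -amp * scale ** 2 * (1.0 - np.exp(-r ** 2 / (2 * scale ** 2))) / r
    return d / r[:, None] * mag[:, None]


class SyntheticPlacode:
    """A generated placode: per-frame apical/basal meshes plus truth."""

    def __init__(self, params: PlacodeParams):
        self.params = params
        self._generate()

    # -- generation --------------------------------------------------------

    def _generate(self):
        p = self.params
        rng = np.random.default_rng(p.seed)
        # seeds in a disc + two pinned guard rings
        r = p.radius_um * np.sqrt(rng.uniform(0, 1, p.n_cells))
        th = rng.uniform(0, 2 * np.pi, p.n_cells)
        centre = np.array([p.radius_um * 1.6, p.radius_um * 1.6])  # canvas frame
        interior = np.column_stack([r * np.cos(th), r * np.sin(th)]) + centre
        guards = []
        for ring, m in ((1.18, 30), (1.45, 30)):
            a = np.linspace(0, 2 * np.pi, m, endpoint=False) + (0.1 * ring)
            guards.append(np.column_stack([np.cos(a), np.sin(a)]) * p.radius_um * ring
                          + centre)
        seeds = np.vstack([interior] + guards)
        seeds = _lloyd(seeds, p.n_cells, 4)
        mesh = _voronoi_mesh(seeds, p.n_cells)
        _enforce_min_edge(mesh)

        pit_centre = centre + np.asarray(p.pit_offset_um, float)
        dists = {cid: np.linalg.norm(mesh.centroid(cid) - pit_centre) for cid in mesh.cells}
        self.pit_cells = sorted(sorted(dists, key=dists.get)[: p.n_pit_cells])

        # schedule neighbour exchanges: circumferential and radial gains
        kinds = []
        for i in range(p.n_circ_gains + p.n_rad_gains):
            kinds.append("radial" if (i % 4 == 3 and p.n_rad_gains > 0) else "circumferential")
        kinds = ([k for k in kinds if k == "circumferential"][: p.n_circ_gains]
                 + [k for k in kinds if k == "radial"][: p.n_rad_gains])
        rng.shuffle(kinds)
        n_ev = len(kinds)
        flip_frames = np.linspace(p.t1_first_frame, p.t1_last_frame, n_ev).round().astype(int) \
            if n_ev else np.array([], int)

        self.apical: dict[int, Mesh] = {}
        truth_events: list[dict] = []
        contacts: dict[int, set] = {}
        pit_path: dict[int, np.ndarray] = {}
        rosettes: list[dict] = []
        # cells of in-flight scripted events are blocked until 2 frames
        # after their flip, so overlapping scripts never interfere
        active_until: dict[int, int] = {}
        pending: list[dict] = []  # scripted events with chosen edges
        drift = np.asarray(p.drift_um_frame, float)

        cur = mesh
        for f in range(p.n_frames):
            if f > 0:
                cur = cur.copy()
                pit_now = np.mean([cur.centroid(c) for c in self.pit_cells], axis=0)
                vids = list(cur.vertices)
                pts = np.array([cur.vertices[v] for v in vids])
                disp = _radial_field(pts, pit_now, p.constriction_rate_min
                                     * p.frame_interval_min, p.constriction_scale_um)
                for v, d in zip(vids, disp):
                    cur.vertices[v] = cur.vertices[v] + d + drift
                if p.circ_shrink_rate_min > 0:
                    busy = {v for ev in pending for v in ev["edge"]}
                    for vk, cids in cur.edges().items():
                        if len(cids) != 2 or set(vk) & busy:
                            continue
                        v1, v2 = tuple(vk)
                        vec = cur.edge_vector(v1, v2)
                        L = np.linalg.norm(vec)
                        if L < 1.0:
                            continue
                        mid = (cur.vertices[v1] + cur.vertices[v2]) / 2.0
                        _, e_c = self._pit_frame_dirs(mid, pit_now)
                        if e_c is None:
                            continue
                        cos2 = float(vec @ e_c / L) ** 2
                        factor = 1.0 - p.circ_shrink_rate_min * p.frame_interval_min * cos2
                        saved = (cur.vertices[v1].copy(), cur.vertices[v2].copy())
                        cur.shrink_edge(v1, v2, max(factor, 0.1))
                        touched = set(cur.cells_at_vertex(v1)) | set(cur.cells_at_vertex(v2))
                        if any(not Polygon(cur.polygon(c)).is_valid
                               or Polygon(cur.polygon(c)).area <= 0 for c in touched):
                            cur.vertices[v1], cur.vertices[v2] = saved
                # progress scripted junction shrinkage, apply due flips
                for ev in pending:
                    if ev["done"]:
                        # resolution phase: grow the gained junction towards a
                        # typical interface length
                        k = f - ev["flip_frame"]
                        if 0 < k <= p.t1_grow_frames:
                            v1, v2 = ev["edge"]
                            # symmetric exchange: the gained junction grows to
                            # the length the lost junction started from
                            resolved = max(p.t1_resolved_um, ev["len0"])
                            target = p.t1_gap_um + (resolved - p.t1_gap_um) * (
                                k / p.t1_grow_frames)
                            cur_len = np.linalg.norm(cur.edge_vector(v1, v2))
                            if 1e-9 < cur_len < target:
                                saved = (cur.vertices[v1].copy(), cur.vertices[v2].copy())
                                cur.shrink_edge(v1, v2, target / cur_len)
                                touched = (set(cur.cells_at_vertex(v1))
                                           | set(cur.cells_at_vertex(v2)))
                                if any(not Polygon(cur.polygon(c)).is_valid
                                       or Polygon(cur.polygon(c)).area <= 0
                                       for c in touched):
                                    cur.vertices[v1], cur.vertices[v2] = saved
                        continue
                    if f < ev["flip_frame"]:
                        k = ev["flip_frame"] - f
                        target = {1: 0.3, 2: 0.55}.get(k, 0.8)
                        v1, v2 = ev["edge"]
                        cur_len = np.linalg.norm(cur.edge_vector(v1, v2))
                        if cur_len > 1e-9:
                            saved = (cur.vertices[v1].copy(), cur.vertices[v2].copy())
                            cur.shrink_edge(v1, v2, min(1.0, target * ev["len0"] / cur_len))
                            touched = set(cur.cells_at_vertex(v1)) | set(cur.cells_at_vertex(v2))
                            if any(not Polygon(cur.polygon(c)).is_valid
                                   or Polygon(cur.polygon(c)).area <= 0 for c in touched):
                                cur.vertices[v1], cur.vertices[v2] = saved
                    elif f == ev["flip_frame"]:
                        # transactional flip: retry with smaller gaps in tight
                        # geometry, drop the event if no gap fits
                        # gaps stay above the 0.44 µm contact tolerance so the
                        # gained interface is always detectable
                        for gap in (p.t1_gap_um, 0.8, 0.6):
                            trial = cur.copy()
                            try:
                                c, d = trial.t1_flip(*ev["losing"], gap=gap)
                            except ValueError:
                                continue
                            cur = trial
                            truth_events.append({
                                "frame_gain": f, "losing": tuple(sorted(ev["losing"])),
                                "gaining": tuple(sorted((c, d))), "orientation": ev["kind"],
                                "scripted": True,
                            })
                            break
                        ev["done"] = True
                if p.n_rosettes and f == p.rosette_frame:
                    blocked = {c for c, rel in active_until.items() if rel > f}
                    rosettes.extend(self._script_rosettes(cur, blocked, pit_centre=np.mean(
                        [cur.centroid(c) for c in self.pit_cells], axis=0)))
                    active_until.update({c: p.n_frames for r in rosettes
                                         for c in r["members"]})

            # select upcoming exchanges against the current geometry,
            # retrying each frame until the flip is due
            selected = {pe["index"] for pe in pending}
            for k_ev, (kind, ff) in enumerate(zip(kinds, flip_frames)):
                if k_ev in selected or not (ff - p.t1_shrink_frames <= f < ff):
                    continue
                blocked = {c for c, rel in active_until.items() if rel > f}
                sel = self._select_t1_edge(cur, kind, blocked)
                if sel is not None:
                    a, b, v1, v2 = sel
                    quartet = set(cur.cells_at_vertex(v1)) | set(cur.cells_at_vertex(v2))
                    for c in quartet:
                        active_until[c] = int(ff) + p.t1_grow_frames + 1
                    pending.append({"index": k_ev, "kind": kind, "flip_frame": int(ff),
                                    "losing": (a, b), "edge": (v1, v2),
                                    "len0": float(np.linalg.norm(cur.edge_vector(v1, v2))),
                                    "done": False})
            # once rosettes are scripted, keep unintended vertex coincidences
            # from emerging anywhere else so rosette counts stay exact
            if p.n_rosettes and f >= p.rosette_frame:
                exempt = {v for r in rosettes for v in r["vertices"]}
                _separate_vertices(cur, 0.5, exempt)

            self.apical[f] = cur
            contacts[f] = cur.contact_pairs()
            pit_path[f] = np.mean([cur.centroid(c) for c in self.pit_cells], axis=0)

        # record any emergent (unscripted) contact gains so the truth log is
        # complete for the emitted geometry; they are rare, but interface
        # lengths crossing the contact tolerance can add transitions
        scripted_keys = {(e["frame_gain"], frozenset(e["gaining"])) for e in truth_events}
        for t, t1 in zip(sorted(contacts)[:-1], sorted(contacts)[1:]):
            for pair in contacts[t1] - contacts[t]:
                if (t1, pair) in scripted_keys:
                    continue
                c1, c2 = tuple(pair)
                mesh1 = self.apical[t1]
                axis = mesh1.centroid(c2) - mesh1.centroid(c1)
                mid = (mesh1.centroid(c2) + mesh1.centroid(c1)) / 2.0
                e_r, _ = self._pit_frame_dirs(mid, pit_path[t1])
                ang_r = 90.0 if e_r is None else float(np.degrees(np.arccos(np.clip(
                    abs(axis @ e_r) / max(np.linalg.norm(axis), 1e-12), 0, 1))))
                truth_events.append({
                    "frame_gain": t1, "losing": None, "gaining": tuple(sorted(pair)),
                    "orientation": "radial" if ang_r < 45.0 else "circumferential",
                    "scripted": False,
                })

        # basal layer: apical pushed through imposed wedging + tilt fields
        self.basal: dict[int, Mesh] = {}
        for f, am in self.apical.items():
            bm = am.copy()
            pit_now = pit_path[f]
            vids = list(bm.vertices)
            pts = np.array([bm.vertices[v] for v in vids])
            disp = _radial_field(pts, pit_now, -p.wedging_amp_per_um * p.dz_um,
                                 p.wedging_scale_um)
            tilt = np.asarray(p.tilt_um_per_um, float) * p.dz_um
            for v, d in zip(vids, disp):
                bm.vertices[v] = bm.vertices[v] + d + tilt
            self.basal[f] = bm

        # imposed myosin enrichment by junction orientation (last frames share
        # the factor map of the frame used for rendering)
        self._junction_factor_cache: dict[int, dict] = {}

        area_rate = {}
        for cid in mesh.cells:
            rr = np.linalg.norm(mesh.centroid(cid) - pit_centre)
            area_rate[cid] = -p.constriction_rate_min * np.exp(
                -rr ** 2 / (2 * p.constriction_scale_um ** 2))

        self.truth = GroundTruth(
            pit_path=pit_path, events=truth_events, contacts=contacts,
            matches={cid: cid for cid in mesh.cells}, rosettes=rosettes,
            junction_factor=self.junction_factors(0), area_rate_min=area_rate,
            wedging_amp_per_um=p.wedging_amp_per_um, tilt_um_per_um=p.tilt_um_per_um,
            circ_enrichment=p.circ_enrichment,
        )
        self._rng_render = np.random.default_rng(p.seed + 1)

    def _pit_frame_dirs(self, mid: np.ndarray, pit: np.ndarray):
        d = mid - pit
        r = np.linalg.norm(d)
        if r < 1e-9:
            return None, None
        e_r = d / r
        return e_r, np.array([-e_r[1], e_r[0]])

    def _select_t1_edge(self, mesh: Mesh, kind: str, used: set):
        """A far-from-pit interior edge aligned with the requested gain
        orientation, with a clean untouched quartet."""
        pit = np.mean([mesh.centroid(c) for c in self.pit_cells], axis=0)
        cands = []
        for vk, cids in mesh.edges().items():
            if len(cids) != 2:
                continue
            a, b = cids
            v1, v2 = tuple(vk)
            if a in mesh.border or b in mesh.border:
                continue
            mid = (mesh.vertices[v1] + mesh.vertices[v2]) / 2.0
            if np.linalg.norm(mid - pit) < self.params.t1_min_radius_um:
                continue
            vec = mesh.edge_vector(v1, v2)
            L = np.linalg.norm(vec)
            if L < 1.8:
                continue
            e_r, e_c = self._pit_frame_dirs(mid, pit)
            if e_r is None:
                continue
            ref = e_c if kind == "circumferential" else e_r
            ang = np.degrees(np.arccos(np.clip(abs(vec @ ref) / L, 0, 1)))
            if ang > 38.0:
                continue
            at1 = set(mesh.cells_at_vertex(v1)) - {a, b}
            at2 = set(mesh.cells_at_vertex(v2)) - {a, b}
            if len(at1) != 1 or len(at2) != 1:
                continue
            c, d = at1.pop(), at2.pop()
            quartet = {a, b, c, d}
            if len(quartet) != 4 or quartet & used or quartet & set(self.pit_cells):
                continue
            if mesh.border & quartet or mesh.shared_edge(c, d) is not None:
                continue
            cands.append((ang, -L, tuple(sorted((a, b))), v1, v2))
        if not cands:
            return None
        cands.sort()
        # trial-flip the best candidates: the flip must succeed and the
        # gaining pair's centroid line must classify as the scripted kind
        for _, _, (a, b), v1, v2 in cands[:10]:
            trial = mesh.copy()
            try:
                c, d = trial.t1_flip(a, b, gap=self.params.t1_gap_um)
            except ValueError:
                continue
            axis = trial.centroid(d) - trial.centroid(c)
            mid = (trial.centroid(d) + trial.centroid(c)) / 2.0
            e_r, _ = self._pit_frame_dirs(mid, pit)
            if e_r is None:
                continue
            ang_r = np.degrees(np.arccos(np.clip(
                abs(axis @ e_r) / np.linalg.norm(axis), 0, 1)))
            got = "radial" if ang_r < 45.0 else "circumferential"
            if got == kind:
                return a, b, v1, v2
        return None

    def _script_rosettes(self, mesh: Mesh, used: set, pit_centre):
        out = []
        degree: dict[int, list] = {}
        for vk, cids in mesh.edges().items():
            if len(cids) == 2:
                for v in vk:
                    degree.setdefault(v, []).append(cids)
        cands = []
        all_vids = list(mesh.vertices)
        all_pos = np.array([mesh.vertices[w] for w in all_vids])
        for v in degree:
            owners = set(mesh.cells_at_vertex(v))
            if len(owners) != 3 or owners & used or owners & mesh.border:
                continue
            if len(degree[v]) < 2:
                continue
            # rosettes sit in the near/mid region, clear of the pit cells and
            # of the far annulus where the exchange script runs
            r = np.linalg.norm(mesh.vertices[v] - pit_centre)
            if not (3.0 < r < self.params.t1_min_radius_um):
                continue
            cands.append((r, v))
        cands.sort()
        for _, v in cands:
            if len(out) >= self.params.n_rosettes:
                break
            # re-check against cells consumed by earlier collapses this frame
            if set(mesh.cells_at_vertex(v)) & used:
                continue
            # the merged point must be isolated: only the two collapsing
            # endpoints may sit inside the detector's merge radius, so the
            # member count stays exact
            nbr_v = [w for vk, cids in mesh.edges().items() if v in vk and len(cids) == 2
                     for w in vk if w != v]
            if len(nbr_v) < 2:
                continue
            w12 = sorted(nbr_v, key=lambda w: np.linalg.norm(mesh.vertices[w]
                                                             - mesh.vertices[v]))[:2]
            keepout = {v, *w12}
            d = np.linalg.norm(all_pos - mesh.vertices[v], axis=1)
            foreign = [w for w, dd in zip(all_vids, d) if w not in keepout and dd < 1.2]
            if foreign:
                continue
            saved_positions = {w: mesh.vertices[w].copy() for w in mesh.vertices}
            try:
                members = mesh.collapse_to_rosette(v)
            except ValueError:
                continue
            # reject collapses that fabricate or drop cell-cell contacts under
            # the analysis adjacency rule (truth must match detection)
            detected = self._contact_like(mesh, members)
            mesh_truth = {p for p in mesh.contact_pairs() if set(p) <= set(members)}
            if detected != mesh_truth:
                mesh.vertices.update(saved_positions)
                continue
            used |= set(members)
            out.append({"frame": self.params.rosette_frame,
                        "position": mesh.vertices[v].tolist(),
                        "members": members, "n": len(members),
                        "vertices": [v, *w12]})
        return out

    @staticmethod
    def _contact_like(mesh: Mesh, cells, restore=None, tol: float = 0.44):
        """Pairs among ``cells`` whose boundaries run within ``tol`` for more
        than a corner's worth — the analysis adjacency rule."""
        polys = {c: Polygon(mesh.polygon(c)) for c in cells}
        pairs = set()
        cl = sorted(cells)
        for i, a in enumerate(cl):
            for b in cl[i + 1:]:
                inter = polys[a].boundary.intersection(polys[b].boundary)
                length = inter.length
                if length <= tol:
                    near = polys[a].boundary.intersection(polys[b].boundary.buffer(tol))
                    length = max(length, near.length - 2.0 * tol)
                if length > tol:
                    pairs.add(frozenset((a, b)))
        return pairs

    # -- exports -----------------------------------------------------------

    def metadata(self) -> RunMetadata:
        p = self.params
        return RunMetadata(pixel_size_um=p.pixel_size_um,
                           frame_interval_min=p.frame_interval_min, dz_um=p.dz_um,
                           side=p.side, posterior=p.posterior,
                           pit_cell_ids=list(self.pit_cells), t0_frame=p.t0_frame,
                           movie_id=f"synthetic-{p.seed}")

    def _table(self, meshes: dict[int, Mesh], layer: str) -> pd.DataFrame:
        p = self.params
        recs = []
        for f, mesh in meshes.items():
            for cid in sorted(mesh.cells):
                recs.append(CellRecord(
                    f"synthetic-{p.seed}", f, (f - p.t0_frame) * p.frame_interval_min,
                    layer, cid, mesh.polygon(cid), True, cid in mesh.border))
        return make_cell_table(recs)

    def apical_cells(self) -> pd.DataFrame:
        return self._table(self.apical, "apical")

    def basal_cells(self) -> pd.DataFrame:
        return self._table(self.basal, "midbasal")

    def junction_factors(self, frame: int) -> dict[frozenset, float]:
        """Imposed per-junction myosin factor: 1 + (g−1)·cos²(edge, e_c)."""
        if frame in getattr(self, "_junction_factor_cache", {}):
            return self._junction_factor_cache[frame]
        p = self.params
        mesh = self.apical[frame]
        pit = self.truth.pit_path[frame] if hasattr(self, "truth") else np.mean(
            [mesh.centroid(c) for c in self.pit_cells], axis=0)
        out = {}
        for vk, cids in mesh.edges().items():
            if len(cids) != 2:
                continue
            v1, v2 = tuple(vk)
            vec = mesh.edge_vector(v1, v2)
            L = np.linalg.norm(vec)
            if L < 1e-9:
                continue
            mid = (mesh.vertices[v1] + mesh.vertices[v2]) / 2.0
            e_r, e_c = self._pit_frame_dirs(mid, pit)
            if e_c is None:
                continue
            cos = abs(vec @ e_c) / L
            out[frozenset(cids)] = 1.0 + (p.circ_enrichment - 1.0) * cos ** 2
        if hasattr(self, "_junction_factor_cache"):
            self._junction_factor_cache[frame] = out
        return out

    def _canvas(self):
        p = self.params
        half = p.radius_um * 1.6
        n = int(np.ceil(2 * half / p.pixel_size_um))
        return half, n

    def to_pixels(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, float) / self.params.pixel_size_um

    def render_labels(self, frame: int, layer: str = "apical") -> np.ndarray:
        """16-bit label image of the layer's polygons (background 0)."""
        from shapely.geometry import Point
        from skimage.draw import polygon as draw_polygon

        half, n = self._canvas()
        mesh = self.apical[frame] if layer == "apical" else self.basal[frame]
        img = np.zeros((n, n), np.uint16)
        cover = np.zeros((n, n), np.uint8)
        shapes = {}
        for cid in sorted(mesh.cells):
            px = self.to_pixels(mesh.polygon(cid))
            rr, cc = draw_polygon(px[:, 1], px[:, 0], shape=img.shape)
            img[rr, cc] = cid
            cover[rr, cc] += 1
            shapes[cid] = Polygon(mesh.polygon(cid))
        # contested boundary pixels go to the cell containing the pixel centre
        for r, c in np.argwhere(cover > 1):
            centre = Point(c * self.params.pixel_size_um,
                           r * self.params.pixel_size_um)
            for cid, shape in shapes.items():
                if shape.contains(centre):
                    img[r, c] = cid
                    break
        return img

    def render_myosin(self, frame: int) -> np.ndarray:
        """Intensity image: junction bands at base × imposed factor, dim
        interior, epidermis outside the placode at the base (embryo
        average) level, plus Gaussian noise."""
        from skimage.draw import line as draw_line
        from skimage.morphology import dilation, disk

        p = self.params
        half, n = self._canvas()
        img = np.full((n, n), p.myosin_interior, float)
        yy, xx = np.mgrid[0:n, 0:n]
        rr_um = np.hypot(xx * p.pixel_size_um - half, yy * p.pixel_size_um - half)
        img[rr_um > p.radius_um + 2.0] = p.myosin_base
        mesh = self.apical[frame]
        factors = self.junction_factors(frame)
        for vk, cids in mesh.edges().items():
            if len(cids) != 2 or frozenset(cids) not in factors:
                continue
            v1, v2 = tuple(vk)
            a = self.to_pixels(mesh.vertices[v1])
            b = self.to_pixels(mesh.vertices[v2])
            rr, cc = draw_line(int(round(a[1])), int(round(a[0])),
                               int(round(b[1])), int(round(b[0])))
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            band = np.zeros((n, n), bool)
            band[rr[ok], cc[ok]] = True
            band = dilation(band, disk(2))
            val = p.myosin_base * factors[frozenset(cids)]
            img[band] = np.maximum(img[band], val)
        rng = np.random.default_rng(p.seed + 1000 + frame)
        return img + rng.normal(0.0, p.myosin_noise_sd, img.shape)

    def epidermis_mask(self) -> np.ndarray:
        p = self.params
        half, n = self._canvas()
        yy, xx = np.mgrid[0:n, 0:n]
        rr_um = np.hypot(xx * p.pixel_size_um - half, yy * p.pixel_size_um - half)
        return rr_um > p.radius_um + 2.0

    def write_dir(self, out_dir) -> None:
        """TIFF label/intensity stacks, cell CSVs, metadata and truth JSON."""
        import os
        import tifffile
        from .tracking_io import write_cells_csv

        os.makedirs(out_dir, exist_ok=True)
        for layer in ("apical", "midbasal"):
            stack = np.stack([self.render_labels(f, layer) for f in sorted(self.apical)])
            tifffile.imwrite(os.path.join(out_dir, f"labels_{layer}.tif"), stack,
                             photometric="minisblack")
        myo = np.stack([self.render_myosin(f).astype(np.float32)
                        for f in sorted(self.apical)])
        tifffile.imwrite(os.path.join(out_dir, "myosin.tif"), myo,
                         photometric="minisblack")
        write_cells_csv(self.apical_cells(), os.path.join(out_dir, "cells_apical.csv"))
        write_cells_csv(self.basal_cells(), os.path.join(out_dir, "cells_midbasal.csv"))
        self.metadata().to_json(os.path.join(out_dir, "meta.json"))
        t = self.truth
        payload = {
            "pit_path": {str(f): v.tolist() for f, v in t.pit_path.items()},
            "events": t.events,
            "contacts": {str(f): [sorted(p) for p in sorted(map(tuple, map(sorted, c)))]
                         for f, c in t.contacts.items()},
            "matches": {str(k): v for k, v in t.matches.items()},
            "rosettes": t.rosettes,
            "area_rate_min": {str(k): v for k, v in t.area_rate_min.items()},
            "wedging_amp_per_um": t.wedging_amp_per_um,
            "tilt_um_per_um": list(t.tilt_um_per_um),
            "circ_enrichment": t.circ_enrichment,
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_placode(params: PlacodeParams | None = None, **kw) -> SyntheticPlacode:
    """Generate a ground-truthed synthetic placode (see PlacodeParams)."""
    if params is None:
        params = PlacodeParams(**kw)
    elif kw:
        raise TypeError("pass either a PlacodeParams or keyword overrides, not both")
    return SyntheticPlacode(params)


# ---------------------------------------------------------------------------
# analytic fixtures


def _hex_lattice_polys(spacing: float, rows: int, cols: int, centre=True):
    """Regular hexagon tiling; returns {cell_id: polygon}, exact shared edges."""
    rc = spacing / np.sqrt(3.0)
    ang = np.radians(30 + 60 * np.arange(6))
    hexagon = np.column_stack([rc * np.cos(ang), rc * np.sin(ang)])
    polys = {}
    cid = 1
    centres = []
    for j in range(rows):
        for i in range(cols):
            cx = i * spacing + (j % 2) * spacing / 2.0
            cy = j * spacing * np.sqrt(3.0) / 2.0
            centres.append((cx, cy))
    centres = np.array(centres)
    if centre:
        centres -= centres.mean(axis=0)
    for c in centres:
        polys[cid] = hexagon + c
        cid += 1
    return polys


def _fixture_table(polys_by_frame: dict[int, dict[int, np.ndarray]], layer="apical",
                   dt=1.0, movie="fixture") -> pd.DataFrame:
    recs = []
    for f, polys in polys_by_frame.items():
        for cid, poly in polys.items():
            recs.append(CellRecord(movie, f, f * dt, layer, cid, poly))
    return make_cell_table(recs)


def generate_fixture(kind: str, **params):
    """Minimal deterministic geometries with analytic truth attached.

    Kinds: ``hex_lattice``, ``affine_flow``, ``shear_frozen``,
    ``t1_quartet``, ``frusta``, ``shear_layers``, ``voronoi_geometry``,
    ``rosette``.
    """
    if kind == "hex_lattice":
        spacing = params.get("spacing", 4.0)
        rows = params.get("rows", 7)
        cols = params.get("cols", 7)
        polys = _hex_lattice_polys(spacing, rows, cols)
        return {"cells": _fixture_table({0: polys}), "polygons": polys,
                "interior_angle_deg": 120.0}

    if kind == "affine_flow":
        # exponential flow x(t) = expm((L+W)·t)·x0 on a hex lattice
        L = np.asarray(params.get("L", np.diag([0.01, -0.01])), float)
        omega = params.get("omega_deg_min", 0.0)
        dt = params.get("dt", 2.0)
        n_frames = params.get("n_frames", 3)
        w = np.radians(omega)
        G = L + np.array([[0.0, -w], [w, 0.0]])
        base = _hex_lattice_polys(params.get("spacing", 4.0), 5, 5)
        frames = {}
        for f in range(n_frames):
            A = expm(G * f * dt)
            frames[f] = {cid: poly @ A.T for cid, poly in base.items()}
        return {"cells": _fixture_table(frames, dt=dt), "L": L, "dt": dt,
                "tissue_truth": (L + L.T) / 2.0}

    if kind == "shear_frozen":
        # rigid cells sliding past each other: rows translate with their y
        gamma = params.get("gamma_per_min", 0.02)
        dt = params.get("dt", 2.0)
        n_frames = params.get("n_frames", 3)
        base = _hex_lattice_polys(params.get("spacing", 4.0), 5, 5)
        cents = {cid: polygon_centroid(p) for cid, p in base.items()}
        frames = {}
        for f in range(n_frames):
            frames[f] = {cid: p + np.array([gamma * f * dt * cents[cid][1], 0.0])
                         for cid, p in base.items()}
        Lg = np.array([[0.0, gamma], [0.0, 0.0]])
        return {"cells": _fixture_table(frames, dt=dt), "dt": dt,
                "tissue_truth": (Lg + Lg.T) / 2.0}

    if kind == "t1_quartet":
        gain_axis_deg = params.get("gain_axis_deg", 90.0)
        n_frames = params.get("n_frames", 6)
        flip_frame = params.get("flip_frame", 2)
        reverse_frame = params.get("reverse_frame", None)
        dt = params.get("dt", 2.0)
        th = np.radians(gain_axis_deg - 90.0)  # losing pair sits along this
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        inner = np.array([[1.4, 0.0], [-1.4, 0.0], [0.0, 1.8], [0.0, -1.8]]) @ R.T
        ring_a = np.linspace(0, 2 * np.pi, 8, endpoint=False) + np.pi / 8
        ring = np.column_stack([np.cos(ring_a), np.sin(ring_a)]) * 4.6
        guard_a = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        guard = np.column_stack([np.cos(guard_a), np.sin(guard_a)]) * 8.0
        seeds = np.vstack([inner, ring, guard])
        mesh0 = _voronoi_mesh(seeds, 12)
        losing = (1, 2)  # the two seeds straddling the origin
        frames, meshes = {}, {0: mesh0}
        events = []
        cur = mesh0
        gained = None
        for f in range(n_frames):
            if f > 0:
                cur = cur.copy()
                if f == flip_frame:
                    c, d = cur.t1_flip(*losing, gap=params.get("gap", 1.0))
                    gained = (c, d)
                    events.append({"frame_gain": f, "losing": losing,
                                   "gaining": tuple(sorted(gained))})
                if reverse_frame is not None and f == reverse_frame and gained:
                    c, d = cur.t1_flip(*gained, gap=params.get("gap", 1.0))
                    events.append({"frame_gain": f, "losing": tuple(sorted(gained)),
                                   "gaining": tuple(sorted((c, d)))})
            meshes[f] = cur
            frames[f] = {cid: cur.polygon(cid) for cid in sorted(cur.cells)}
        return {"cells": _fixture_table(frames, dt=dt), "events": events, "dt": dt,
                "losing": losing}

    if kind == "frusta":
        # space-filling frusta: apical = basal lattice scaled about the origin
        s = params.get("s", 1.07)
        dz = params.get("dz", 7.0)
        basal = _hex_lattice_polys(params.get("spacing", 4.0), 5, 5)
        apical = {cid: p * s for cid, p in basal.items()}
        a = _fixture_table({0: apical}, layer="apical")
        b = _fixture_table({0: basal}, layer="midbasal")
        centre_id = min(basal, key=lambda c: np.linalg.norm(polygon_centroid(basal[c])))
        return {"apical": a, "basal": b, "dz": dz, "centre_cell": centre_id,
                "wedging_truth": np.log(s) / dz}

    if kind == "shear_layers":
        shift = params.get("shift_um", 3.5)
        dz = params.get("dz", 7.0)
        basal = _hex_lattice_polys(params.get("spacing", 4.0), 5, 5)
        apical = {cid: p + np.array([shift, 0.0]) for cid, p in basal.items()}
        a = _fixture_table({0: apical}, layer="apical")
        b = _fixture_table({0: basal}, layer="midbasal")
        return {"apical": a, "basal": b, "dz": dz, "tilt_truth": (shift / dz, 0.0)}

    if kind == "voronoi_geometry":
        rng = np.random.default_rng(params.get("seed", 0))
        n = params.get("n_cells", 16)
        half = params.get("half_um", 10.0)
        pts = rng.uniform(-half, half, (n, 2))
        ga = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        guard = np.column_stack([np.cos(ga), np.sin(ga)]) * half * 2.2
        seeds = np.vstack([pts, guard])
        mesh = _voronoi_mesh(seeds, n)
        polys = {cid: mesh.polygon(cid) for cid in mesh.cells}
        return {"cells": _fixture_table({0: polys}), "polygons": polys,
                "seeds": {cid: seeds[cid - 1] for cid in mesh.cells},
                "interior": sorted(set(mesh.cells) - mesh.border)}

    if kind == "rosette":
        n = params.get("n_cells", 6)
        radius = params.get("radius_um", 4.0)
        polys = {}
        for k in range(n):
            a0, a1 = 2 * np.pi * k / n, 2 * np.pi * (k + 1) / n
            arc = np.linspace(a0, a1, 5)
            pts = np.vstack([[0.0, 0.0], np.column_stack(
                [np.cos(arc), np.sin(arc)]) * radius])
            polys[k + 1] = pts
        return {"cells": _fixture_table({0: polys}), "centre": (0.0, 0.0), "n": n}

    raise ValueError(f"unknown fixture kind: {kind!r}")
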