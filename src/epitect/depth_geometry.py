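"""Apical/mid-basal cell matching and z-strain rates.

Cells tracked at two depths are matched one-to-one, then the strain-rate
machinery of :mod:`epitect.strain2d` is reused with depth standing in
for time: the basal layer plays "frame t", the apical layer "frame t+1"
and the layer separation Δz replaces Δt. The cell-shape term becomes
**wedging** (proportional size change per µm in z), the intercalation
term **interleaving**, the fitted domain translation **tilt** (xy µm per
z µm) and the fitted rotation **twist** (degrees per µm). Change is
measured basal → apical, so a cell narrower apically than basally
(bottle shape) has negative mean wedging.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strain2d import domain_strain_decomposition
from .tracking_io import build_adjacency

__all__ = ["LayerMatch", "ZGeometry", "match_layers", "z_strain_decomposition", "zgeometry_table"]


@dataclass
class LayerMatch:
    """One-to-one apical↔basal cell match for one frame."""

    frame: int
    mapping: dict[int, int]  # apical cell_id -> basal cell_id
    error_um: dict[int, float]  # prediction error per apical id
    ratio: dict[int, float]  # error / apical centroid distance used
    unmatched: list[int] = field(default_factory=list)
    warning: str = ""


def match_layers(
    apical: pd.DataFrame,
    basal: pd.DataFrame,
    seeds: dict[int, int],
    frame: int,
    adjacency=None,
    max_ratio: float = 0.25,
) -> LayerMatch:
    """Propagate apical↔basal matches outward from manual seed matches.

    For each unmatched apical cell adjacent to matched ones, the basal
    centroid is predicted by translating each matched neighbour's basal
    centroid by the apical centroid offset (averaged over neighbours);
    the nearest unclaimed basal centroid is accepted iff its distance to
    the prediction is within ``max_ratio`` of the apical centroid
    distance used. Propagation is a FIFO queue seeded in input order, so
    results are deterministic.
    """
    if len(seeds) < 3:
        raise ValueError("at least 3 seed matches are required")
    a = apical[(apical["frame"] == frame) & (apical["layer"] == "apical")].set_index("cell_id")
    b = basal[(basal["frame"] == frame) & (basal["layer"] == "midbasal")].set_index("cell_id")
    for sa, sb in seeds.items():
        if sa not in a.index or sb not in b.index:
            raise ValueError(f"seed match ({sa}, {sb}) refers to a missing cell")
    if adjacency is None:
        adjacency = build_adjacency(apical, frame, "apical")

    mapping = dict(seeds)
    error = {sa: 0.0 for sa in seeds}
    ratio = {sa: 0.0 for sa in seeds}
    claimed = set(seeds.values())
    b_ids = [i for i in b.index]
    b_xy = b[["x", "y"]].values.astype(float)

    queue = deque(mapping.keys())
    deferred: set[int] = set()
    while queue:
        src = queue.popleft()
        for cand in adjacency.neighbors(src):
            if cand in mapping or cand not in a.index:
                continue
            matched_nb = [n for n in adjacency.neighbors(cand) if n in mapping]
            if not matched_nb:
                continue
            cand_xy = a.loc[cand, ["x", "y"]].values.astype(float)
            preds, dists = [], []
            for n in matched_nb:
                n_xy = a.loc[n, ["x", "y"]].values.astype(float)
                nb_basal = b.loc[mapping[n], ["x", "y"]].values.astype(float)
                preds.append(nb_basal + (cand_xy - n_xy))
                dists.append(np.linalg.norm(cand_xy - n_xy))
            pred = np.mean(preds, axis=0)
            used_dist = float(np.mean(dists))
            free = [k for k, bid in enumerate(b_ids) if bid not in claimed]
            if not free:
                continue
            d = np.linalg.norm(b_xy[free] - pred, axis=1)
            k = int(np.argmin(d))
            err = float(d[k])
            if used_dist > 0 and err / used_dist <= max_ratio:
                bid = b_ids[free[k]]
                mapping[cand] = bid
                error[cand] = err
                ratio[cand] = err / used_dist
                claimed.add(bid)
                deferred.discard(cand)
                queue.append(cand)
            else:
                deferred.add(cand)
    unmatched = sorted(set(a.index) - set(mapping))
    warning = ""
    if unmatched:
        warning = f"{len(unmatched)} apical cells left unmatched"
    return LayerMatch(frame, mapping, error, ratio, unmatched, warning)


@dataclass
class ZGeometry:
    """Depth-resolved geometry of one focal-cell domain."""

    cell_id: int
    frame: int
    wedging: np.ndarray  # pp per µm
    interleaving: np.ndarray  # pp per µm
    tilt: np.ndarray  # xy µm per z µm
    twist_deg_um: float
    n_cells: int
    valid: bool
    flag: str = ""


def _stacked_two_frame(apical, basal, mapping, frame):
    """Pseudo movie: basal layer at frame 0, apical at frame 1, shared ids."""
    a = apical[(apical["frame"] == frame) & (apical["layer"] == "apical")]
    b = basal[(basal["frame"] == frame) & (basal["layer"] == "midbasal")]
    inv = {v: k for k, v in mapping.items()}
    rows = []
    for _, r in b.iterrows():
        if r["cell_id"] in inv:
            d = r.to_dict()
            d.update(frame=0, layer="z", cell_id=inv[r["cell_id"]])
            rows.append(d)
    for _, r in a.iterrows():
        if r["cell_id"] in mapping:
            d = r.to_dict()
            d.update(frame=1, layer="z")
            rows.append(d)
    return pd.DataFrame(rows)


def z_strain_decomposition(
    apical: pd.DataFrame,
    basal: pd.DataFrame,
    match: LayerMatch,
    focal_id: int,
    frame: int,
    dz_um: float,
    contact_tol_um: float = 0.44,
) -> ZGeometry:
    """Wedging/interleaving/tilt/twist for one matched focal domain.

    Runs the identical code path as the temporal strain decomposition on
    a two-"frame" stack (basal first, apical second) with Δt := Δz, so
    the z-strain additivity interleaving = total − wedging is inherited.
    """
    if focal_id not in match.mapping:
        return ZGeometry(focal_id, frame, np.zeros((2, 2)), np.zeros((2, 2)),
                         np.zeros(2), 0.0, 0, False, "focal cell unmatched")
    stack = _stacked_two_frame(apical, basal, match.mapping, frame)
    adj = {0: build_adjacency(stack, 0, "z", contact_tol_um),
           1: build_adjacency(stack, 1, "z", contact_tol_um)}
    res = domain_strain_decomposition(stack, adj, focal_id, 0, "z", dz_um)
    return ZGeometry(
        focal_id, frame, res.cell_shape, res.intercalation, res.translation,
        res.rotation_deg, res.n_cells, res.valid, res.flag,
    )


def zgeometry_table(
    apical: pd.DataFrame,
    basal: pd.DataFrame,
    match: LayerMatch,
    rframe,
    frame: int,
    dz_um: float,
) -> pd.DataFrame:
    """Per-cell ZGeometry rows with radial/circumferential projections."""
    a = apical[(apical["frame"] == frame) & (apical["layer"] == "apical")].set_index("cell_id")
    rows = []
    for cid in match.mapping:
        zg = z_strain_decomposition(apical, basal, match, cid, frame, dz_um)
        if not zg.valid:
            continue
        pos = a.loc[cid, ["x", "y"]].values.astype(float)
        if np.allclose(pos, rframe.origin(frame)):
            continue
        wp = rframe.project_tensor(zg.wedging, pos, frame)
        ip = rframe.project_tensor(zg.interleaving, pos, frame)
        tp = rframe.project_vector(zg.tilt, pos, frame)
        r_um, theta = rframe.radial_coords_of(pos, frame)
        rows.append({
            "cell_id": cid, "frame": frame, "r_um": r_um, "theta_deg": theta,
            "n_cells": zg.n_cells,
            "wedge_rad": wp.rad, "wedge_circ": wp.circ,
            "inter_rad": ip.rad, "inter_circ": ip.circ,
            "tilt_rad": tp.rad, "tilt_circ": tp.circ,
            "twist_deg_um": zg.twist_deg_um,
        })
    return pd.DataFrame(rows)
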