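"""Small-domain strain-rate tensors and their additive decomposition.

For a domain of a focal cell plus its first corona of neighbours,
tracked over a three-frame window, three symmetric 2x2 rate tensors are
computed (units: proportional change per minute):

* **T** — tissue strain rate, from the best-fit affine map of the domain
  centroid motions: T = sym(log Â)/Δt, with Â the least-squares linear
  map (plus translation) carrying window-start centroids to window-end
  centroids.
* **C** — cell-shape strain rate, the domain mean of the rotation-free
  log map between each cell's moment-ellipse at window start and its
  ellipse at window end, de-rotated by the domain rotation (polar factor
  of Â).
* **I = T − C** — intercalation strain rate, the continuous sliding of
  cells past one another.

The same machinery doubles as the z-strain engine (deformation per µm of
depth instead of per minute) — see :mod:`epitect.depth_geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import (
    fit_affine,
    polygon_second_moments,
    real_logm,
    polar_rotation,
    spd_log,
    spd_sqrt,
    spd_transport,
    sym,
)

__all__ = [
    "ShapeTensor",
    "DomainStrainResult",
    "shape_tensor",
    "domain_strain_decomposition",
    "strain_table",
    "accumulate_strain",
]


@dataclass
class ShapeTensor:
    """Best-fit-ellipse tensor of one cell: eigenvalues are semi-axes (µm)."""

    cell_id: int
    frame: int
    layer: str
    q: np.ndarray


def shape_tensor(polygon: np.ndarray) -> np.ndarray:
    """Q = 2·M^(1/2) of the polygon's area-normalised second moments.

    For an elliptical polygon the eigenvalues of Q equal the semi-axis
    lengths; for a w×h rectangle they are (w/√3, h/√3).
    """
    return 2.0 * spd_sqrt(polygon_second_moments(polygon))


@dataclass
class DomainStrainResult:
    """Strain-rate decomposition of one focal-cell domain at one frame."""

    cell_id: int
    frame: int
    layer: str
    n_cells: int
    tissue: np.ndarray
    cell_shape: np.ndarray
    intercalation: np.ndarray
    rotation_deg: float  # domain rotation rate, degrees per unit
    translation: np.ndarray  # domain translation rate, µm per unit
    valid: bool
    flag: str = ""

    def project(self, rframe, position=None, frame: int | None = None):
        """(rad, circ) of T, C, I at the focal position (dict of tuples)."""
        frame = self.frame if frame is None else frame
        return {
            "tissue": rframe.project_tensor(self.tissue, position, frame),
            "cell_shape": rframe.project_tensor(self.cell_shape, position, frame),
            "intercalation": rframe.project_tensor(self.intercalation, position, frame),
        }


def _invalid(cid, frame, layer, n, flag):
    z = np.zeros((2, 2))
    return DomainStrainResult(cid, frame, layer, n, z, z, z, 0.0, np.zeros(2), False, flag)


def domain_strain_decomposition(
    cells: pd.DataFrame,
    adjacency,
    focal_id: int,
    frame: int,
    layer: str,
    dt: float,
    placode_only: bool = True,
) -> DomainStrainResult:
    """Decompose local deformation around a focal cell at a frame.

    ``adjacency`` maps frame -> AdjacencyMap for the layer. The window is
    the three frames centred on ``frame`` when both neighbours exist in
    the data, otherwise a flagged two-frame forward/backward window.
    """
    sub = cells[cells["layer"] == layer]
    frames = sorted(int(f) for f in sub["frame"].unique())
    if frame not in frames:
        return _invalid(focal_id, frame, layer, 0, "frame absent")
    f0, f1 = frame - 1, frame + 1
    flag = ""
    if f0 not in frames or f1 not in frames:
        flag = "end window"
        if f1 in frames:
            f0 = frame
        elif f0 in frames:
            f1 = frame
        else:
            return _invalid(focal_id, frame, layer, 0, "isolated frame")
    span = (f1 - f0) * dt

    adj = adjacency[frame]
    domain = [focal_id] + adj.neighbors(focal_id)
    at = {f: sub[sub["frame"] == f].set_index("cell_id") for f in (f0, frame, f1)}
    if placode_only:
        pl = set(at[frame].index[at[frame]["is_placode"]])
        domain = [c for c in domain if c in pl]
    tracked = [c for c in domain if c in at[f0].index and c in at[f1].index]
    if focal_id not in at[frame].index:
        return _invalid(focal_id, frame, layer, len(tracked), "focal cell absent")
    if len(tracked) < 3:
        return _invalid(focal_id, frame, layer, len(tracked), "fewer than 3 tracked cells")

    x0 = at[f0].loc[tracked, ["x", "y"]].values.astype(float)
    x1 = at[f1].loc[tracked, ["x", "y"]].values.astype(float)
    # non-collinearity check on the start configuration
    s = np.linalg.svd(x0 - x0.mean(axis=0), compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        return _invalid(focal_id, frame, layer, len(tracked), "collinear centroids")

    a_hat, _b = fit_affine(x0, x1)
    if np.linalg.det(a_hat) <= 0:
        return _invalid(focal_id, frame, layer, len(tracked), "degenerate fitted map")
    log_a = real_logm(a_hat)
    tissue = sym(log_a) / span
    r_dom, _ = polar_rotation(a_hat)
    rotation = float(np.degrees(np.arctan2(r_dom[1, 0], r_dom[0, 0]))) / span
    translation = (x1.mean(axis=0) - x0.mean(axis=0)) / span

    rates = []
    for cid in tracked:
        m0 = polygon_second_moments(at[f0].loc[cid, "polygon"])
        m1 = polygon_second_moments(at[f1].loc[cid, "polygon"])
        m1p = r_dom.T @ m1 @ r_dom  # remove the domain rotation
        f_map = spd_transport(m0, m1p)
        rates.append(spd_log(f_map) / span)
    cell_shape = np.mean(rates, axis=0)
    inter = tissue - cell_shape
    return DomainStrainResult(
        focal_id, frame, layer, len(tracked), tissue, cell_shape, inter,
        rotation, translation, True, flag,
    )


def strain_table(
    cells: pd.DataFrame,
    adjacency,
    rframe,
    layer: str,
    dt: float,
    frames=None,
) -> pd.DataFrame:
    """Per-(focal cell, frame) decomposition with radial projections.

    Returns one row per valid placode-cell domain with tensor components
    and rad/circ projections of T, C and I at the focal centroid.
    """
    sub = cells[cells["layer"] == layer]
    if frames is None:
        frames = sorted(int(f) for f in sub["frame"].unique())
    rows = []
    for f in frames:
        here = sub[(sub["frame"] == f) & sub["is_placode"]]
        for cid, x, y, tmin in zip(here["cell_id"], here["x"], here["y"], here["time_min"]):
            res = domain_strain_decomposition(cells, adjacency, cid, f, layer, dt)
            if not res.valid:
                continue
            pos = np.array([x, y])
            if np.allclose(pos, rframe.origin(f)):
                continue
            proj = res.project(rframe, pos, f)
            r_um, theta = rframe.radial_coords_of(pos, f)
            rows.append({
                "cell_id": cid, "frame": f, "time_min": tmin, "layer": layer,
                "n_cells": res.n_cells, "r_um": r_um, "theta_deg": theta,
                "t_xx": res.tissue[0, 0], "t_xy": res.tissue[0, 1], "t_yy": res.tissue[1, 1],
                "c_xx": res.cell_shape[0, 0], "c_xy": res.cell_shape[0, 1],
                "c_yy": res.cell_shape[1, 1],
                "i_xx": res.intercalation[0, 0], "i_xy": res.intercalation[0, 1],
                "i_yy": res.intercalation[1, 1],
                "t_rad": proj["tissue"].rad, "t_circ": proj["tissue"].circ,
                "c_rad": proj["cell_shape"].rad, "c_circ": proj["cell_shape"].circ,
                "i_rad": proj["intercalation"].rad, "i_circ": proj["intercalation"].circ,
                "flag": res.flag,
            })
    return pd.DataFrame(rows)


def accumulate_strain(rates, dt: float):
    """Cumulative strain ratio exp(Σ rate·dt) from a mean-rate series.

    ``rates`` is a 1D sequence of per-time-point mean strain rates.
    NaN entries are excluded from the integral (the interval contributes
    nothing) and reported in the returned flag array.

    Returns (ratio array, gap-flag boolean array); ratio before the first
    sample is implicitly 1.
    """
    rates = np.asarray(rates, float)
    gaps = np.isnan(rates)
    contrib = np.where(gaps, 0.0, rates) * dt
    return np.exp(np.cumsum(contrib)), gaps
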