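"""Mobile pit-centred radial coordinate system.

The placode is analysed in local radial/circumferential axes anchored at
the invagination pit. The origin tracks the mean centroid of the pit
cells through time; the circumferential angle is zero towards posterior
and increases anticlockwise for a left-side placode and clockwise for a
right-side one, so mirrored placodes overlay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RadialFrame:
    """Per-frame pit origin plus the posterior axis and handedness."""

    origins: dict[int, np.ndarray]
    posterior: np.ndarray
    side: str = "left"
    interpolated: set[int] = field(default_factory=set)

    def __post_init__(self):
        p = np.asarray(self.posterior, float)
        n = np.linalg.norm(p)
        if n == 0:
            raise ValueError("posterior vector must be nonzero")
        self.posterior = p / n
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def _sign(self) -> float:
        return 1.0 if self.side == "left" else -1.0

    def origin(self, frame: int) -> np.ndarray:
        return self.origins[int(frame)]

    def radial_coords_of(self, point, frame: int) -> tuple[float, float]:
        """(r µm, θ degrees in [0, 360)) of a point in this frame."""
        d = np.asarray(point, float) - self.origin(frame)
        r = float(np.linalg.norm(d))
        if r == 0:
            return 0.0, 0.0
        e = self.posterior
        cross = e[0] * d[1] - e[1] * d[0]
        theta = np.degrees(np.arctan2(cross, np.dot(d, e))) * self._sign
        return r, float(theta % 360.0)

    def unit_vectors(self, position, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(e_r, e_c) at a position: radial away from the pit, and the
        circumferential direction of increasing θ."""
        d = np.asarray(position, float) - self.origin(frame)
        r = np.linalg.norm(d)
        if r == 0:
            raise ValueError("radial direction undefined at the origin")
        e_r = d / r
        e_c = self._sign * np.array([-e_r[1], e_r[0]])
        return e_r, e_c

    def radial_angle(self, position, frame: int) -> float:
        """Absolute angle (degrees) of the local radial direction in image coords."""
        e_r, _ = self.unit_vectors(position, frame)
        return float(np.degrees(np.arctan2(e_r[1], e_r[0])))

    def project_tensor(self, e: np.ndarray, position, frame: int) -> "RadialProjection":
        e_r, e_c = self.unit_vectors(position, frame)
        e = np.asarray(e, float)
        return RadialProjection(float(e_r @ e @ e_r), float(e_c @ e @ e_c))

    def project_vector(self, v, position, frame: int) -> "RadialProjection":
        e_r, e_c = self.unit_vectors(position, frame)
        v = np.asarray(v, float)
        return RadialProjection(float(v @ e_r), float(v @ e_c))

    def classify_orientation(self, axis, position, frame: int) -> str:
        """"radial" iff the acute angle to the local radial axis is < 45°;
        a tie at exactly 45° classifies as circumferential."""
        axis = np.asarray(axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        e_r, _ = self.unit_vectors(position, frame)
        c = abs(float(axis @ e_r)) / n
        ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
        return "radial" if ang < 45.0 else "circumferential"

    def to_json(self, path) -> None:
        d = {
            "posterior": self.posterior.tolist(),
            "side": self.side,
            "origins": {str(f): o.tolist() for f, o in self.origins.items()},
            "interpolated": sorted(int(f) for f in self.interpolated),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RadialFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            origins={int(f): np.array(o, float) for f, o in d["origins"].items()},
            posterior=np.array(d["posterior"], float),
            side=d["side"],
            interpolated=set(d.get("interpolated", [])),
        )


from typing import NamedTuple


class RadialProjection(NamedTuple):
    """Radial and circumferential components of a projected quantity."""

    rad: float
    circ: float


def build_mobile_frame(
    pit_cells,
    cells: pd.DataFrame,
    meta=None,
    layer: str = "apical",
    posterior=(1.0, 0.0),
    side: str = "left",
) -> RadialFrame:
    """Track the pit origin as the mean centroid of the pit cells.

    Frames where no pit cell is tracked get a linearly interpolated (or
    edge-extrapolated) origin and are flagged in ``interpolated``.
    """
    pit_cells = list(pit_cells)
    if not pit_cells:
        raise ValueError("pit cell list is empty")
    if meta is not None:
        posterior = meta.posterior
        side = meta.side
    sub = cells[(cells["layer"] == layer)]
    frames = sorted(int(f) for f in sub["frame"].unique())
    known_f, known_xy = [], []
    for f in frames:
        pit = sub[(sub["frame"] == f) & (sub["cell_id"].isin(pit_cells))]
        if len(pit):
            known_f.append(f)
            known_xy.append(pit[["x", "y"]].values.mean(axis=0))
    if not known_f:
        raise ValueError("no pit cell tracked in any frame")
    known_xy = np.array(known_xy)
    origins, interp = {}, set()
    for f in frames:
        if f in known_f:
            origins[f] = known_xy[known_f.index(f)]
        else:
            interp.add(f)
            if len(known_f) == 1:
                origins[f] = known_xy[0]
            else:
                # linear interpolation, linear extrapolation at the ends
                i = np.searchsorted(known_f, f)
                i0 = max(0, min(i - 1, len(known_f) - 2))
                f0, f1 = known_f[i0], known_f[i0 + 1]
                w = (f - f0) / (f1 - f0)
                origins[f] = known_xy[i0] * (1 - w) + known_xy[i0 + 1] * w
    return RadialFrame(origins=origins, posterior=np.asarray(posterior, float),
                       side=side, interpolated=interp)
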