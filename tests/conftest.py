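"""Shared fixtures: one fully generated synthetic placode per session plus
small geometric helpers used across modules."""

import numpy as np
import pytest

from epitect.radial_frame import RadialFrame, build_mobile_frame
from epitect.synthetic import PlacodeParams, generate_placode
from epitect.tracking_io import CellRecord, build_adjacency, build_adjacency_over, make_cell_table


class PlacodeBundle:
    """A generated placode with the standard analysis products attached."""

    def __init__(self, placode):
        self.placode = placode
        self.params = placode.params
        self.truth = placode.truth
        self.cells = placode.apical_cells()
        self.basal = placode.basal_cells()
        self.meta = placode.metadata()
        self.adjacency = build_adjacency_over(self.cells, "apical")
        self.rframe = build_mobile_frame(self.meta.pit_cell_ids, self.cells, self.meta)


@pytest.fixture(scope="session")
def placode():
    """The default study-condition placode (seed 0) with analysis products."""
    return PlacodeBundle(generate_placode(PlacodeParams(seed=0)))


@pytest.fixture(scope="session")
def small_placode():
    """A short 3-frame placode for raster/IO tests."""
    return generate_placode(PlacodeParams(seed=0, n_frames=3, n_circ_gains=0,
                                          n_rad_gains=0, n_rosettes=0))


@pytest.fixture
def origin_frame():
    """A static radial frame centred far away, so local axes are near-uniform."""
    return RadialFrame(origins={0: np.array([0.0, 0.0])}, posterior=(1.0, 0.0), side="left")


def make_wheel(n, radius=8.0, centre=(0.0, 0.0), frame=0):
    """Central regular n-gon plus n outer neighbours sharing its edges.

    Returns (cell table, adjacency); the central cell has id 1 and its
    interfaces have equal angular spans, so Fourier recovery is exact.
    """
    c = np.asarray(centre, float)
    ang = 2 * np.pi * np.arange(n) / n
    inner = np.column_stack([np.cos(ang), np.sin(ang)]) * radius + c
    recs = [CellRecord("wheel", frame, 0.0, "apical", 1, inner)]
    for j in range(n):
        v0, v1 = inner[j], inner[(j + 1) % n]
        quad = np.array([v0, v1, (v1 - c) * 1.6 + c, (v0 - c) * 1.6 + c])
        recs.append(CellRecord("wheel", frame, 0.0, "apical", j + 2, quad))
    cells = make_cell_table(recs)
    return cells, build_adjacency(cells, frame, "apical")
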