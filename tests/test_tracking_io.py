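"""Cell table I/O, label-image loading, adjacency and track filters."""

import numpy as np
import pandas as pd
import pytest

from epitect._geometry import polygon_area
from epitect.synthetic import generate_fixture
from epitect.tracking_io import (
    CellRecord,
    build_adjacency,
    filter_tracks,
    load_tracked_layers,
    make_cell_table,
    read_cells_csv,
    write_cells_csv,
)


def _row_of_squares(n=3, side=2.0):
    recs = []
    for i in range(n):
        sq = np.array([[0, 0], [side, 0], [side, side], [0, side]]) + [i * side, 0.0]
        recs.append(CellRecord("m", 0, 0.0, "apical", i + 1, sq))
    return make_cell_table(recs)


def test_duplicate_cell_id_in_frame_rejected():
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    recs = [CellRecord("m", 0, 0.0, "apical", 1, sq), CellRecord("m", 0, 0.0, "apical", 1, sq + 5)]
    with pytest.raises(ValueError, match="duplicate"):
        make_cell_table(recs)


def test_csv_round_trip_is_exact(tmp_path, small_placode):
    cells = small_placode.apical_cells()
    path = tmp_path / "cells.csv"
    write_cells_csv(cells, path)
    back = read_cells_csv(path)
    assert list(back["cell_id"]) == list(cells["cell_id"])
    for a, b in zip(cells["polygon"], back["polygon"]):
        assert np.array_equal(np.asarray(a, float), b)


def test_adjacency_of_three_squares_in_a_row():
    adj = build_adjacency(_row_of_squares(3), 0, "apical")
    assert sorted(adj.pairs()) == [(1, 2), (2, 3)]
    assert adj.length(1, 2) == pytest.approx(2.0)
    assert adj.neighbors(2) == [1, 3]


def test_hexagonal_interior_cell_has_six_neighbours():
    fx = generate_fixture("hex_lattice", rows=5, cols=5)
    adj = build_adjacency(fx["cells"], 0, "apical")
    centre = 13  # middle of the 5x5 block
    assert len(adj.neighbors(centre)) == 6
    # interface lengths cannot exceed the perimeter
    from shapely.geometry import Polygon

    for cid in (centre,):
        per = Polygon(fx["polygons"][cid]).length
        assert sum(adj.length(cid, nb) for nb in adj.neighbors(cid)) <= per + 1e-6


def test_adjacency_matches_generator_contact_graph(placode):
    for frame in (0, 10):
        got = {frozenset(p) for p in placode.adjacency[frame].pairs()}
        assert got == placode.truth.contacts[frame]


def test_label_images_recover_polygon_areas(small_placode):
    meta = small_placode.metadata()
    stack = [small_placode.render_labels(f, "apical") for f in range(3)]
    links = pd.DataFrame(
        [(f, cid, cid) for f in range(3) for cid in sorted(small_placode.apical[f].cells)],
        columns=["frame", "label", "cell_id"],
    )
    table = load_tracked_layers(stack, links, meta)
    truth = {cid: polygon_area(small_placode.apical[0].polygon(cid))
             for cid in small_placode.apical[0].cells}
    sub = table[table["frame"] == 0]
    errs = np.array([abs(polygon_area(p) - truth[c]) / truth[c]
                     for c, p in zip(sub["cell_id"], sub["polygon"])])
    assert errs.mean() < 0.02  # rasterisation error at 0.22 µm/px
    assert errs.max() < 0.05


def test_missing_frame_in_links_raises(small_placode):
    meta = small_placode.metadata()
    stack = [small_placode.render_labels(f, "apical") for f in range(3)]
    links = pd.DataFrame(
        [(f, cid, cid) for f in (0, 2) for cid in sorted(small_placode.apical[f].cells)],
        columns=["frame", "label", "cell_id"],
    )
    with pytest.raises(ValueError, match="missing frame"):
        load_tracked_layers(stack, links, meta)


def test_truncated_track_is_flagged():
    img0 = np.zeros((30, 30), np.uint16)
    img0[2:12, 2:12] = 1
    img0[2:12, 14:24] = 2
    img1 = img0.copy()
    img2 = img0.copy()
    img2[img2 == 2] = 0  # label 2 vanishes at frame 2
    from epitect.tracking_io import RunMetadata

    links = pd.DataFrame([(0, 1, 1), (0, 2, 2), (1, 1, 1), (1, 2, 2), (2, 1, 1)],
                         columns=["frame", "label", "cell_id"])
    table = load_tracked_layers([img0, img1, img2], links, RunMetadata())
    assert set(table.loc[table["cell_id"] == 2, "frame"]) == {0, 1}
    assert table.loc[table["cell_id"] == 2, "track_gap"].all()
    assert not table.loc[table["cell_id"] == 1, "track_gap"].any()


def test_filter_tracks_by_lineage_and_velocity():
    rng = np.random.default_rng(0)
    recs = []
    for f in range(4):
        for i in range(9):
            x, y = (i % 3) * 2.0, (i // 3) * 2.0
            sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2]]) + [x, y]
            jump = 10.0 * f if i == 4 else 0.0  # cell 5 teleports
            if i == 8 and f >= 2:
                continue  # cell 9 is a short track
            recs.append(CellRecord("m", f, 2.0 * f, "apical", i + 1, sq + [jump, 0]))
    cells = make_cell_table(recs)
    filtered, log = filter_tracks(cells, min_lineage=3, max_rel_velocity_um_min=3.0)
    reasons = dict(zip(log["cell_id"], log["reason"]))
    assert reasons[9] == "lineage"
    assert reasons[5] == "relative velocity"
    assert set(filtered["cell_id"]) == {1, 2, 3, 4, 6, 7, 8}


def test_clean_placode_passes_filters(placode):
    filtered, log = filter_tracks(placode.cells,
                                  frame_interval_min=placode.meta.frame_interval_min)
    assert len(log) == 0
    assert len(filtered) == len(placode.cells)


def test_all_cells_filtered_raises(small_placode):
    cells = small_placode.apical_cells()
    with pytest.raises(ValueError, match="review thresholds"):
        filter_tracks(cells, area_range_um2=(1e5, 1e6))
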