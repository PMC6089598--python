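"""Generator self-consistency: determinism, validity, closed analysis loops."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from epitect.intercalation import detect_exchanges
from epitect.radial_frame import build_mobile_frame
from epitect.strain2d import domain_strain_decomposition
from epitect.synthetic import PlacodeParams, generate_fixture, generate_placode
from epitect.tracking_io import build_adjacency_over, write_cells_csv


def test_same_seed_gives_identical_outputs(tmp_path):
    paths = []
    for k in range(2):
        placode = generate_placode(PlacodeParams(seed=5, n_frames=4))
        p = tmp_path / f"cells{k}.csv"
        write_cells_csv(placode.apical_cells(), p)
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    img_a = generate_placode(PlacodeParams(seed=5, n_frames=4)).render_myosin(1)
    img_b = generate_placode(PlacodeParams(seed=5, n_frames=4)).render_myosin(1)
    assert np.array_equal(img_a, img_b)


def test_different_seeds_differ():
    a = generate_placode(PlacodeParams(seed=1, n_frames=2)).apical_cells()
    b = generate_placode(PlacodeParams(seed=2, n_frames=2)).apical_cells()
    assert not np.allclose(sorted(a["x"]), sorted(b["x"]))


def test_all_polygons_stay_simple_and_positive(placode):
    for meshes in (placode.placode.apical, placode.placode.basal):
        for mesh in meshes.values():
            for cid in mesh.cells:
                poly = Polygon(mesh.polygon(cid))
                assert poly.is_valid and poly.area > 0


def test_static_params_give_static_movie():
    placode = generate_placode(PlacodeParams(
        seed=3, n_frames=4, constriction_rate_min=0.0, n_circ_gains=0, n_rad_gains=0,
        n_rosettes=0, drift_um_frame=(0.0, 0.0)))
    cells = placode.apical_cells()
    adjacency = build_adjacency_over(cells, "apical")
    f0 = cells[cells["frame"] == 0].set_index("cell_id")
    f3 = cells[cells["frame"] == 3].set_index("cell_id")
    for cid in f0.index:
        np.testing.assert_allclose(f0.loc[cid, ["x", "y"]].values.astype(float),
                                   f3.loc[cid, ["x", "y"]].values.astype(float), atol=1e-12)
    meta = placode.metadata()
    rframe = build_mobile_frame(meta.pit_cell_ids, cells, meta)
    res = domain_strain_decomposition(cells, adjacency, meta.pit_cell_ids[0], 1, "apical",
                                      meta.frame_interval_min)
    assert res.valid
    assert np.abs(res.tissue).max() < 1e-12
    assert np.abs(res.cell_shape).max() < 1e-12


def test_pure_circumferential_script_is_fully_detected():
    placode = generate_placode(PlacodeParams(
        seed=4, n_circ_gains=10, n_rad_gains=0, n_rosettes=0))
    cells = placode.apical_cells()
    meta = placode.metadata()
    adjacency = build_adjacency_over(cells, "apical")
    rframe = build_mobile_frame(meta.pit_cell_ids, cells, meta)
    events, _ = detect_exchanges(adjacency, cells, rframe)
    scripted = [e for e in placode.truth.events if e["scripted"]]
    assert len(scripted) == 10
    assert all(e["orientation"] == "circumferential" for e in scripted)
    detected = sorted((e.frame_gain, e.gaining_pair) for e in events)
    truth = sorted((e["frame_gain"], tuple(e["gaining"])) for e in placode.truth.events)
    assert detected == truth


def test_uniform_constriction_accumulates_exponentially():
    # a near-flat constriction profile: every cell loses area at ~1%/min,
    # so over 18 min the cell-shape area ratio is ~exp(-0.18)
    placode = generate_placode(PlacodeParams(
        seed=2, constriction_scale_um=500.0, n_circ_gains=0, n_rad_gains=0,
        n_rosettes=0, n_frames=11, t0_frame=1))
    cells = placode.apical_cells()
    meta = placode.metadata()
    adjacency = build_adjacency_over(cells, "apical")
    ratios = []
    mesh0, mesh9 = placode.apical[1], placode.apical[10]
    for cid, rate in placode.truth.area_rate_min.items():
        if cid in mesh0.border:
            continue
        a0 = Polygon(mesh0.polygon(cid)).area
        a1 = Polygon(mesh9.polygon(cid)).area
        ratios.append(a1 / a0)
    assert np.mean(ratios) == pytest.approx(np.exp(-0.18), rel=0.02)
    # and the strain machinery measures the same cumulative cell-shape strain
    rframe = build_mobile_frame(meta.pit_cell_ids, cells, meta)
    from epitect.strain2d import strain_table

    table = strain_table(cells, adjacency, rframe, "apical", meta.frame_interval_min,
                         frames=range(1, 11))
    area_rate = table.groupby("frame")[["c_rad", "c_circ"]].mean().sum(axis=1)
    measured = np.exp((area_rate * meta.frame_interval_min).iloc[:-1].sum())
    assert measured == pytest.approx(np.exp(-0.18), rel=0.05)


def test_fixture_kinds_and_unknown_kind():
    assert set(generate_fixture("frusta")) >= {"apical", "basal", "wedging_truth"}
    with pytest.raises(ValueError, match="unknown fixture"):
        generate_fixture("nonsense")


def test_hex_lattice_tiles_exactly():
    fx = generate_fixture("hex_lattice", rows=3, cols=3)
    from epitect.tracking_io import build_adjacency

    adj = build_adjacency(fx["cells"], 0, "apical")
    # the central cell of a 3x3 block touches all 6 surrounding cells
    assert len(adj.neighbors(5)) == 6


def test_written_truth_is_json_round_trippable(tmp_path, small_placode):
    small_placode.write_dir(tmp_path / "out")
    import json

    with open(tmp_path / "out" / "truth.json") as fh:
        truth = json.load(fh)
    assert set(truth) >= {"pit_path", "events", "contacts", "matches"}
    import tifffile

    labels = tifffile.imread(tmp_path / "out" / "labels_apical.tif")
    assert labels.shape[0] == 3 and labels.max() > 0
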