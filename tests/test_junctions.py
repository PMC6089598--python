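"""Voronoi-referenced junction signatures of active shortening."""

import numpy as np
import pandas as pd
import pytest

from epitect.intercalation import detect_exchanges
from epitect.junctions import (
    endpair_elongation,
    junction_deviations,
    junction_metrics_table,
    voronoi_reference,
)
from epitect.radial_frame import RadialFrame, build_mobile_frame
from epitect.synthetic import PlacodeParams, generate_fixture, generate_placode
from epitect.tracking_io import build_adjacency, build_adjacency_over


def _deviations_of_geometry(fx):
    cells = fx["cells"]
    adj = build_adjacency(cells, 0, "apical")
    polys = {cid: np.asarray(p, float) for cid, p in zip(cells["cell_id"], cells["polygon"])}
    ref = voronoi_reference(fx["seeds"])
    interior = set(fx["interior"])
    out = []
    for a, b in adj.pairs():
        if a in interior and b in interior and ref.has_edge(a, b):
            out.append(junction_deviations((a, b), polys, adj, ref))
    return out


@pytest.mark.parametrize("seed", range(10))
def test_self_tessellation_has_zero_deviations(seed):
    devs = _deviations_of_geometry(generate_fixture("voronoi_geometry", seed=seed))
    assert devs
    for d in devs:
        assert abs(d.length_deviation_um) < 1e-9
        if np.isfinite(d.angle_deviation_deg):
            assert abs(d.angle_deviation_deg) < 1e-6


def test_collinear_centroids_rejected():
    with pytest.raises(ValueError, match="collinear"):
        voronoi_reference({i: np.array([float(i), 0.0]) for i in range(5)})


def test_shortened_junction_has_negative_deviations():
    fx = generate_fixture("voronoi_geometry", seed=1)
    cells = fx["cells"]
    polys = {cid: np.asarray(p, float) for cid, p in zip(cells["cell_id"], cells["polygon"])}
    adj = build_adjacency(cells, 0, "apical")
    ref = voronoi_reference(fx["seeds"])
    interior = set(fx["interior"])
    pair = next((a, b) for a, b in adj.pairs()
                if a in interior and b in interior and ref.has_edge(a, b)
                and adj.length(a, b) > 1.5)
    base = junction_deviations(pair, polys, adj, ref)
    # pull the junction's two end vertices towards its midpoint by 30%
    line = adj.polyline(*pair)
    coords = np.asarray(line.coords)
    p0, p1 = coords[0], coords[-1]
    mid = (p0 + p1) / 2.0
    moved = {}
    for cid, poly in polys.items():
        q = poly.copy()
        for old, new in ((p0, mid + (p0 - mid) * 0.7), (p1, mid + (p1 - mid) * 0.7)):
            d = np.linalg.norm(q - old, axis=1)
            q[d < 1e-9] = new
        moved[cid] = q
    from epitect.tracking_io import CellRecord, make_cell_table

    cells2 = make_cell_table(
        CellRecord("m", 0, 0.0, "apical", cid, q) for cid, q in moved.items())
    adj2 = build_adjacency(cells2, 0, "apical")
    short = junction_deviations(pair, moved, adj2, ref)
    assert short.length_deviation_um < base.length_deviation_um - 0.1
    assert short.angle_deviation_deg < base.angle_deviation_deg - 1.0


def test_endpair_elongation_signs(origin_frame):
    rf = RadialFrame(origins={0: np.array([0.0, 0.0])}, posterior=(1, 0), side="left")
    # a cell due radial (+y from origin... position (0, 10)): circ axis is x
    rect_circ = np.array([[-2, 9], [2, 9], [2, 11], [-2, 11]], float)
    assert endpair_elongation([7], {7: rect_circ}, rf, 0) == pytest.approx(np.log(2), rel=1e-6)
    rect_rad = np.array([[-1, 8], [1, 8], [1, 12], [-1, 12]], float)
    assert endpair_elongation([7], {7: rect_rad}, rf, 0) == pytest.approx(-np.log(2), rel=1e-6)
    square = np.array([[-1, 9], [1, 9], [1, 11], [-1, 11]], float)
    assert endpair_elongation([7], {7: square}, rf, 0) == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def contractile_placode():
    """Placode with tissue-wide active circumferential junction shortening."""
    placode = generate_placode(PlacodeParams(seed=1, circ_shrink_rate_min=0.01))
    cells = placode.apical_cells()
    meta = placode.metadata()
    adjacency = build_adjacency_over(cells, "apical")
    rframe = build_mobile_frame(meta.pit_cell_ids, cells, meta)
    events, _ = detect_exchanges(adjacency, cells, rframe)
    return placode, cells, meta, adjacency, rframe, events


def _metrics(placode_bits, frames):
    placode, cells, meta, adjacency, rframe, events = placode_bits
    tables = []
    for f in frames:
        tables.append(junction_metrics_table(cells, adjacency, rframe, events, f,
                                             frame_interval_min=meta.frame_interval_min))
    return pd.concat(tables, ignore_index=True)


def test_t1_junction_status_and_lead_time(contractile_placode):
    placode, cells, meta, adjacency, rframe, events = contractile_placode
    sample_frames = sorted({e.frame_gain - 2 for e in events if e.frame_gain >= 2})
    tab = _metrics(contractile_placode, sample_frames)
    t1 = tab[tab["status"] == "T1"]
    assert len(t1) > 0
    assert (t1["time_to_exchange_min"] == -4.0).all()  # nearest sample to -3 min


def test_active_shrinkage_signature_ordering(contractile_placode):
    placode, cells, meta, adjacency, rframe, events = contractile_placode
    sample_frames = sorted({e.frame_gain - 2 for e in events if e.frame_gain >= 2})
    tab = _metrics(contractile_placode, sample_frames)
    circ_t1 = tab[(tab["status"] == "T1") & (tab["orientation"] == "circumferential")]
    circ_base = tab[(tab["status"] == "baseline") & (tab["orientation"] == "circumferential")]
    rad_base = tab[(tab["status"] == "baseline") & (tab["orientation"] == "radial")]
    assert len(circ_t1) >= 5 and len(circ_base) >= 30 and len(rad_base) >= 30
    m_t1 = circ_t1["length_deviation_um"].mean()
    m_cb = circ_base["length_deviation_um"].mean()
    m_rb = rad_base["length_deviation_um"].mean()
    assert m_t1 < m_cb < m_rb


def test_baseline_metrics_are_stationary(contractile_placode):
    early = _metrics(contractile_placode, [4])
    late = _metrics(contractile_placode, [14])
    for tab in (early, late):
        tab.drop(tab[tab["status"] != "baseline"].index, inplace=True)
    d_len = abs(early["length_deviation_um"].mean() - late["length_deviation_um"].mean())
    assert d_len < 0.25  # µm; no drift of the neutral-geometry offset
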