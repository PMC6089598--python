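"""Neighbour-exchange detection, gain statistics and rosette counting."""

import numpy as np
import pytest

from epitect.intercalation import (
    count_rosettes,
    cumulative_gain_ratio,
    detect_exchanges,
    productive_gain_rate,
)
from epitect.radial_frame import RadialFrame
from epitect.synthetic import generate_fixture
from epitect.tracking_io import build_adjacency_over


def _far_frame():
    # radial frame with a distant origin so the quartet's local axes are uniform
    return RadialFrame(origins={f: np.array([100.0, 0.0]) for f in range(10)},
                       posterior=(1.0, 0.0), side="left")


def test_quartet_t1_yields_one_classified_event():
    fx = generate_fixture("t1_quartet", gain_axis_deg=90.0, flip_frame=2, n_frames=5)
    adjacency = build_adjacency_over(fx["cells"], "apical")
    events, log = detect_exchanges(adjacency, fx["cells"], _far_frame())
    assert len(events) == 1
    ev = events[0]
    assert ev.frame_gain == 2 and ev.frame_loss == 1
    assert ev.losing_pair == tuple(sorted(fx["losing"]))
    assert ev.gaining_pair == tuple(sorted(fx["events"][0]["gaining"]))
    # gain axis vertical = circumferential for an origin far along +x
    assert ev.orientation == "circumferential"


def test_t1_and_its_reversal_cancel():
    fx = generate_fixture("t1_quartet", gain_axis_deg=90.0, flip_frame=2,
                          reverse_frame=5, n_frames=8)
    adjacency = build_adjacency_over(fx["cells"], "apical")
    events, _ = detect_exchanges(adjacency, fx["cells"], _far_frame())
    assert len(events) == 2
    orients = sorted(e.orientation for e in events)
    assert orients == ["circumferential", "radial"]
    series = productive_gain_rate(events, adjacency)
    assert series["cum_circ"].iloc[-1] == 1
    assert series["cum_rad"].iloc[-1] == 1
    assert abs(series["cum_productive"].iloc[-1]) < 1e-9


def test_scripted_placode_events_recovered_exactly(placode):
    events, log = detect_exchanges(placode.adjacency, placode.cells, placode.rframe)
    detected = sorted((e.frame_gain, e.gaining_pair, e.orientation) for e in events)
    truth = sorted((e["frame_gain"], tuple(e["gaining"]), e["orientation"])
                   for e in placode.truth.events)
    assert detected == truth
    scripted = [e for e in placode.truth.events if e["scripted"]]
    n_circ = sum(1 for e in scripted if e["orientation"] == "circumferential")
    n_rad = sum(1 for e in scripted if e["orientation"] == "radial")
    assert (n_circ, n_rad) == (placode.params.n_circ_gains, placode.params.n_rad_gains)


def test_losing_pairs_identified_for_scripted_events(placode):
    events, _ = detect_exchanges(placode.adjacency, placode.cells, placode.rframe)
    by_gain = {(e.frame_gain, e.gaining_pair): e for e in events}
    for t in placode.truth.events:
        if t["scripted"]:
            ev = by_gain[(t["frame_gain"], tuple(t["gaining"]))]
            assert ev.losing_pair == tuple(t["losing"])


def test_productive_gain_arithmetic():
    from epitect.intercalation import NeighbourExchangeEvent
    from epitect.tracking_io import AdjacencyMap

    adj = {}
    for f in (0, 1):
        a = AdjacencyMap(f, "apical")
        for i in range(100):  # 100 tracked interfaces
            a.add(i, 1000 + i, 1.0)
        adj[f] = a
    mk = lambda o, i: NeighbourExchangeEvent(0, None, 1, (2000 + i, 3000 + i),
                                             np.array([1.0, 0]), o, np.zeros(2))
    events = [mk("circumferential", i) for i in range(3)] + [mk("radial", 99)]
    series = productive_gain_rate(events, adj)
    assert series["productive"].iloc[0] == pytest.approx((3 - 1) / 50)
    assert cumulative_gain_ratio(series) == pytest.approx(np.exp(0.04))


def test_constant_rate_accumulates_linearly():
    from epitect.intercalation import NeighbourExchangeEvent
    from epitect.tracking_io import AdjacencyMap

    adj = {}
    for f in range(6):
        a = AdjacencyMap(f, "apical")
        for i in range(40):
            a.add(i, 1000 + i, 1.0)
        adj[f] = a
    events = [NeighbourExchangeEvent(f, None, f + 1, (5000 + f, 6000 + f),
                                     np.array([1.0, 0]), "circumferential", np.zeros(2))
              for f in range(5)]
    series = productive_gain_rate(events, adj)
    assert series["cum_productive"].iloc[-1] == pytest.approx(5 / 20)


def test_zero_interface_step_is_flagged():
    from epitect.tracking_io import AdjacencyMap

    adj = {0: AdjacencyMap(0, "apical"), 1: AdjacencyMap(1, "apical")}
    series = productive_gain_rate([], adj)
    assert series["flag"].iloc[0] == "no interfaces"
    assert np.isnan(series["productive"].iloc[0])


def test_wedge_rosette_and_hexagonal_null():
    fx = generate_fixture("rosette", n_cells=6)
    rosettes = count_rosettes(fx["cells"], 0, min_cells=5)
    assert len(rosettes) == 1
    assert rosettes[0][1] == 6
    np.testing.assert_allclose(rosettes[0][0], [0.0, 0.0], atol=1e-9)

    hexes = generate_fixture("hex_lattice", rows=5, cols=5)
    assert count_rosettes(hexes["cells"], 0, min_cells=5) == []
    # every interior vertex of a hexagonal lattice is exactly 3-way
    assert count_rosettes(hexes["cells"], 0, min_cells=4) == []


def test_scripted_rosettes_counted_exactly(placode):
    frame = placode.params.rosette_frame
    rosettes = count_rosettes(placode.cells, frame)
    truth = placode.truth.rosettes
    assert sorted(r[1] for r in rosettes) == sorted(r["n"] for r in truth)
    got = sorted(tuple(np.round(r[0], 1)) for r in rosettes)
    want = sorted(tuple(np.round(r["position"], 1)) for r in truth)
    for g, w in zip(got, want):
        assert np.linalg.norm(np.array(g) - np.array(w)) < 0.5
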