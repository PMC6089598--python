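# epitect

Radial tissue-tectonics morphometrics for epithelial placodes.

During tube budding — the canonical example being the early *Drosophila*
salivary-gland placode — a roughly circular patch of ~100 epithelial
cells bends and invaginates through a focal pit at its dorsal-posterior
corner. `epitect` quantifies the cell behaviours that drive this from
segmented, tracked time-lapse movies:

- a **mobile radial coordinate system** anchored on the pit, so every
  oriented measure can be expressed as a radial ("towards/away from the
  pit") and a circumferential component, with left/right placodes
  overlaid by a handedness convention;
- **strain-rate decomposition**: for small domains (a focal cell plus
  its first corona of neighbours, tracked over a three-frame window) the
  total tissue strain rate **T** is fitted from centroid motions, the
  cell-shape strain rate **C** from the rotation-free log map between
  each cell's best-fit moment ellipse at the window ends, and the
  intercalation strain rate is the additive remainder **I = T − C**
  (units: proportional change per minute);
- **z-strain rates**: with cells matched one-to-one between an apical
  and a mid-basal layer ~7 µm deeper, the same machinery runs with
  depth in place of time, yielding cell **wedging** (shape analogue),
  **interleaving** (intercalation analogue, a "T1 in depth"), **tilt**
  (domain translation per µm of depth) and **twist** (rotation per µm);
- **discrete neighbour exchanges**: T1 events detected from adjacency
  changes between consecutive frames, classified by gain-axis
  orientation, summarised as the *productive* gain proportion
  (circumferential minus radial gains over half the tracked interface
  count) and its cumulative strain proxy; plus rosette counting
  (vertices where ≥ 5 cells meet);
- **junction signatures of active shortening**: actual junction lengths
  and end-vertex angles compared with a Voronoi tessellation seeded on
  the actual cell centroids as the neutral reference, plus signed
  end-pair cell elongation;
- **junctional myosin polarity**: per-interface mean intensity over a
  ±2 px band, and per-cell Fourier decomposition of the intensity
  profile around the perimeter — period-1 amplitude is *unipolarity*,
  period-2 *bipolarity*, both as fractions of mean perimeter intensity,
  with radial projections;
- a ground-truthed **synthetic placode generator** (kinematic polygonal
  mesh with scripted constriction fields, T1 flips, rosettes, a derived
  basal layer and rendered label/myosin images) that closes the loop
  for every stage, and temporal **binning/statistics** utilities with
  embryo-level inference.

## Worked example

```python
import numpy as np
from epitect import (PlacodeParams, generate_placode, build_adjacency_over,
                     build_mobile_frame, detect_exchanges, productive_gain_rate,
                     strain_table)

placode = generate_placode(PlacodeParams(seed=0))
cells = placode.apical_cells()          # pandas cell table, polygons in µm
meta = placode.metadata()
adjacency = build_adjacency_over(cells, "apical")
rframe = build_mobile_frame(meta.pit_cell_ids, cells, meta)

events, _ = detect_exchanges(adjacency, cells, rframe)
orient = [e.orientation for e in events]
print(len(events), orient.count("circumferential"), orient.count("radial"))

table = strain_table(cells, adjacency, rframe, "apical", meta.frame_interval_min)
far = table[table["r_um"] >= 12.0]
dt = meta.frame_interval_min
i_rad = float((far.groupby("frame")["i_rad"].mean() * dt).sum())
print(round(np.exp(i_rad), 3))

series = productive_gain_rate(events, adjacency)
print(round(float(np.exp(series["cum_productive"].iloc[-1])), 3))
```

prints

```
16 12 4
1.036
1.062
```

— the detector recovers the generator's 16 scripted neighbour gains
(12 circumferential, 4 radial, the circumferential bias reported for
the placode); the far-from-pit tissue expands radially by a cumulative
factor ≈ 1.04 through continuous intercalation; and the discrete-gain
proxy built only from exchange counts gives a comparable cumulative
ratio ≈ 1.06.

A thin CLI mirrors the batch steps (`epitect simulate | load | frame |
strain | t1`); run `epitect --help`.

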