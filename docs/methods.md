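# Methods

## Coordinate conventions

All geometry lives in image coordinates: x to the right, y down, origin
at the top-left pixel corner, polygon vertices at sub-pixel resolution
scaled to µm (default 0.22 µm/px). Downstream mathematics is entirely
in µm. The mobile radial frame sets θ = 0 towards posterior and
increases anticlockwise for a left-side placode and clockwise for a
right-side one, so mirrored placodes overlay; the circumferential unit
vector points along increasing θ. The pit origin is the mean centroid
of the designated pit cells per frame, tracked by identity forwards and
backwards from t = 0 (the frame before the first tissue bending);
frames without any tracked pit cell are linearly interpolated (edge
frames extrapolated) and flagged. Radial distance is planar Euclidean:
with tissue curvature below 0.05 µm⁻¹ over the analysis window, the
flat approximation is adopted throughout and no un-curving step exists.

An axis is classified *radial* when its acute angle to the local radial
direction is strictly less than 45°, otherwise *circumferential*; the
tie at exactly 45° is circumferential, a deterministic convention.

## Strain-rate decomposition

Domains are a focal cell plus its first corona of neighbours at the
central frame, restricted to placode cells, over a three-frame window
(≈ 4 min at 2 min/frame; at movie ends a flagged two-frame window).
Let Â be the least-squares affine map carrying the domain centroids at
the window start onto the window end (≥ 3 non-collinear tracked cells
required, else the domain is flagged invalid). Then

- tissue strain rate **T** = sym(log Â)/Δt, with the matrix logarithm
  split through the polar decomposition Â = R·U (log Â ≈ log U +
  log R); the rotation angle of R gives the domain rotation rate and
  the mean displacement the translation rate;
- cell shape: each cell's polygon is summarised by its area-normalised
  second central moment matrix M (the moment ellipse; the shape tensor
  Q = 2·M^½ has the ellipse semi-axes as eigenvalues — a w×h rectangle
  gives w/√3, h/√3). Between window ends, the cell-shape rate is
  log F/Δt where F is the unique symmetric positive-definite solution
  of F·M₀·F = Rᵀ·M₁·R — the rotation-free transport map between the
  ellipses, de-rotated by the domain polar rotation so that rigid
  rotations carry exactly zero shape strain. **C** is the unweighted
  mean over the domain's cells tracked at both window ends;
- intercalation **I = T − C**, exact by construction.

The log-strain formulation makes the decomposition exact on
exponential affine flows (tissue error < 10⁻⁶ against sym L) and
exactly zero on rigid rotations; these are the oracle tests. Strain
rates are in proportional change per minute and are projected onto the
radial/circumferential axes at the focal centroid (rad + circ = trace,
preserved to machine precision).

Cumulative strains are the exponential of the time-integral of
per-time-point *mean* rates — only averages are accumulated, never
per-cell distributions; missing time points contribute nothing and are
flagged.

## Depth geometry

Apical and mid-basal layers (nominal bands 1–3 µm and 7–8 µm; Δz
defaults to 7 µm and is configurable) are matched cell-to-cell by
breadth-first propagation from ≥ 3 manual seed matches: a candidate's
basal centroid is predicted by offsetting matched neighbours' basal
centroids with the apical centroid offsets (averaged over matched
neighbours), and the nearest unclaimed basal centroid is accepted only
if its error is within 0.25 of the apical centroid distance used. The
FIFO propagation order makes results deterministic.

z-strain rates reuse the identical decomposition code path with the
basal layer as the earlier "frame", the apical layer as the later one
and Δz in place of Δt (a test asserts bit-level equality of the two
routes). Wedging is the cell-shape term (pp/µm; basal→apical
convention, so apically-constricted bottle shapes are negative),
interleaving the intercalation term, tilt the fitted domain translation
per µm of depth and twist the fitted rotation per µm. Tilt is the
domain-fitted translation rather than the focal cell's own in-line —
the choice that falls out of the shared strain-domain machinery.

## Neighbour exchanges and rosettes

Adjacency: two cells are neighbours when their boundaries share a
polyline longer than 2 px (0.44 µm) — exactly for vector meshes, or
within that tolerance for raster traces separated by a 1-px watershed
ridge (with a 2·tol corner correction so vertex touches never count).
A gain is any pair adjacent at t+1 but not at t (both cells tracked at
both frames; otherwise suppressed and logged); the associated loss is
the quartet's other diagonal when identifiable. The gain axis is the
gaining pair's centroid–centroid line at t+1, classified at its
midpoint. Solitary and rosette-associated T1s are not distinguished.
The productive proportion per step is (circumferential − radial gains)
divided by half the tracked interface count at the step's start frame,
and its running sum exponentiates into a discrete-gain strain proxy.
Rosettes are merged polygon vertices (single-linkage within 2 px)
touched by ≥ 5 distinct cells.

## Junction signatures

The neutral reference is the Voronoi tessellation seeded with actual
cell centroids; a guard corona (in practice the placode border cells)
bounds the regions of all measured cells, and unbounded cells are
excluded — the clipping rule the reference needs but that a mechanical
model would make unnecessary. Length deviation is actual − Voronoi
edge length (µm; negative suggests active shortening). Angle deviation
is measured in the *opposite* (third) cell at each 3-way end vertex —
its polygon interior angle minus the corresponding Voronoi-region angle
— averaged over both ends; 4-way ends are flagged and skipped.
End-pair elongation uses e = ln(λ₁/λ₂) of the opposite cells' shape
tensors projected with cos 2(major axis − circumferential direction),
positive for circumferential elongation. Junctions are sampled in "T1"
status at −3 min before their exchange (nearest frame) and in
"baseline" status when no event touches them within ±5 frames (the
exclusion window is not externally specified; ±5 frames ≈ ±10 min was
fixed once).

## Myosin quantification and polarity

Interface intensity is the mean over the interface polyline rasterised
and dilated 2 px on each side, background-subtracted (median of a
supplied non-placode mask) and clamped at zero. Per cell, interface
intensities form a piecewise-constant angular profile I(θ) over each
interface's angular span seen from the centroid; Fourier coefficients
are exact arc integrals over the covered measure. Amplitudes are
2|cₙ|/c₀ divided by the mean-arc attenuation factor sinc(n·π/N), so a
pure cosine of relative amplitude a on N equal interfaces is recovered
exactly (without the correction a hexagonal cell would attenuate
period 1 by 4.5% and period 2 by 17%); unequal spans leave a residual
bias far below the 10% hexagon tolerance. Phases are reported in image
coordinates, the bipolarity phase as an axis mod 180°; bipolar circ
projection is the negative of the rad projection (cos 2 identity).
Border cells (those abutting the actomyosin cable) and cells with
fewer than 3 usable interfaces are excluded. The depth used for
extraction is a per-movie configuration; the default is the apical
band.

## Synthetic placode generator

The generator is kinematic — prescribed vertex displacement fields and
scripted topology changes on a shared-vertex polygonal mesh — not a
force-based vertex model, because ground truth must be exact rather
than emergent. Study-condition defaults: 100 cells in a 22 µm disc
(Lloyd-relaxed Voronoi with two pinned guard rings; ~4.4 µm cell
diameter), pit 11 µm off-centre towards posterior, 20 frames at
2 min/frame spanning t = −18…+20 min, two layers 7 µm apart, 0.22 µm
pixels. The apical constriction field is a radial potential flow with
divergence −0.01·exp(−r²/2ℓ²) per min (ℓ = 7 µm), so the imposed
area-loss rate is known per cell; a small uniform drift emulates embryo
motion. The exchange script (12 circumferential + 4 radial gains — the
reported two-thirds circumferential bias — spread over frames 5–16 in
the far region r > 12 µm) shrinks a selected junction over three
frames (×0.55, ×0.3), flips it with a 1.2 µm new junction, and grows
the gained junction back to the lost junction's original length over
three frames, so each scripted exchange is a complete T1. Selection
trial-flips candidates so the post-flip gain axis always classifies as
the scripted orientation; flips are transactional with polygon
validity and neighbour-overlap checks. Two 5-cell rosettes are
scripted at frame 18 in the mid annulus by collapsing two edges of one
vertex; interior edges are kept ≥ 0.9 µm at t = 0 and vertex
coincidences outside scripted rosettes are separated, so the scripted
topology changes are the only adjacency transitions — any residual
emergent transition is still recorded in the truth log (flagged
unscripted), which therefore always matches the emitted geometry. An
optional mode imposes tissue-wide active shortening of circumferential
junctions (cos²-weighted proportional length loss per minute) for the
junction-signature experiments. The basal layer is the apical mesh
pushed through an imposed radial wedging field (−0.01 pp/µm near the
pit) and a uniform tilt; the true apical↔basal matching is identity.
Myosin images paint junction bands at base × (1 + (g−1)·cos²(edge,
circumferential)) with g = 1.5, a dim interior, the epidermis outside
the placode at the embryo-average level, and additive Gaussian noise
(σ = 5 on a base of 100, SNR 20). All randomness flows from one seed;
outputs are byte-identical across runs.

What the generator does *not* emulate: mechanical force balance,
continuous (non-T1) sliding between exchanges, curvature, segmentation
errors, photobleaching, or z-drift. Passing tests therefore demonstrate
that the measurement pipeline recovers known kinematics and imposed
signals exactly or within stated tolerances — not that it is robust to
every artefact of real microscopy.

On the default placode, the discrete-gain strain proxy and the
continuous far-region intercalation strain agree closely when the only
deformation is the circumferential exchange script; with the full
mixed script the net (circumferential − radial) continuous signal is a
small difference of noisy terms and seed-to-seed spread of order ±20%
remains. The cross-check test therefore runs on the
exchange-only configuration, which is also the condition under which
the equivalence is well defined.

## Statistics

Time series are aggregated in 4.5-min bins tiling [−18, +18] min in two
stages — domain → embryo → group — and the displayed error band is the
mean of within-embryo variances (between-embryo variation is accounted
for in tests but not displayed). Group comparisons treat the embryo as
the experimental unit; the default backend is a Welch t-test on
per-embryo bin means, a deliberate approximation to the full
mixed-effects model (group fixed effect, embryo random intercept) that
preserves embryo-level inference without REML; the statsmodels MixedLM
backend is available behind the same interface. Type-I error of the
default backend is calibrated on null simulations. The two-sample
Kolmogorov–Smirnov test uses the asymptotic p-value, switching to the
exact small-sample p below n = 3 with a warning.

## Numerical choices and limitations

- Contact tolerance 2 px everywhere (adjacency, rosette merging),
  tolerant of 1-px watershed ridges.
- Rasterised label images recover polygon areas with ~0.6% mean error
  at 0.22 µm/px; the smallest cells can reach ~3% (discretisation
  floor), which bounds what image-based tests can assert.
- Problem sizes in tests (100-cell placodes, 20 frames, 100 random
  reference geometries, 60–200 simulation replicates) were chosen as
  the smallest sizes at which the statistical assertions are stable.
- The exact ellipse-to-ellipse map of the upstream strain-rate
  literature is not restated there; the symmetric transport map with
  polar de-rotation used here is a declared, oracle-validated choice.
- Track filtering removes whole tracks (lineage length, area range,
  aspect ratio, velocity relative to the per-frame median motion); it
  does not attempt to repair partially bad tracks.
- The maximal-overlap frame linker in `tracking_io` is a convenience
  for unlinked label stacks, not a reimplementation of the original
  study's tracker; externally supplied links take precedence.
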