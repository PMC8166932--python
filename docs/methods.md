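# Methods

## Model

The mineralized collagen fibril (MCF) is an upright cylinder of
diameter 50 or 200 nm and length 1000 nm. Its frame defines the global
axes: W and T span the equatorial cross-section, L is the longitudinal
axis. The mineral phase is a set of oriented rectangular
parallelepipeds ("platelets"), each described by a centroid, three
half-dimensions (half-width, half-thickness, half-length) and a proper
rotation mapping the platelet's local width/thickness/length axes to
(W, T, L). Collagen, water and non-collagenous proteins are not
represented: the model asks a purely geometric question — at which
mineral volume fraction (VF) do connected networks of platelets first
span the fibril?

A *tolerance cylinder*, 5% larger than the nominal fibril in both
radius and length (the longitudinal slack split between the two ends),
bounds the dynamics, so that platelets at the periphery have room to
rotate. Containment is tested on all eight vertices with closed
boundaries (a vertex exactly on the boundary is inside), so rotation
round-off cannot reject a boundary platelet.

## Initial configurations

Platelet dimensions are drawn uniformly from the experimentally
observed ranges — length 50–170 nm, width 5–90 nm, thickness 2–5 nm —
with width capped at 90% of the fibril diameter so a platelet always
fits the cross-section. Two site generators build the initial
staggered arrangement (platelet axes aligned with W, T, L):

* **Fixed-pitch lattice** — pitches at least the maximum platelet
  dimension plus 2 nm clearance, axial stagger of half a period
  between adjacent columns. Overlap-free by construction but limited
  to low VF; used mainly for validation.
* **Adaptive staggered packing** (default) — parallel layers stacked
  along T, each layer sharing one sampled thickness (apatite thickness
  has low dispersion, so platelets within one mineral layer are taken
  equally thick); widths sampled and laid side by side along the
  available chord of the layer; each (layer, width-slot) column filled
  along L with sampled lengths, adjacent columns staggered by half the
  mean length; 0.4 nm clearance everywhere. The packing is
  overlap-free, lies inside the nominal cylinder, and reaches ~70%
  VF at 50 nm diameter, comfortably above the top of the study grid.

A target VF is realized by taking a uniformly random subset of the
packed platelets, added one at a time until the summed platelet volume
first reaches the target (platelets that would overshoot by more than
0.9 percentage points are skipped, so the achieved VF is within ±1
point of the target). The VF grid of the study is 7% to 52% in steps
of 5 percentage points. VF accounting uses the nominal cylinder volume
and ignores pairwise-overlap double counting, which the 10% cap keeps
negligible; VF is fixed at initialization.

## Metropolis dynamics

One cycle attempts one move per platelet, in index order. A trial
move translates the platelet by independent uniform draws from
[-τ, τ] on each axis and rotates it about the world W, T, L axes (that
fixed order) by Gaussian angles of standard deviation θ. The move is
accepted iff

1. all vertices stay inside the tolerance cylinder;
2. for every other platelet, the pairwise interpenetration satisfies
   both caps below;
3. the inclination of the platelet length axis to L is ≤ 20°.

There is no Boltzmann weighting — acceptance is purely geometric — so
the chain samples the flat measure over legal configurations, times
the orientation prior below. After each cycle, τ and θ are multiplied
by 1.1 if more than half the attempts were accepted and by 0.9
otherwise (caps 5 nm and 10°), holding the acceptance ratio near 0.5.

**Orientation state.** Each platelet's orientation is parametrized by
its three world-axis rotation angles (applied W→T→L); trial rotations
step these angles and the matrix is rebuilt from them, so orientations
are exactly orthonormal at all times. Two constraints shape the
orientation ensemble:

* a hard support of ±20° per axis — the co-alignment range of the
  apatite *c*-axis with the collagen axis reported for bone;
* a Gaussian texture of dispersion σ₀ = 2° per axis about perfect
  alignment, enforced as a Metropolis–Hastings factor on the angle
  step. The dispersion is set by the spanning thresholds themselves:
  the 50 nm width chord sits just above the widest platelet (45 nm)
  plus a ~2° tilt of a 170 nm length axis, and the 25 nm thickness
  chord just above a 4-platelet stack plus small tilts — i.e. the
  thresholds separate genuine multi-platelet networks from tilted
  small aggregates only when typical tilts are of this order. With a
  flat ±20° ensemble a single tilted platelet reaches ~58 nm of T
  extent and the W/T anisotropy of the transition inverts.

  Setting `texture_sigma_deg=None` (flat orientation measure) and/or
  `angle_cap_deg=None` (free random walk) restores the simpler
  ensembles.

**Interpenetration caps.** Crystal coalescence is modelled as shallow
surface fusion. A pairwise overlap is legal when

* its volume is at most 10% of the smaller platelet's volume, and
* its penetration depth (minimum translation distance, computed over
  the 15 separating-axis candidates; exact for face contacts) is at
  most 10% of the smaller platelet's thinnest dimension.

The volume-only rule is insufficient on its own for plate-shaped
particles: 10% of a thin plate's volume permits full-thickness
penetration over 10% of the face area, which gives legal-overlap phase
space of order 10⁴ nm³ per pair and makes interpenetrating networks
span the fibril already at VF ≈ 0.1, an order of magnitude below the
observed transitions. The depth cap (≈ 0.2–0.5 nm, one or two atomic
layers) confines fusion to the crystal surfaces; the volume cap is
retained but is then almost never the binding constraint.
`max_depth_frac=None` restores the volume-only rule.

## Connectivity and clusters

The minimum distance d between two platelets is the exact distance
between the two closed boxes, computed by alternating nearest-point
projection between them (globally convergent for convex bodies;
multi-started from the centre and corners; absolute accuracy well
below 10⁻⁶ nm in validation), with a separating-axis pre-test that
returns d = 0 for touching or interpenetrating pairs. Overlap volumes
are exact: one box is clipped by the six face planes of the other
(Sutherland–Hodgman on the polytope's faces plus a cap polygon per
plane) and the volume integrated by the divergence theorem; degenerate
slivers evaluate to 0.

Two connectivity criteria are analysed on the *same* realizations:

* **hydrated shell** — d ≤ δ with δ = 14 Å, the cut-off of long-range
  electrostatic interaction through the hydrated amorphous layer that
  coats the crystals (equivalently, soft shells of thickness δ/2
  touch). By default pairs with d = 0 also connect — a coalesced pair
  is a fortiori in contact; `include_overlapping_in_shell=False`
  reproduces the literal relation 0 < d ≤ δ (measured effect on the
  50 nm thresholds: under one percentage point);
* **interpenetration** — positive overlap volume (coalesced crystals
  forming a continuum).

Neighbour search prunes pairs with a cell list (cell edge ≥ maximum
platelet diagonal + reach) or, in the pair-table path, an axis-aligned
bounding-box prescreen with the same superset guarantee. Connected
components are merged with the tree-based union-find (path compression
and union by size) at the core of the Newman–Ziff cluster algorithm;
the full dynamic bond-insertion bookkeeping of that scheme is not
needed here.

## Spanning tests and percolation curves

For each cluster the vertex extents d_W, d_T, d_L are the ranges of
its platelets' corner coordinates. The tests are:

* **W**: some vertex strictly outside the circle of diameter 90% of
  the fibril diameter (the cluster reaches the periphery) and
  d_W ≥ W_percolation (50 nm at 50 nm diameter, 120 nm at 200 nm);
* **T**: the same ring filter and d_T ≥ T_percolation (25 / 50 nm);
* **L, reduced length**: d_L ≥ L_cluster (300 / 450 nm), the typical
  fibril lengths seen in tomography; no boundary filter;
* **L, full length**: some vertex outside the central 95%-length
  cylinder (i.e. in a 25 nm end cap) and d_L ≥ the full fibril length
  — the longitudinal mirror of the W test, selecting clusters that
  span the entire 1000 nm;
* clusters of fewer than 5 platelets never count as spanning
  (`min_cluster_size`): the transition is bistable only for clusters
  of more than four platelets, and the chord thresholds are meant to
  select genuine networks, not stray pairs of wide platelets.

Per VF, the percolation probability is P = n_p / N over N
realizations with its binomial standard error. The curve P(VF) is
fitted by weighted nonlinear least squares with

P(VF) = ½ [1 + tanh((VF − VF_c)/Δ)],

weights = inverse binomial variance floored at 1/(4N) (so P ∈ {0, 1}
points are retained at finite weight), initial VF_c at the grid point
with P nearest 0.5 and initial Δ a quarter of the grid span, Δ
constrained positive. The fitted curve equals 0.5 at VF_c by
construction. All-zero or all-one curves are refused with a
"no transition" status; non-convergence returns the last iterate
flagged. A nonparametric crossing (first grid VF with P ≥ 0.5) is
reported alongside for robustness.

## Problem sizes and numerical choices

The desk-scale defaults — chosen as this package's study conditions —
are: 50 nm diameter, the ten-point VF grid, N = 50 realizations per VF
split over 5 independent Markov chains (each with its own packed
start), 2000 equilibration cycles per chain and 10 thinning cycles
between snapshots. Bond counts at 2000 cycles match runs three times
longer within noise, so the chains are equilibrated at this budget; at
50 nm the sweep covers 21–150 platelets per realization and runs in a
few minutes on one core. Full-scale simulations of this system use
budgets orders of magnitude larger (~10⁶ moves per platelet, both
diameters); fitted thresholds here carry a seed-to-seed spread of
roughly ±1 percentage point at this scale.

Numerical conventions worth knowing: containment boundaries are
closed, the peripheral ring filter is strictly `>`, SAT separation is
strict (touching boxes count as contact, d = 0, volume 0), overlap
volumes below 10⁻¹² nm³ evaluate to 0, and identical seeds reproduce
trajectories bit for bit (randomness is drawn once per cycle in fixed
order from a `numpy` Generator).

## What the generator does and does not emulate

The synthetic configurations reproduce: cylindrical confinement, the
staggered plate arrangement with parallel equatorial layers, variable
platelet dimensions across the observed ranges, near-alignment of the
crystal length axis with the fibril, and volume fractions spanning
healthy to hypermineralized tissue. They do not reproduce:
mineralization-state-dependent platelet dimension distributions
(dimensions here are sampled uniformly over the full observed ranges
at every VF), collagen-mediated spatial correlations, nucleation/growth
kinetics, needle-shaped minerals, or curved/core–shell crystal
geometry. Passing tests therefore demonstrate correctness of the
geometry, dynamics, clustering and fitting machinery and qualitative
agreement of the percolation behaviour — not a quantitative match to
any particular specimen.

## Known limitations

* With uniform dimension sampling the hydrated-shell network at low VF
  is comparatively dense: the fitted shell W-direction threshold at
  50 nm lands near 17% VF (seed-to-seed 16–19%) versus the ~22%
  reported for this system, and under shell connectivity the
  T threshold falls slightly below the W threshold (the permissive
  25 nm T chord is reached by mid-sized shell clusters). The
  interpenetration thresholds, their W < T ordering, the low
  full-length spanning probability and the saturation of the
  equatorial curves reproduce within stochastic tolerances.
* The depth-cap formulation of crystal coalescence is this package's
  modelling choice (see above); the volume-only variant is available
  but over-connects plate-shaped particles.
* Finite-size scaling to infinite systems, cluster-size distributions
  and mechanical consequences of spanning networks are out of scope.
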