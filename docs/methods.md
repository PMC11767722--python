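# Methods

This note documents the models, numerical choices and known limitations of
`lumenflow`, in the order the pipeline runs.

## Mask processing

A lumen mask is a binary raster; lumen objects use 8-connectivity and the
background 4-connectivity (the standard digital-topology pairing, avoiding
connectivity paradoxes).  Cleaning removes 8-connected components below
`min_object_px` (default 50 px) and fills 4-connected interior holes.  The
total lumen area is the exact integer count of true pixels, converted to µm²
by the squared pixel size; no smoothing or sub-pixel estimation is applied.

### Stage classification

The five morphological stages of long-term perfusion culture — meshwork,
sprouting, remodeling, stable, erosion — are defined observationally, not
algorithmically, so the classifier is an operationalization:

* the area series is smoothed by a centered moving average
  (`smooth_window = 3` frames) and differentiated; `|slope|` below
  `flat_tol = 1%` of the maximum area per frame counts as flat;
* a rising phase is *meshwork* until the skeleton-orientation anisotropy
  exceeds `aniso_threshold = 0.3`, after which it is *sprouting*.  The
  anisotropy is 1 − circular variance of the doubled edge-orientation
  angles, length-weighted (0 = isotropic, 1 = perfectly aligned); doubling
  makes antipodal directions equivalent;
* falling → *remodeling*; flat → *stable*; rising after a stable run →
  *erosion*.  Transitions only move forward through the canonical order, and
  *stable* is reachable only from *remodeling*: without that restriction a
  single smoothing-flattened frame at the sprouting peak would skip the
  remodeling stage entirely.  Runs shorter than `min_stage_frames = 2` are
  merged into their predecessor.

Smoothing leaks each boundary by about one frame, which bounds the
frame-label accuracy achievable on sharp synthetic transitions to roughly
85–95%.  A day-range fallback labeling (meshwork to day 8, sprouting to 20,
remodeling to 30, stable to 45, erosion after) is available when only
acquisition days are trusted.

## Flow solver

Steady incompressible **Stokes** flow is solved on a marker-and-cell (MAC)
staggered grid in which every lumen pixel is one fluid cell: velocity
components live on cell faces, pressure at cell centers.  At the scales of a
perfused microvascular culture (`U ~ 1e-4 m/s`, `L ~ 1e-4 m`, water-like
medium) the Reynolds number is ~1e-2, so dropping the inertial term changes
nothing measurable, and the resulting linearity is what makes the
dimensionless edge weights exactly independent of the (typically unrecorded)
absolute inlet velocity.

* **Ports.** Rectangular inlet/outlet channels (default 20 px long) are
  attached flush to the two borders along the flow axis, spanning the
  lumen's border footprint, so a developed profile enters the imaged region.
* **Boundary conditions.** No-slip walls by ghost reflection (the wall lies
  exactly on the cell face, half a cell from the first velocity unknown); a
  parabolic inlet profile whose discrete sum is rescaled so the inlet flux
  is exactly `U_inlet × port width`; zero traction at the outlet (ghost
  pressure 0, zero normal velocity gradient), which also pins the pressure
  level.
* **Linear algebra.** The momentum equations are scaled by `h²/µ` and
  pressure by `h/µ` so all coefficients are O(1); the saddle-point system
  gets a 1e-12 pressure penalty and is factorized directly
  (`scipy.sparse.linalg.spsolve`).  A 256×384 px frame solves in roughly a
  second.
* **Connectivity.** Flow components use 4-connectivity (diagonally touching
  pixels share no face, hence carry no flux).  Lumen pixels with no
  face-connected inlet–outlet path are flagged *no-flow* and excluded from
  the solve; a mask touching only one border yields a zero field flagged
  `zero_flow` rather than an error, because pre-perfusion frames (meshwork)
  are legitimate inputs.

Validation: on a 64-px-wide straight channel the centerline velocity matches
`1.5 U` to 0.05% and the wall shear stress matches the plane-Poiseuille
closed form `6 µU/w` to 0.05%; the error falls monotonically under grid
refinement (0.8% at 16 px width, 0.2% at 32, 0.05% at 64).  Discrete mass
conservation (inlet vs outlet flux) holds to solver precision by
construction.

### Wall shear stress

Wall pixels are lumen pixels with a 4-connected in-image background neighbor
(image borders are open vessel ends, not walls).  The inward normal is the
normalized gradient of the Euclidean distance map; the tangential velocity
at the wall-pixel center, half a cell from the no-slip face, gives
`tau = µ |u_t| / (h/2)` — first order in `h`, which the Poiseuille check
shows is ample at these widths.  Isolated pixels with an undefined normal
get `tau = 0` and a degeneracy flag.

### Edge flux

The flow rate of an edge is measured on straight cross-sections perpendicular
to the local chain tangent (tangent from a ±3 px window fit), sampled every
0.25 px with bilinear interpolation and integrated by the rectangle rule.
Sections are trimmed to the lumen **and** clamped to 1.6× the local
half-width + 2 px: without the clamp, sections of short junction-adjacent
edges run on into the joining vessel and systematically inflate their flux.
An edge's `Q` is the median over sections at 25/50/75% of the chain (a
single midpoint section for chains under 3 px), oriented downstream.

## Network extraction

Skeletonization uses homotopy-preserving thinning (`skimage`); spurs shorter
than `spur_min_px = 5` that terminate at a junction are pruned iteratively
(isolated short segments are kept).  The distance map is computed on the
unpruned mask.  Node pixels are skeleton pixels with 8-neighbor degree ≠ 2,
clustered by adjacency; chains are traced deterministically (sorted pixel
order) between clusters; components that are pure cycles get one anchor node
with a self-loop.  The node clusters plus chains reproduce the skeleton
pixel set exactly, and parallel edges/self-loops are kept (multigraph).

Edge regions implement the inverse distance transform: each chain pixel
paints a disc of radius equal to its distance-map value; competing claims go
to the nearest chain pixel.  A second pass with slackened radius
(1.5 r + 2 px) claims disc-shadowed leftovers — vessel end caps beyond the
last chain pixel and junction cores — bringing coverage of flow-bearing
lumen above 99% on channel toys while regions stay pairwise disjoint.

### Edge weights

`R_tau` divides the wall-integrated shear of the edge's region
(`Σ tau_i × h` over the region's wall pixels) by a reference wall traction
`tau_ref × d_ch`, with `tau_ref = 8 µ U_inlet d_ch / A_lumen` — the
Poiseuille-like stress of an equivalent channel whose width is the total
lumen area divided by the chamber length.  The printed form of this
normalization is typographically ambiguous; the equivalent-channel reading
is the default and a `literal` grouping is selectable, the two differing
only by a uniform positive factor across all edges (shortest paths and all
trend directions are unchanged).  `R_Q` is `|Q| / (U_inlet w_inlet)` with
`w_inlet` defaulting to the attached port width.  The magnitude is used
because perfusion direction alternates daily in such experiments and the
centralities need magnitudes; the signed value is kept as `Q_signed`.
No-flow edges get both weights 0 and a flag.

## Centralities

Betweenness treats weights as **costs** (high wall shear = expensive
transport).  The default `path_count` variant is the standard
shortest-path-counting betweenness (unnormalized, endpoints excluded,
computed per component), the algorithm the igraph/networkx family
implements; zero-cost edges are lifted to 1e-12 to keep distances defined,
and parallel edges are collapsed to the minimum-cost one for path routing
(self-loops lie on no shortest path).  A `paper_text` variant instead ratios
the summed costs of shortest paths through a node against the summed costs
over all pairs; it is retained as an interpretation of a verbal definition
and is not the default.  Strength is the exact incident-weight sum,
self-loops counted twice; the mean over nodes satisfies
`mean_strength = 2 Σ_e w(e) / |V|` identically.

Cross-sample aggregation aligns acquisition days by clustering within 0.5
day and reports the cross-sample mean with a Student-t 95% CI (absent below
two samples).

## Synthetic data

The generator emulates a 2 mm (flow direction) × 3 mm chamber; the
full-resolution raster is 1280×1920 px at 1.5625 µm/px, and the scaled-down
raster used throughout the tests and the acceptance script is 256×384 px at
7.8125 µm/px with 4 frames per stage — sizes chosen so a full five-seed
study runs in minutes on one CPU.  All stochastic choices come from one
`numpy` RNG seeded once, in a fixed order, so a config fixes the mask
sequence bit-exactly.

* **Toy geometries** (straight channel, Y-branch, lattice, bridge lattice)
  are drawn with flow along columns; widths below 4 px are rejected as
  unresolvable.  The bridge lattice is the canonical pruning configuration:
  two high-flow parallel channels joined by one perpendicular, nearly
  flow-free bridge.
* **Meshwork**: 25 isotropic random segments in the first frame (+25% per
  later frame), log-normal widths around a 40 µm capillary scale.  Segments
  anchor on the existing lumen so vasculogenesis grows one connected mesh,
  except a `free_segment_fraction = 0.4` that stays detached — the satellite
  cords that never join the perfused network.
* **Sprouting**: two full-length feedthrough channels placed inside the
  mesh's footprint, plus longer axial segments with an orientation spread
  set by `sprout_anisotropy` (default 0.8).
* **Remodeling** is closed-loop: each frame analyzes the current mask with
  the full pipeline and removes `prune_fraction_per_frame = 10%` of the
  flow-bearing edges with the lowest `R_Q` among edges within 45° of
  perpendicular to the flow axis, restricted to genuinely low-flow segments
  (`R_Q ≤ 0.1`), skipping any candidate whose removal would cut the
  inlet–outlet path (checked on the pixels, not just the graph) or strand a
  currently-perfused region — a segment whose removal de-perfuses a region
  is not redundant.  In parallel, non-perfused satellite lumens, lacking any
  shear stimulus, retract by disk(2) erosion per frame.  Both processes are
  flow-dependent regression; the second is what drives the strength-
  centrality rise, since it removes zero-strength nodes without touching the
  perfused network's flow.
* **Stable**: ±1 px jitter on 5% of wall pixels, half dilating and half
  eroding, so the area changes by well under 1% per frame.
* **Erosion**: dilation growing in from the two port borders plus a
  thickening monolayer strip, so the area rises again.

What the generator does **not** emulate: brightfield appearance, cell-scale
dynamics, gradual width adaptation of surviving vessels, 3D structure (the
real chamber is 100 µm high and analyzed in 2D), or measurement noise in
segmentation.  Passing tests therefore demonstrate that the *analysis*
recovers the flow-topological signatures from masks that exhibit them, not
that real cultures will show effect sizes of the same magnitude.

## Defaults chosen where the source material is silent

`U_inlet = 1e-4 m/s` (typical capillary-scale velocity) and
`µ = 1e-3 Pa·s` (culture medium ≈ water) are test defaults only — both are
pure scale factors on the solution, and only the dimensionless `R_tau`,
`R_Q` and the centralities are scientifically meaningful.  `d_ch = 2 mm` is
the chamber length along the flow.  The 45° pruning angle, the 0.1 `R_Q`
cap, and the generator rates above are model choices documented here and
exposed as config fields.

## Known limitations

* The WSS operator is first-order at the wall; rough (staircase) walls show
  pixel-level `tau` scatter that the wall *integral* averages out.
* Very short edges between nearby junctions can still carry distorted flux
  despite the section clamp; the median over three sections bounds, but does
  not eliminate, this.
* The `paper_text` betweenness variant's denominator ("all pairs not via the
  node") is one reading of an ambiguous verbal definition.
* Pruning erases whole edge regions per event; real regression narrows
  vessels gradually.
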