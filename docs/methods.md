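# Methods

This note documents the models, numerical choices and degenerate-case
policies behind `softcut`, in the order data flows through a run: the
synthetic scene, the meshless discretization, the dynamics, the cutting
procedure, and the transfer accounting. It also states what the synthetic
benchmark does and does not establish.

## The synthetic scene

The benchmark object is a solid torus of major radius `R` (default 1) and
minor radius `r` (default 0.3), axis along z, defined by the implicit
inequality `(sqrt(x² + y²) − R)² + z² ≤ r²`.

- **Nodes** are the points of a regular grid of spacing `h` that fall
  inside the solid; **integration elements** sit on the dual grid (offset
  `h/2`), each with volume `h³`. A dual-grid placement is the simplest
  reading of "cubic integration element": every interior element is the
  center of a node cube. Generation is deterministic given `(R, r, h)`.
- **Render surface**: the parametric torus triangulated on an
  `n_u × n_v` grid — `n_u·n_v` vertices, `2·n_u·n_v` triangles, closed
  (every edge shared by exactly two triangles, Euler characteristic 0).
- **Anchor**: nodes with `x < −(R − r/2)` are Dirichlet-fixed so the torus
  hangs and sags under gravity `(0, 0, −9.81)` m/s². Something must anchor
  the object or the demo is a rigid free fall.
- **Blade**: a two-point vertical segment in the plane y = 0 with
  endpoints at `z = ±1.5r` (always outside the solid), translating along x
  from `R − 1.5r` to `R + 1.5r` over the cut frames, so its swept surface
  bisects the tube cross-section at θ = 0. First and last frames lie
  entirely outside the solid.

Units are SI-flavored but arbitrary: the defaults (below) give a very soft,
decimeter-scale object, which is the regime of interest.

## Meshless discretization

Each element is coupled to at least `k_min = 8` nearest nodes (by rest
distance). If the selected set fails the **coplanarity spread test** —
smallest eigenvalue of the centered covariance of the node positions
must exceed `(0.05 h)²` — next-nearest nodes are appended until it passes,
up to the fixed row width (default 16). A set that cannot be fixed within
the row width is a capacity overflow, reported with the element index.

Shape functions are **moving least squares** with linear basis
`p(x) = (1, x, y, z)` and the C² cubic B-spline weight of normalized
distance `q = ‖x − xᵢ‖ / rᵢ`:

    w(q) = 2/3 − 4q² + 4q³        q ≤ 1/2
    w(q) = 4/3 (1 − q)³           1/2 < q ≤ 1
    w(q) = 0                      otherwise

`φᵢ(x) = pᵀ(x) A⁻¹(x) wᵢ(x) p(xᵢ)` with moment matrix
`A(x) = Σⱼ wⱼ(x) p(xⱼ) pᵀ(xⱼ)`; gradients by the total derivative
(differentiating both `A` and `w`). These satisfy partition of unity,
gradient consistency and linear reproduction to round-off, which is what
makes rigid translations exactly strain-free and keeps the lumped mass
total exact.

Numerical choices:

- **Support radii**: per node, `rᵢ = 1.1 ×` the distance to its 8th
  nearest element center at rest, computed once and never updated.
  Where a stored pair nevertheless falls outside support (a far neighbor
  appended to cure coplanarity, or a boundary surface vertex), that
  pair's radius — and only that pair's — is expanded to `1.05 ×` the
  actual distance, so every stored pair carries a strictly positive
  weight and the moment matrix is never starved by construction.
- **Conditioning**: `cond(A) > 1e12` raises a rank-deficiency error naming
  the element or vertex; no silent regularization, because a (nearly)
  coplanar neighbor set is a modeling failure the caller must repair.
- Shape functions are evaluated at **rest positions only**
  (total-Lagrangian small strain, consistent with the linear material);
  they are stored, not re-derived per frame, and a cut re-evaluates only
  the rows it modified.

## Dynamics

Linear elasticity: `ε = sym(∇u)`, `σ = λ tr(ε) I + 2με`, with Lamé
parameters from Young's modulus `E` and Poisson ratio `ν`. Defaults:
`E = 10 kPa`, `ν = 0.45`, `ρ = 1000 kg/m³` — soft-tissue-like — and
`Δt = 1/60 s` (frame-coupled physics at 60 FPS).

Each frame solves

    (M − Δt² K) Δv = Δt (K u₀ + f_ext),   v = v₀ + Δv,   u = u₀ + Δt v

- **K is never assembled.** Its action is one pass over elements:
  `ε = sym(Σᵢ ∇φᵢ ⊗ pᵢ)`, `σ(ε)`, then `fᵢ −= V σ ∇φᵢ`. The operator is
  symmetric negative semi-definite with rigid translations in its
  nullspace. A `StiffnessOperator` snapshot caches the gathered index and
  gradient arrays once per frame; conjugate gradient then applies it a few
  hundred times.
- **CG** is unpreconditioned, stops at `‖r‖ ≤ tol·‖b‖` (default
  `tol = 1e−6`, cap `10·n_nodes` iterations), and needs exactly two scalar
  reductions per iteration (`r·r`, `p·Ap`) — the pair a device-resident
  solver would return to the host. Hitting the cap yields a flagged,
  non-fatal result; non-finite values raise.
- **Mass lumping**: `mᵢ = Σ_I ρ V_I φᵢᴵ` — except that MLS shape values
  can be negative near the boundary, which would give some nodes negative
  mass and destroy the positive-definiteness of `M − Δt²K`. Lumping
  therefore uses `max(φ, 0)` renormalized to unit sum per element: every
  node mass is positive, total mass equals `ρ ΣV` exactly element by
  element, and the plain formula is recovered wherever `φ ≥ 0` (all
  interior elements). Isolated nodes get a floor mass of `1e−12 ×` the
  mean. Masses are refreshed after every cut frame.
- **Dirichlet constraints** by projection: fixed-node components of the
  operator input, output and right-hand side are zeroed, preserving
  symmetry.
- **Character of the integrator.** The right-hand side uses forces at the
  *start* of the step only. Per eigenmode of `(M, −K)` the resulting
  `(u, v)` propagation matrix has determinant 1: the map is
  area-preserving, so motion is unconditionally *bounded* for any `Δt`
  (the stability that matters when cutting keeps changing the smallest
  element), but energy is not monotonically dissipated — from a state
  with nonzero velocity it oscillates. From a displaced state at rest the
  step does contract energy (`E₁ = E₀ · m/(m + Δt²k)` per mode). There is
  no Rayleigh damping. An undamped torus therefore keeps swinging around
  its static sag; applications wanting settling should add damping
  externally.
- A `precision: single` switch casts the state to float32 per frame; its
  behavioral effect is exposed for experimentation but carries no
  guarantees.

## Cutting

Each frame the blade polyline at frames t and t+1 spans one quad per
segment, split into two triangles; triangles with area below `1e−12 h²`
are discarded. Severing and visibility both test **rest-configuration
segments** against cut triangles, consistent with the rest-position shape
functions.

- **Intersection predicate**: orientation (signed-volume) tests. A link is
  severed when its endpoints straddle or touch the triangle's plane and
  the three edge orientations share a sign, zeros allowed — ties count as
  hits, so grazing links are severed conservatively. One exception: a
  segment lying entirely *in* the triangle's plane (both endpoint
  orientations zero) grazes without crossing and is not severed; without
  this rule every in-plane link in the model would count as cut by an
  axis-aligned blade. Orientation signs are snapped to zero below
  `1e−10 ×` the product of edge norms, so tie classification is immune to
  rounding differences between algebraically equivalent determinant
  formulas (grid geometry plus an axis-aligned blade makes exact ties
  common, not rare).
- **Detection** runs on all element-node and vertex-node links against the
  newly swept triangles only, with an axis-aligned bounding-box prefilter;
  the test suite checks it against an all-pairs scalar oracle frame by
  frame.
- **Severing and reconnection**: severed nodes are removed from their
  element rows. A row left short of `k_min` or coplanar is topped up with
  nearest **visible** nodes — visible meaning the center-to-node segment
  crosses no triangle of the *accumulated* cut surface — so opposite
  sides of a cut never re-couple. Shape rows of modified elements are
  re-evaluated; exactly the modified rows become dirty.
- **Overflow policy**: if no admissible neighbor set exists within the
  fixed row width, the library raises by default; the simulation driver
  uses `on_overflow="warn"`, which *refuses that element's cut* (row left
  unsevered) and counts the event in the cut log. Refusal is the only
  non-fatal option that preserves every invariant (non-coplanarity,
  partition of unity, mass accounting); it trades a locally duller blade
  for a well-posed system.
- **Surface weights**: vertex rows lose severed nodes and the remaining
  weights are renormalized (rebuild only on degeneracy: weight sum below
  `1e−9`, in which case the vertex is remapped to the nearest visible
  element's node set). A vertex lying exactly in the cut surface can end
  up with no visible element; it keeps its previous mapping (logged at
  debug level). No new triangles are generated along the cut — crack-face
  re-triangulation is out of scope.
- Nodes that lose every incident element become inert debris: gravity and
  velocity zeroed, position frozen. Conservative tie severing makes this
  reachable (a grid plane coincident with the blade plane), and unforced
  floor-mass nodes would otherwise free-fall forever.

## Fixed-width tables and transfer accounting

Four tables mirror the per-object state: connectivity (int32 node
indices), shape values (float64), shape gradients (float64 3-vectors) and
surface weights (packed int32+float64 records). Each is allocated once at
`n_rows × max_row_width` plus an int32 row-length vector and never grows;
unused slots are zero-filled on write so serialization is reproducible,
and consumers must honor row lengths.

Rows are grouped into batches of `batch_size` rows (default 64, per
table — the choice is exposed in the config). Writing a row dirties its
batch and nothing else. `flush()` returns the transfer plan — one
`(batch, bytes)` entry per dirty batch, where a batch's bytes are its
payload slots plus its slice of the row-length vector, so one flush unit
is self-contained — and clears the flags. A `TableMirror` applying only
flushed batches equals the source after every flush; this mirror
equivalence is property-tested over randomized edit scripts. With
batching disabled, any edit ships the whole table (the comparison policy);
the toggle changes ledger bytes only, never physics.

The ledger records, per frame and table, bytes under batched transfer
versus a full copy. The headline figure is the **aggregate reduction
`1 − Σ batched / Σ full` over the frames with at least one table edit**
(frames without edits transfer nothing and are excluded as trivially
favorable). `scripts/acceptance.py` recomputes it on a ~5,000-element
torus with a 10,000-triangle surface, 200 frames, one blade cut over 60
frames, batch size 64.

## What the synthetic benchmark does and does not establish

The generator emulates the published experiment's *shape*: a torus
deforming under gravity while a scripted blade cuts the tube, at a
desk-scale resolution (~5k elements vs. up to 80k). A green run
establishes that (a) the discretization keeps its reproduction invariants
through arbitrary severing, (b) cut edits stay local in the table layout,
and (c) batched dirty transfer eliminates ≥ 80% of mirrored bytes on edit
frames. It does **not** establish wall-clock speedups, frame rates, or
single-vs-double precision behavior — those are hardware statements,
deliberately out of scope — nor realism of the material model (linear
elasticity, no contact, no self-collision). The cut region of a regular
grid model is also friendlier to batch locality than an unstructured
organ mesh would be; the batch size is a config knob, not a tuned result.

## Known limitations

- An element may never exceed the fixed row width; the driver's refusal
  policy masks the failure locally instead of growing storage.
- Severing is conservative (ties cut), so a blade coincident with a grid
  plane severs the in-plane node sheet from both sides, producing frozen
  debris nodes.
- No preconditioner; CG iteration counts grow with stiffness contrast.
- Rendering, haptics, GPU execution and crack-face re-triangulation are
  out of scope; the transfer model is host-memory byte accounting under
  the stated contract.
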