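# softcut

Real-time soft-tissue simulators for surgical training must deform and
*cut* virtual organs at interactive rates. On accelerator hardware the
bottleneck is not only the arithmetic but the rigidity of device memory:
the graph that couples a deformable object together (which nodes each
integration element sees, the shape functions of each pair, the weights
that skin the render surface onto the volume) changes every time the
scalpel severs a connection, and naively re-uploading or reallocating it
stalls the simulation.

`softcut` is a cuttable meshless soft-body simulator built around the data
structure that solves this: a **fixed-row-width table** in which every row
occupies the same memory regardless of how many items it holds, paired with
a row-length vector, allocated once and never grown. Rows are grouped into
**batches**, the unit of dirty tracking: after a localized cut, only the
batches containing modified rows need to be copied to a device mirror. A
built-in **transfer ledger** accounts byte-for-byte what such a mirror
would receive, so the transfer saving is measurable without a GPU (actual
accelerator execution is explicitly out of scope).

The mechanics around the store:

- **Discretization** — Element-Free Galerkin: a node cloud plus cubic
  integration elements (centers + volume `h³`), each coupled to ≥ 8
  neighbor nodes through moving-least-squares (MLS) shape functions with a
  linear basis and cubic B-spline weights, so partition of unity
  (Σᵢ φᵢ = 1), gradient consistency (Σᵢ ∇φᵢ = 0) and linear reproduction
  (Σᵢ φᵢ xᵢ = x) hold exactly.
- **Dynamics** — linear elasticity, σ = λ tr(ε) I + 2με, integrated
  implicitly: each frame solves `(M − Δt²K) Δv = Δt (K u₀ + f_ext)` with
  lumped (diagonal) mass `M` and the stiffness `K` never assembled — only
  its action `K·p` via a loop over elements — using matrix-free conjugate
  gradient whose per-iteration global reductions are exactly the two
  scalars `r·r` and `p·Ap`. Stable far beyond the explicit time-step limit.
- **Cutting** — a polyline blade sweeps a triangulated cut surface each
  frame; an element-node or vertex-node link is severed when its
  rest-configuration segment crosses a newly swept triangle. Elements left
  short of neighbors (or with a coplanar, MLS-degenerate set) are topped up
  with the nearest *visible* nodes — never reconnecting across the cut —
  and only the modified rows are re-evaluated and marked dirty.
- **Surface** — render vertices carry MLS weights over volume nodes
  (`xᵥ = Xᵥ + Σᵢ wᵢᵛ uᵢ`); cutting severs and renormalizes these weights
  without re-triangulation.

The test scene is a synthetic solid torus (major radius `R`, minor radius
`r`, grid spacing `h`) that hangs under gravity from one fixed side while
a two-point blade cuts through the tube — generated procedurally, no
downloads.

## Worked example

```sh
cat > demo.yaml <<'EOF'
grid_spacing: 0.12
surface_n_u: 24
surface_n_v: 12
n_frames: 40
cut_start_frame: 5
cut_n_frames: 20
batch_size: 32
EOF
softcut generate --config demo.yaml --out-dir demo_model
softcut simulate --config demo.yaml --out-dir demo_run
softcut report demo_run/ledger.csv
```

which prints

```
INFO wrote demo_model/volume.txt (1032 nodes, 936 elements) and demo_model/surface.obj (288 vertices, 576 triangles)
INFO simulated 40 frames; logs in demo_run
table                  all frames  edit frames
connectivity               98.7%       95.0%
shape_gradients            98.7%       95.0%
shape_values               98.7%       95.0%
surface_weights            98.1%       92.2%
aggregate                  98.7%       94.7%
```

Reading the report: over the frames in which the blade actually modified a
table ("edit frames"), batched flushing shipped 94.7% fewer bytes to the
mirror than copying the four tables in full would have; over all 40 frames
(most of which have no edits at all) the saving is 98.7%. The run
directory also holds `frames.csv` (per-frame CG iterations, residual, max
displacement — e.g. frame 0 converged in 149 iterations with max
displacement 3.3 mm as the torus starts to sag) and `cuts.csv` (per cut
frame: severed volume/surface links, modified elements, overflow warnings —
e.g. frame 13 severed 48 element-node links and rebuilt 24 element rows).
Add `--export-obj` to write the deformed surface as an OBJ per frame, and
`--no-batching` to re-run with whole-table transfers for comparison (the
physics is bitwise identical; only the ledger changes).

## Library use

```python
from softcut import RunConfig
from softcut.simulation import Simulation, build_scene

scene = build_scene(RunConfig(grid_spacing=0.12, n_frames=40,
                              cut_start_frame=5, cut_n_frames=20))
sim = Simulation(scene)
sim.run()
ledger = scene.tables.ledger
print(ledger.reduction(ledger.frames_with_edits()))
```

## Acceptance benchmark

`scripts/acceptance.py` regenerates the headline figure from scratch: a
~5,000-element torus with a 10,000-triangle surface, 200 frames at
Δt = 1/60 s, one blade cut through the tube over 60 frames, batch size 64.
It runs the full pipeline and writes the aggregate transfer reduction over
edit frames (as a percentage) to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The pipeline is deterministic; `--seed` is accepted for reproducibility
plumbing. Expect a few minutes on one CPU core.

## Layout

| module | contents |
| --- | --- |
| `softcut.store` | `FixedWidthTable`, `TableMirror`, `TransferLedger` |
| `softcut.model` | torus volume/surface factories, neighbor selection, blade trajectory |
| `softcut.mls` | MLS shape values/gradients, coplanarity spread test |
| `softcut.dynamics` | lumped mass, matrix-free `K·p`, CG, implicit step |
| `softcut.cutting` | swept cut surface, link detection, severing + reconnection |
| `softcut.surface` | vertex→node weight table, surface position update |
| `softcut.tables`, `softcut.simulation`, `softcut.config`, `softcut.io`, `softcut.cli` | assembly, frame loop, YAML config, text formats, CLI |

See `docs/methods.md` for the model, its assumptions, and every numerical
choice (tolerances, tie rules, degenerate-case policies).
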