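# Methods

This note records the modelling assumptions, parameter defaults and
design decisions behind `emocaccess`, in the spirit of a model
description a maintainer or reviewer would need to interpret its
outputs.

## Facility readiness and classification

The readiness score (0–14) is the sum of five general-readiness
points and up to nine signal-function points, one per function that is
simultaneously staffed and equipped. The score measures *readiness*,
not recent performance: a facility that could theoretically provide a
function counts even if low patient volume means it has not done so
recently.

Classification applies the level rules top-down with first-match-wins
precedence: 5 (score ≥ 10 and caesarean in the last three months),
4 (score ≥ 10), 3 (score ≤ 9 and motorised transport), 2 (6 ≤ score
≤ 9), 1 (otherwise). Because the transport rule sits above the score
bands, transport promotes *any* score-0–9 facility to level 3,
including scores 0–5; the classification tables this mirrors are
consistent with that reading (level-3 facilities span the full 0–9
band) though not conclusive, and the precedence is fixed here as a
design decision. Missing survey flags are treated as `False`
(not ready) — the conservative reading of a non-response.

The staffed/equipped mapping from raw staff-cadre and stock
inventories is configurable through `SignalFunctionChecklist`. The
default is deliberately minimal — one kit item per function, any
clinical cadre, with caesarean requiring surgical staff plus
anaesthesia capability — because real assessments carry their own item
checklists; users reproducing a specific survey should supply theirs.

## Cost surface

Per-cell crossing cost in minutes is `cell_size / speed`. Walking
speeds per land-cover class default to 2–5 km/h (wetland 2, forest 3,
cropland 4, grassland/bare 5); motorised speeds per road class default
to 80/50/30 km/h for primary/secondary/tertiary. These defaults are
literature-style substitutes, clearly configurable via `SpeedConfig`,
not survey-calibrated constants. Roads are rasterised at one-cell
width and override walking speed; the fastest class wins where
segments overlap (a deterministic tie-break). Water is impassable
unless a bridge-flagged road segment crosses the cell.

Slope attenuates walking speed isotropically by `exp(−k·|slope|)` with
`k = 3.5` per unit gradient — a Tobler-style hiking decay normalised
to exactly 1 on flat ground. A single isotropic cost raster is used
(no direction-dependent costs); motorised cells are not attenuated by
default since class speeds are already per-class assumptions
(`attenuate_roads=True` switches this).

Travel-time maps use standard cost-distance semantics: 8-connected
moves, step cost equal to the mean of the two cells' crossing costs,
scaled by √2 on diagonals, computed as multi-source shortest paths
(scipy's sparse-graph Dijkstra). Tests verify equivalence against an
independently built explicit graph.

## Catchments and bypassing

Each (level, zone) class has hour bounds and a priority rank (see
README table). Bounds are half-open `[lower, upper)`: a cell at
exactly 2.0 h of a level 5 belongs to its secondary zone. The
boundary convention at 1/2/3/5 h is a package decision — the
underlying classification tables do not state one — chosen so the
primary/secondary partition never double-counts. Overlaps keep the
lowest rank; ties on rank break by shorter segment-1 time, then roster
order, making delineation fully deterministic. Cells reached by no
class are reported as their own OUTSIDE row in every population table
rather than silently dropped.

Catchments are computed in raster semantics (per-facility travel-time
maps thresholded at class bounds), not as vector polygons, so they
agree exactly with the cost surface and with the per-cell brute-force
oracle used in tests.

## Referral

The road graph carries traversal minutes per edge from class speeds.
Facilities snap to the nearest graph node with no distance limit (the
snap distance is logged); travel between a facility and the network
is counted as zero — the simplest reading of along-network transfer.
When both adjustments apply the result is `2·T + 30`, not `2·(T+30)`:
the phone search happens once, before any vehicle moves, and the two
delays are modelled as independent add-ons. The alternative ordering
differs by 30 min and is worth a sensitivity check in applied work. A
level-5 facility without transport is treated as if a vehicle were
stationed there (it is a referral destination, so the status quo
requires one).

## Scenarios

Model 1 selects upgrades greedily: each round picks the level-4
candidate maximising the population newly brought within the level-5
primary bound (2 h), breaking ties by higher readiness score then
lower id. This is a transparent stand-in for "high score and
geographically strategic location" — the source analyses do not state
an algorithm, and the greedy rule should not be attributed to them.

Model 2 sets the vehicle and communication flags everywhere. The
flags feed the transport criterion (promoting score-0–9 facilities to
level 3) and the referral adjustments, but the readiness score stays
frozen at baseline: the empirical pattern this reproduces (level-2
populations shifting to level 3 while level-4/5 first-preference
populations stay put) shows the intervention is modelled as referral
infrastructure, not as clinical readiness points.

A structural caveat: the priority overlay makes *band* improvements
monotone (adding level-5 facilities can only grow the population
within 2 h of a level 5) but **not** per-cell total times. A cell
newly captured by an upgraded facility's rank-1 catchment is modelled
as travelling there directly even when its former
short-segment-1-plus-referral route was quicker; a handful of cells
per landscape therefore show longer Model-1/3 totals than Model 0.
This is inherent to strict priority-based bypassing, not an
implementation artefact, and is surfaced (not hidden) by the test
suite.

## Population-weighted statistics

Weighted mean and SD use the population-expansion definition (SD with
no small-sample correction — a finite-sample correction is meaningless
when weights are populations). The 95th percentile is the
linearly interpolated inverse CDF on cumulative weights, defined so
that integer weights reproduce `numpy.percentile` of the explicitly
replicated sample. Segment-2 statistics are computed over the
transfer-needing subpopulation only (which is why they can exceed the
total-journey mean); total-journey statistics cover the whole modelled
population. Cells assigned to a facility cut off from the road
network are excluded from weighted statistics and reported as a
separate unreachable-population count. Expected pregnancies and severe
complications are available as configurable multipliers (crude birth
rate, default 0.039; severe-complication share of pregnancies, 15 %).

## Synthetic landscapes

The generator emulates the statistical structure of the real inputs
this pipeline expects, at desk scale:

* **Grid** — 150 × 150 cells of 500 m (a 75 km window). Real
  population rasters are finer (≈100 m); the coarser default keeps
  travel-time heterogeneity (cells from minutes to >5 h from care)
  while the full four-model pipeline runs in about a second.
* **Land cover** — smoothed-noise fields thresholded to a configurable
  class mixture, with a river of water cells carved across the window.
* **DEM** — smoothed noise scaled to 400 m relief.
* **Population** — 50 000 people: Gaussian kernels around 20
  settlements with log-normal sizes (60 % of mass) plus a patchy rural
  background (40 %), zero on water, total mass exact.
* **Roads** — a minimum spanning tree over settlements plus two extra
  edges, classed at random, with bridge flags where segments cross
  water. Optionally some settlements are left off-network to exercise
  unreachable-referral paths.
* **Facilities** — default roster {level 5: 2, 4: 6, 3: 3, 2: 13,
  1: 4}, echoing the census-like pattern of a few surgical hospitals,
  a large mid tier and a tail of minimal posts. Attributes are
  constructed backwards from the requested level (target score drawn
  near census-like level means, transport pinned where the rules pin
  it, vehicle/communication marginals configurable), so
  classification is the identity on the request — which the tests
  exploit.

What the generator does **not** emulate: real geography (road network
topology follows settlements, not terrain), seasonal/wet-surface
variation, facility siting politics, or gridded pregnancy surfaces.
Passing tests therefore demonstrate correctness of the *method* under
controlled conditions, not calibration to any real country's access
figures — national headline numbers require the corresponding national
census, road and population datasets.

## Numerical choices

All internal times are minutes; reports add hours. Grid indexing is
row-major with row 0 at the northern edge and cell-centre
registration. Rasters are exchanged as ESRI ASCII grids and vectors
as GeoJSON — plain-text formats any GIS reads. Impassable/unreachable
cells carry `+inf` internally and the ASCII-grid NODATA value on disk.
Degenerate inputs are rejected loudly: grids smaller than 4 × 4,
facilities outside the grid, all sources impassable, empty road sets,
rosters without a level 5, negative or non-finite transfer times,
all-zero weights.
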