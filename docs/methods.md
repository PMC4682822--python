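# Methods

## Model

The nervous system is a directed weighted graph embedded in the plane.
Chemical connections are directed with synapse counts `nsyn(ij)`;
electrical connections (gap junctions) are symmetric with counts
`ngap(ij)`, stored as a symmetric matrix so that one electrical connection
appears as two ordered entries. The wiring cost of a layout
`X = (x_1 … x_n)`, `x_i ∈ R²` in mm, is

    TWL(X) = Σ_{i,j} A_ij · d(x_i, x_j)

summed over ordered pairs. Weight schemes for `A`:

* **unit_joint** — `A = 1[chem>0] + 0.5·1[elec>0]`. The halving makes each
  electrical connection contribute its length once in the ordered-pair sum,
  so every connection has unit weight regardless of type; entries take
  values in {0, 0.5, 1, 1.5}.
* **synapse_counts** — `A = nsyn + f·ngap` with `f = 0.5` by default. The
  halving convention is retained when indicators are replaced by counts;
  `f` is exposed (`WeightScheme.elec_factor`) because the convention choice
  is independent of the counts themselves.
* **binary_union** — `A = 1[chem>0 or elec>0]`: type- and
  multiplicity-blind.
* **scaled** — `A = c_ch·1[chem>0] + 0.5·c_el·1[elec>0]` for per-type
  weight experiments (doubling one type, zeroing the other, …).

Cost functions `d`: the `l1` norm, and `‖x−y‖₂^p` for `p ∈ {1,2,3,4}`.
`p ≥ 2` are not metrics (no triangle inequality) but are standard wiring
cost models; TWL under them carries units mm^p, so displacement summaries
are always reported in plain Euclidean mm as well — powered-norm averages
shrink mechanically when typical distances are below 1 mm and are not
comparable across `p`.

The placement problem anchors motor and sensory neurons (and optionally
designated interneurons) at their real coordinates and minimizes TWL over
the free interneuron positions. Because the objective only sees the
symmetric part of `A`, solvers work with `w = A + Aᵀ` and
`TWL = ½ Σ w_ij d_ij`; this is an internal reformulation, never a semantic
change.

## Solvers

* **Squared Euclidean cost.** The objective is a convex quadratic;
  stationarity for free node `i` is `x_i Σ_j w_ij = Σ_j w_ij x_j`, a
  weighted graph-Laplacian system with the anchors as Dirichlet boundary
  values, solved sparsely per coordinate. This is exact (one linear solve),
  and is also the warm start for every other solver.
* **Euclidean cost (multifacility Weber).** IRLS on the smoothed cost
  `√(d² + ε²)`: each iteration solves the Laplacian system with weights
  `w_ij/√(d_ij²+ε²)`. ε is annealed from 1e-3 to 1e-12 of the coordinate
  scale (anchor bounding-box diagonal) in decade steps; convergence per
  level at relative objective change ≤ 1e-10, global iteration cap 10⁴
  (exceeding it returns the best layout flagged unconverged). Degenerate
  optima (e.g. collinear two-anchor instances, or strongly coupled free
  nodes collapsing to one point) are handled by the smoothing; tests assert
  objectives, not coordinates, in such cases.
* **l1 cost.** Separable across coordinates. If no free–free edge exists,
  each free coordinate is an independent weighted median (when the optimum
  is an interval, its midpoint is returned for determinism). Coupled
  instances are solved per coordinate as an LP (`min Σ w_e t_e` s.t.
  `t_e ≥ ±(x_i − x_j)`) with HiGHS; the vertex solution is a global
  optimum.
* **Cubed/fourth-power cost.** Smooth convex minimization (L-BFGS with
  analytic gradient) from the quadratic optimum; gradient tolerance
  1e-10 × coordinate scale. Routing `p = 2` through this path reproduces
  the exact linear solve and serves as a consistency check.

Structural handling, all solvers: a free node with no edges keeps its
input position (with a warning, recorded in diagnostics); a free component
with edges but no path to an anchor raises an error naming the component
(its optimum is translation-invariant, the problem ill-posed). Fixed rows
are copied bit-identically into the solution; the reported objective is
recomputed through the public TWL function.

* **Minimal inter-neuron distance.** The soma-exclusion constraint
  `d_ij ≥ δ` for every pair with a free endpoint makes the problem
  nonconvex; only a local refinement from the convex optimum is attempted.
  If the warm solution already satisfies the constraint it is returned
  unchanged. Otherwise violating pairs are separated deterministically
  along their connecting direction (coincident pairs get a
  deterministic index-derived direction), then the layout is polished with
  SLSQP on the active constraint set (`d_ij² ≥ δ²` for pairs within 2δ),
  iterating separation/polish until every pair satisfies the constraint to
  1e-9·δ. The pre-separation step matters because the constraint gradient
  vanishes exactly at coincident pairs. An optional bounding-box clamp is
  available for this refinement. The objective can only rise relative to
  the warm start; at soma-scale δ the increase is far below 0.1% because
  only near-coincident pairs are touched.

## Random-placement null

Free nodes are drawn i.i.d. uniform over the body region, fixed nodes stay
at their real positions, and the TWL is recorded per draw (default 1000
draws). The body outline is not part of the input data, so the region is a
reconstruction: the axis-aligned bounding box of all real positions by
default, or the convex hull (rejection sampling) as a tighter proxy; the
choice is recorded in the result alongside the seed. The contract is the
ordering `optimal ≤ real ≤ random mean` and 1/√n convergence of the mean,
not any particular absolute value, which depends on the region shape.

## Scenario statistics

From the three headline values the pipeline derives
`reduction_abs = real − opt`, `reduction_pct = 100·reduction_abs/real`,
`pct_below_random = 100·(random − real)/random`, and
`random_excess_pct = 100·(random − real)/real`; these identities hold to
1e-9 relative and are what published comparison tables of such analyses
print. Displacements (real vs optimal position per free node) are
histogrammed with half-open bins (default width 0.05 mm). Outliers are
detected from the largest inter-point gap in the sorted displacements
exceeding a threshold (default 0.2 mm) rather than a fixed cutoff, because
the location of the empty band between "barely moved" and "moved far"
neurons is dataset-specific. Mean displacement is also expressed as a
percentage of body length, taken as the anterior–posterior extent of the
anchor positions — the only body-length proxy reconstructible from the
inputs. Re-fitting with outliers anchored can only lower the reduction
(anchoring monotonicity), quantifying how much of the optimality gap those
neurons carry.

## Synthetic generator

`SynthConfig` defaults define the study conditions: 200 anchors — 90 head,
70 tail, 40 ventral cord — and 80 free interneurons (mirroring a
193-fixed/86-free connectome partition at similar scale) in a 1.2 × 0.15 mm
body (adult-hermaphrodite scale). Head anchors occupy the anterior 12% of
the body, tail anchors the posterior 12%, cord anchors a thin ventral band;
head anchors lean sensory, tail/cord anchors lean motor. Each ordered pair
is wired chemically with probability `chem_fraction·exp(−d/λ)` and each
unordered pair electrically with probability `(1−chem_fraction)·exp(−d/λ)`,
with λ = 0.1 mm and `chem_fraction = 0.85` (chemical synapses outnumber
gap junctions severalfold in real wiring diagrams). Multiplicities are
i.i.d. geometric with mean 2.5 — a low-variance, "fairly even" count
distribution; the variance is configurable to probe the opposite regime.
Everything derives from one seed; an empty graph triggers regeneration
with a derived seed up to a retry cap.

The generator reproduces the qualitative structure the analysis needs —
two anchor clusters plus a cord, distance-decaying connectivity, head-ward
pull on tail-placed interneurons wired to the head — but not the real
degree distribution, bilateral symmetry, or neuron-class-specific wiring
rules, so synthetic results validate the machinery and its invariants, not
the biological magnitudes. The planted mode replaces free positions with
the exact quadratic-cost optimum, giving instances with a known solution
for recovery tests (recovery to ≤ 1e-6 mm is part of the acceptance
suite).

## Problem sizes and numerics

The default test and acceptance workloads use the full 280-neuron synthetic
instance for pipeline runs (solvers finish in under a second) and batches
of ~25-neuron instances for the 50-fold planted-recovery check; brute-force
grid oracles are applied to instances with ≤ 3 free nodes, where exhaustive
search is meaningful. Monte-Carlo calibration uses 1e5 draws against
two-dimensional quadrature on a one-free-node problem. Floating-point
accumulation uses fixed elementwise order, so repeated runs with one seed
are bit-identical. All tolerances and iteration caps cited above are
function arguments with those defaults.

## Known limitations

* Straight-line (or powered straight-line) costs only; no along-body or
  neurite-routing distances. Cell-body positions proxy wire length, which
  is inexact for *en passant* synapses.
* The min-distance refinement is local; no global nonconvex solve.
* The 2D body outline is unknown to the package, so random baselines
  depend on the chosen region proxy.
* Exact reproduction of published millimetre values for the real
  *C. elegans* network requires the external position/connectivity tables
  in the documented formats; with the synthetic generator, only the
  orderings, identities and convergence properties are meaningful.
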