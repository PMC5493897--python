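# Methods

This note records the model conventions, numerical choices and known
limitations of `grnscape`.  Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Model and conventions

**State and forces.** Expression levels `v_i ∈ (0,1)` are mean-field
averages of underlying two-state (on/off) genes.  `W[j,i]` is the directed
force of gene *j* on gene *i* (row = source, column = target — enforced by
the config validator), `l_i` a constant external input.  The total force is
`h_i = Σ_j W[j,i] v_j + l_i`; the open interval is required because the
mixing entropy has infinite slope at 0 and 1.

**Noise convention, Θ = 2T.** The user-facing noise parameter is the
temperature `T`; the entropy weight in the landscape is `Θ = 2T`.  This
factor is fixed by requiring that gene-by-gene stationarity of the
free energy coincide *exactly* with the fixed points `v_i = g(h_i/Θ)` of
the rate equation — the correspondence the whole method rests on.  Only the
pairing of `T` values with landscapes depends on this convention, not any
qualitative result.

**Decomposed vs landscape energy.** Because `W` is in general asymmetric,
no single-valued energy has all the one-sided forces as its gradient.  Two
related quadratics are therefore exposed:

* `internal_energy(..., per_gene=True)` returns the per-gene decomposed
  parts `E_i = −½[Σ_{j≠i} W[j,i] v_j v_i + ½W[i,i] v_i² + l_i v_i]`, whose
  own-gene derivatives are exactly `−h_i/2`.  These generate the dynamics;
  the frozen-partner stationarity identity is verified to 1e−8 for random
  asymmetric matrices.  Their sum counts every reciprocal coupling twice
  (once per direction).
* `landscape_energy` returns `E = −¼ vᵀWv − ½ lᵀv`, which counts each
  unordered pair once at the *mean* of its two directed strengths and each
  self-interaction with the same ¼ coefficient as the decomposition.  This
  is the unique quadratic whose full gradient reproduces the one-sided
  forces whenever couplings are reciprocal (symmetric `W`); `free_energy`
  and the grid use it.  A naive ½ coefficient would double-count every
  pair in the gradient, displacing landscape minima away from the
  dynamical fixed points *even for symmetric matrices* — with the ¼ form
  the two routes agree exactly in the symmetric case (verified on random
  instances), and asymmetric circuits incur only the mean-coupling error.

The practical consequence: for strongly one-sided interactions the
landscape feels half the directed force.  The test suite asserts the
two-route agreement empirically for every zoo circuit; for arbitrary
asymmetric networks it can fail, which is the method's documented
approximation, not a bug.

**Degradation.** `γ` generalises the `−v_i` decay term of the rate
equation and enters the dynamics only; the free-energy derivation has no
degradation parameter, so the landscape always assumes `γ = 1`.
Sensitivity sweeps over `γ` therefore report dynamics-derived summaries
(fixed-point counts) and NaN barriers rather than inventing a deformed
landscape.

## Grid, graph, attractors, paths

* **Cell-centred grid.** `d` bins per axis with centres `(k+½)/d` keep all
  evaluations strictly inside `(0,1)`, where the entropy is finite.  `F`
  is shifted additively so `min F ≥ 0`.  Default resolutions
  `d = 200/50/40/25` for `N = 1/2/3/4` keep the cell count near a few
  hundred thousand; a configurable budget (default 10⁷ cells) guards
  against accidental blow-ups.
* **Orientation and ties.** Each axis-adjacent pair carries exactly one
  edge, from higher to lower F; exact ties point to the lexicographically
  smaller index tuple.  This deterministic rule replaces breaking ties
  with an arbitrarily small perturbation and, as a corollary, forbids
  directed cycles outright: every strongly connected component is a
  singleton.  The condensation machinery still handles arbitrary digraphs
  and is cross-checked against an O(V³) reachability-matrix oracle.
* **Attractors.** Condensation sinks with indegree ≥ 1, sorted by F; a
  multi-cell sink (impossible under the tie rule, but supported) would be
  represented by its minimum-F member.
* **Basins.** Every cell is labelled by the attractor it reaches along
  descending edges; cells that reach several are assigned by the shorter
  descending Dijkstra distance.  Because descending edge weights telescope
  (any descending route from cell *c* to attractor *a* costs exactly
  `F(c) − F(a)`), this distance rule effectively assigns dual-reach cells
  to the reachable attractor with the *highest* floor, and cells above two
  equal-F attractors tie exactly and are labelled ridge.  On the perfectly
  symmetric toggle switch this makes the entire dual-reach region a ridge
  — deterministic and symmetric, but a large set; treat ridge counts as a
  property of this rule, not as a measure of a geometric ridge line.
* **Paths.** Attractors are sinks, so routes are computed on the
  undirected adjacency with non-negative weights.  Two readings of the
  free-energy change are provided: `abs` (`|ΔF|`, the default; path length
  = total variation of F, symmetric in the endpoints) and `uphill`
  (`max(0, ΔF)`; length = total ascent, and forward/reverse lengths differ
  exactly by `F(target) − F(source)`, asserted numerically).  The barrier
  is `max F` along the route minus `F(source)`.  Dijkstra totals are
  verified against exhaustive simple-path enumeration on small grids; SCC
  detection and Dijkstra themselves are delegated to
  `scipy.sparse.csgraph`, with deterministic (implementation-defined) tie
  resolution among equal-length routes.
* **Saddle artefacts.** With axis-aligned (von Neumann) adjacency, a
  saddle whose descent directions are diagonal can appear as a shallow
  lattice minimum once the surface is flat relative to the grid
  quantisation (e.g. the toggle's central saddle at temperatures near the
  bistability boundary).  Analyses that traverse temperature ladders
  therefore select route endpoints by expression pattern (lowest-F
  attractor per documented high/low signature) rather than assuming the
  attractor count stays two away from the default parameters.

## Dynamics and fitting

* **Integrator.** Forward Euler with the stability guard `dt·γ/η < 1`,
  iterates clamped to `[1e−9, 1−1e−9]`; the Euler map is the reference
  contract, not an approximation to it.  `steady_states` integrates from a
  seeded Halton sequence over `(0.02, 0.98)^N`, refines each limit by
  damped Picard iteration to 1e−10 and deduplicates at 1e−4 (max-norm).
* **Fitting to time series** minimises squared discrepancies between
  observed increments and Euler-predicted increments over masked `W`, `l`
  entries, with bounded trust-region least squares (default bounds
  `W ∈ [−20, 20]`, `l ∈ [−10, 10]`) and seeded multistart; a fit with more
  free parameters than increment residuals is rejected as
  under-determined.  Identifiability of a saturating switch comes from
  transient data: the recovery experiment uses ten short trajectories
  (five observations each, spacing 0.2) launched from a Halton design over
  the state square, giving exact recovery from noiseless data and ≲15%
  worst-entry error at observation noise σ = 0.01.
* **Fitting to attractors** minimises the fixed-point defect at the target
  states with a hinge penalty on the spectral radius of the fixed-point
  Jacobian `J[i,j] = g′(h_i/Θ) W[j,i]/Θ` (margin 0.95), using bounded
  derivative-free Powell search with seeded multistart; infeasibility is
  reported with the violating target.

## The model zoo and its re-derived parameters

Only the *sign patterns* of the five circuits are literature-derived; no
published magnitudes are used.  The toy models are hand-set: the single
self-activating gene (`w = 4`, `l = −2`) is bistable for `T < 0.5`, and
the symmetric toggle (`self = 2`, `cross = −4`, `l = 1`) for `T < 0.75`.

For the three asymmetric circuits the defaults must make the documented
pair of cell states appear as exactly two attractors by *both* routes,
agreeing within one grid cell, with the documented gene orderings along
the optimal routes.  Exact joint placement is provably impossible for
these sign patterns (a gene whose switching force arrives through a
one-sided edge always feels a strictly different landscape force), so the
derivation (`scripts/derive_zoo_params.py`) instead drives both routes'
attractors into the same deeply saturated corner cells: bounded least
squares over `(W, l)` with hinge residuals requiring a strong
self-consistent force at the two wanted corner patterns for the dynamics
matrix *and* its symmetrisation, rejection of every unwanted corner
pattern, and — where an ordering is documented — free-energy ordering
constraints between candidate saddle corners (the GATA2-high/PU.1-high
pass must undercut the alternatives, which is what makes GATA2 rise before
PU.1 falls on the myeloid-to-erythroid route; likewise OCT4-SOX2 precedes
NANOG on the stem cell reprogramming route).  The resulting constants are
frozen in `grnscape.zoo` at `T = 0.25`; the derivation script reproduces
and re-verifies them deterministically.

Consequently the zoo's attractor *positions* are deliberately extreme
(near-corner expression) and the landscape *shapes* carry no quantitative
claim; only the attractor repertoire, its agreement across routes, the
temperature trends and the route orderings are asserted.

## Synthetic data generator

`generate_synthetic_timeseries` integrates a zoo circuit with the Euler
step equal to the output spacing and adds seeded i.i.d. Gaussian
observation noise, clipped back into `(0,1)`.  It emulates densely and
regularly sampled, fully observed expression measurements with known
network topology.  It does **not** emulate intrinsic (copy-number)
stochasticity, unobserved genes, measurement calibration drift or
irregular sampling — so passing recovery tests show correctness of the
estimator under the model's own assumptions, not robustness on real
expression data.

## Problem sizes and determinism

Default analyses run on grids of 200 (1 gene) to 25⁴ ≈ 3.9×10⁵ cells
(4 genes); the full acceptance computation, including the four-gene
landscape, its condensation and routes, completes in well under a minute
on one core.  All stochastic components (multistart optimisers, Halton
starts, observation noise) are seeded; identical seeds give bit-identical
reported values.

## Known limitations

* The landscape exists only up to the mean-coupling approximation;
  strongly anti-symmetric circuits (e.g. ring oscillators) fall outside
  the method's domain and the two routes may then disagree or the
  landscape may show spurious minima.
* Basin labels for dual-reach cells follow the degenerate telescoping rule
  described above.
* No stochastic simulation, no transition-rate (Kramers) estimates, no
  cooperative (triplet) couplings — the type stores them, nothing
  evaluates them — and no topology inference: interaction masks are
  user-supplied.
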