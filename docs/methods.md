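# Methods

## Model

`infinet` implements a three-state spin cascade on a directed network.
The network is unweighted and simple: self-loops are removed at ingestion
and parallel duplicate links collapse to one (the adjacency convention is
Aᵢⱼ = 1 iff j → i, with Aⱼⱼ = 0).  Two matrices derive from A:

- **S̃** — column-normalized adjacency, S̃ᵢⱼ = Aᵢⱼ/Σₗ Aₗⱼ, with all-zero
  columns at dangling nodes (no outgoing links).
- **S** — the proper column-stochastic matrix, equal to S̃ except that
  dangling columns become the uniform vector 1/N.

S is used only for ranking; the spin dynamics use the symmetrized coupling
**W = S̃ + S̃ᵀ** built from S̃, so dangling nodes exert no artificial
uniform influence on the cascade.  S is never materialized densely: the
Google operator applies G v = α(S̃v + (Σ_dangling v)/N) + (1−α)·Σv/N
matrix-free (`s_dense()` exists for small test networks only).

Each node carries σᵢ ∈ {−1, 0, +1}.  Panel nodes are pinned: red (+1,
activator) and blue (−1, repressor) spins never change.  One **sweep**
visits every variable node once, in a freshly drawn uniform random
permutation, and sets σᵢ ← sign(Zᵢ) with Zᵢ = Σ_{j≠i} Wᵢⱼ σⱼ, keeping the
previous spin when Zᵢ = 0.  Updates are asynchronous: each new value is
visible to later updates in the same sweep, so the sweep order matters and
the ensemble over orders is part of the model.  A **realization** starts
white everywhere except the pinned panels and any initial (non-pinned)
blue seeds, runs up to `tau_max` sweeps (default 100, matching the regime
where typical runs freeze after ~10 sweeps and rare ones take ~70), and
exits early at the first sweep that changes nothing — that sweep is a true
fixed point for every order, because all fields were evaluated at an
unchanged global state, so the early exit is exact, and `tau_last` records
it.  An **ensemble** of R independent realizations yields fr(i), the
fraction of realizations where node i ends red, and fr = Σᵢ fr(i)/Nv over
the Nv variable nodes.

### Assumptions and scope

- Links are unweighted and unsigned; activator/inhibitor link polarity is
  deliberately out of scope (the sign structure lives entirely in the
  pinned panels).
- The update rule has no temperature or noise and no inertia: any nonzero
  field flips a node, however small.  One consequence, verified by exact
  enumeration in the tests: a lone blue seed adjacent to a pinned red node
  flips red whenever it is updated before acquiring a blue neighbor, so
  even a perfect structural bottleneck has frc bounded away from zero by
  an order-race probability.
- Initial blue seeds are variable and may flip; only panel nodes are
  pinned.

## Randomness and reproducibility

Realization r of a run with master seed s uses the independent substream
`SeedSequence(entropy=s, spawn_key=(r,))` for both the initial-blue draw
and every sweep permutation.  Results are therefore independent of
execution order, and identical seeds reproduce ensembles bit-for-bit —
the workflow layer records each run in a manifest (parameters, seed,
package version, input digests) whose replay reproduces output files
byte-identically.  An exact global symmetry is preserved by the
implementation and asserted in the tests: swapping the red and blue roles
under identical streams negates every final spin exactly (IEEE negation
is exact, so sign(Z) flips exactly).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 0.85 | damping factor of the Google matrix |
| power-iteration tol | 1e−12 (L1) | restart-stable ranks; residual bound ‖GP−P‖₁ < 10·tol |
| tau_max | 100 | sweeps per realization (early exit on convergence) |
| R | run-dependent | realizations; fr(i) has binomial error √(fr(1−fr)/R) |
| n_b | all panel blues | how many panel blues are pinned (prefix of panel order) |
| n_ib | 0 | initial blue seeds per realization |
| Δfr | 0.01 | histogram bin width |
| tail fr_min | 5e−3 | lower cutoff of the log-log tail fit |
| min_support | 100 | conditional frc estimates below this are flagged undefined |

Rank indices are 1-based; ties (in rank_index, Kfr, and group selection)
break by ascending node index — the source material never mentions ties,
so the rule is simply deterministic and documented.

## Estimators

`rank_single_blue` measures frc(i) by dedicated fixed-configuration
ensembles (one per candidate, independent derived seeds).
`conditional_frc` instead conditions a single random-placement ensemble
post hoc on the draw containing (or exactly equaling) a query
configuration; the two agree within Monte Carlo error, which the tests
assert.  Conditional estimates report their support count and refuse to
report numbers below `min_support` (the useful regime in practice is
support ≳ 1000; the threshold is exposed).  The consistency identity
fr = ∫ fr·p(fr) dfr is exact here because the distribution object retains
the per-bin first moment of the empirical measure; evaluating the integral
with bin centers instead reproduces only the familiar approximate check
(≈ 0·w₀ + peak·w₁).

## Synthetic generator: what it emulates, what it does not

The generator produces a directed preferential-attachment graph (new nodes
attach to in-degree-weighted targets, exponent configurable, 3-node seed
cycle per component; edge counts are topped up to the target with
preferential extra links).  Defaults emulate the gross structure of the
large curated PPI network the model was developed on: mean out-degree 7.3,
a hub-unreachable fraction of 0.18 forming its own small component (the
stable-white set), 10 red and 6 blue panel nodes.

Two deliberate design choices:

- **The red panel is *not* the top hubs.**  The red activators get
  in-degree near `red_degree_factor` (default 2.4, the observed
  shell-to-panel ratio of the real activator panel) times the mean degree.
  At desk scale (N ≈ 1000) pinning the top hubs red makes the panel
  adjacent to ~80% of the network, the outcome becomes order-independent
  and no barrage can work — whereas the real geometry has modest-degree
  activators whose Erdös shell *contains* the top hubs, which is exactly
  why a small blue barrage can outrace the cascade.  With this choice the
  synthetic benchmark reproduces the qualitative phenomenology: fr(0) ≈
  0.8, monotone decay of fr with n_ib, and a clear advantage for
  Erdös-shell placement.
- **The blue panel is drawn from mid-degree nodes**, mirroring the
  observation that curated repressor panels sit far from the top of the
  K/K* rankings.

What a green test on synthetic data does **not** establish: agreement with
any number measured on the proprietary network (node counts, NE = 353,
specific frc values, the fr ≈ 0.76 baseline, the −1.5 tail).  Those
quantities depend on the real topology; the machinery that computes them
is fully implemented and exactly tested on enumerable fixtures, but the
published values themselves are not reproducible without the network.
The generator also makes no attempt to match the real degree sequence,
bi-functional link statistics, or biological annotations.

## Numerical choices

- Power iteration starts uniform; non-convergence raises with the last
  residual.  Agreement with a dense eigensolver is asserted to L∞ ≤ 1e−9
  on all fixtures with N ≤ 50.
- The sweep kernel is a numba-compiled CSR loop; the low-level `sweep` API
  and the ensemble engine share it, so there is one dynamics
  implementation.  Tests cross-check it against an independent dense
  double-loop oracle and against exact enumeration over all sweep orders
  (propagating a probability measure over distinct states, which is
  mathematically identical to expanding all (Nv!)^τ order sequences).
- Histogram bins are half-open [kΔ, (k+1)Δ) with the last bin closed at 1;
  the CCDF uses strict inequality (fraction of values strictly greater);
  the median is the smallest observed value with P ≤ 0.5, with no
  interpolation — at ensemble resolution 1/R this reproduces the discrete
  medians such ensembles report (e.g. 10⁻⁵ at R = 100,000).
- The tail exponent is an ordinary least-squares slope of log P vs log fr
  over points with fr ≥ fr_min and P > 0 (≥ 10 points required); the
  standard error flags poor power-law fits.
- Degenerate inputs: edgeless networks give S̃ = 0 and uniform S and
  PageRank; an empty variable set makes a sweep a no-op with tau_last = 1;
  empty samples are rejected rather than summarized.

## Known limitations

- Purely asynchronous dynamics; no synchronous variant, temperature, or
  continuous opinion states.
- `evaluate_all_subsets` is limited to groups of ≤ 12 nodes (2^k runs).
- The generator's hub-unreachable component is structural (a separate
  component); it does not model nodes connected to the giant component but
  isolated from any particular panel.
- Conditional frc for configurations ("exact" mode) needs very large
  ensembles to accumulate support; the dedicated fixed-configuration
  estimator is preferred for small groups.
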