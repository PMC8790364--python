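# Methods

## Model

A circular lattice of `N` CpG dyads, each in one of three states:
unmethylated (`u`), hemimethylated (`h`), methylated (`m`). Transitions
are single-site and never jump directly between `u` and `m` (methylases
and demethylases act on one strand at a time, so `h` is an obligatory
intermediate). Twelve reactions, four non-collaborative
(`u→h`, `h→m`, `m→h`, `h→u`) and eight collaborative, in which a mediator
CpG — restricted to the target's two nearest neighbours — promotes the
transition without changing its own state. The rates are parameterized by
three numbers:

| | demethylation | methylation |
|---|---|---|
| non-collaborative | `k3 = k4 = a` | `k1 = k2 = a·y` |
| collaborative | `k9..k12 = a·x` | `k5..k8 = a·x·y` |

`a > 0` (time⁻¹) sets the clock and cancels from every steady-state
statistic (asserted numerically in the tests); `x ≥ 0` is the
collaborativity strength; `y ≥ 0` the methylation strength. `y = 1` is the
symmetry point where relabelling `u ↔ m` maps the system onto itself; all
steady-state statistics obey `μ_u(x, y) = μ_m(x, 1/y)`.

Per-site exit channels (the two neighbour slots are directed, so for
`N = 2` the single other site is counted twice — this keeps the finite
lattice consistent with the factor-of-two structure of the mean-field
effective rates):

* `u → h` at `k1 + k5·n_h + k6·n_m`
* `h → m` at `k2 + k7·n_h + k8·n_m`; `h → u` at `k4 + k11·n_h + k12·n_u`
* `m → h` at `k3 + k9·n_h + k10·n_u`

with `n_s` the number of neighbours in state `s`.

## Stochastic simulation

Gillespie's direct method with O(1)-per-event updates: per-site exit
propensities are kept in an array with 32-site block partial sums, so site
selection is a two-level linear scan and an event touches only the target
site and its two neighbours. Running sums are re-consolidated every 2¹⁶
events to bound floating-point drift. All randomness comes from one seeded
generator per run; identical (parameters, config, seed) give bit-identical
snapshot matrices.

**Steady-state detection.** The paper-level notion "proportions fluctuate
around fixed values" is operationalized as: average the time-weighted
u/h/m proportions over windows of `max(50·N, 10⁴)` events and declare
steady state when two consecutive window-to-window changes are below 0.01
in max norm. The 10⁴-event floor keeps the window average quiet enough for
the tolerance on very small lattices, where a 50·N-event window is
dominated by shot noise. Window size, tolerance, the number of required
consecutive passes and a fixed-event override are all exposed in
`SimConfig`; a run that does not stabilize within `max_events` (default
10⁹) raises a convergence error naming the budget.

**Snapshot spacing.** Snapshots are taken at constant intervals
`Δt = N / Φ̂`, with `Φ̂` the mean total propensity over the last burn-in
window — about one reaction per site between snapshots, so successive
rows are substantially decorrelated in every parameter regime. An
absorbed chain (`y = 0` reaches the all-`u` state, where no reaction can
fire) simply repeats its final pattern.

**Read emulation.** To mimic hairpin-bisulfite sequencing — short reads,
both strands of one molecule, no linkage between reads — a pool of
`T = 10⁴` steady-state snapshots of an `N = 1000` lattice is generated and
each CpG independently draws `coverage = 30` snapshot indices without
replacement. The flat dataset deliberately destroys within-molecule
spatial information; only the mean and variance of the `z` encoding
survive for inference, exactly the situation with real short-read data.
The emulation does **not** model bisulfite conversion failure, sequencing
error, mapping bias or coverage variation, so passing recovery tests
demonstrate identifiability from ideal moments, not robustness to assay
noise.

## Pattern statistics

Snapshots are encoded `z = u + 2h + 3m ∈ {1, 2, 3}`. Per snapshot row the
estimators are: the mean of `z`; the site-to-site variance with
denominator `N − 1`; and the covariance between the row and its cyclic
shift by one site, centred on the row mean, with denominator `N`. Rows are
then averaged and the neighbour correlation is the ratio of the averaged
covariance to the averaged variance. The mixed denominators are kept
deliberately — the correlation is defined through exactly this pair of
conventions. Degenerate inputs (zero variance, e.g. an absorbed run)
flag the correlation as undefined rather than emitting NaN.

Two consequences of the row-centred conventions worth knowing:

* for `N = 2` and `N = 3` the per-row correlation is *identically*
  −1/2 and −1/3 regardless of parameters (a centring identity), so
  comparisons at those sizes use absolute tolerances;
* for general `N` the estimators differ from the population (infinite-`N`)
  moments by `−Var(row mean) = O(1/N)`: measured against the OPMF
  prediction at `x = 5, y = 1`, the variance gap shrinks as
  0.0226 (`N=100`) → 0.0100 (`N=200`) → 0.0038 (`N=500`) → 0.0019
  (`N=1000`), while grand-mean estimators at `N = 1000` agree with OPMF to
  ~0.1%. At `N = 200` this bias is an order of magnitude larger than the
  Monte-Carlo standard error of a 10⁶-state replicate, so
  strict SE-scaled comparisons of variance/covariance/correlation against
  infinite-`N` model predictions resolve the estimator bias, not model
  error. The mean levels are unaffected (they are unbiased).

## Mean-field models

All three models are independent of `N` and of `a`.

**One-site.** Each site sees only the mean occupancies. The four effective
rates (`m→h`: `k3 + 2k9·μ_h + 2k10·μ_u`, etc.; the `k7`/`k11` terms carry
an extra factor of two because those reactions involve two `h` reactants,
either of which may change) define implicit equations for `(μ_u, μ_h)`
solved by damped fixed-point iteration (damping 0.5, residual < 10⁻¹⁴,
jitted; random-start root-finder fallback). Because single-site indicator
variables satisfy `L_i L_j = δ_ij L_i`, all second moments collapse to the
means; the package also integrates the three second-moment ODEs at the
fixed point and checks that they relax to exactly this collapse. The model
yields `μ_z` and `σ²(z)` but no spatial statistics.

**Pair models.** The state space is the six unordered CpG pairs
(`mm, uu, hh, um, hm, uh`) with proportions `μ₁..μ₆`. Twelve effective
first-order reactions connect them; the effective rates fold the influence
of flanking sites into either the mean pair state (DPMF — disjoint tiling
of the lattice) or conditional probabilities of the flanking site given
the shared site (OPMF — every site belongs to two pairs). OPMF conditional
terms with an empty condition (zero denominator) are defined as 0, which
keeps the rates finite on the simplex boundary. The steady state is the
fixed point of: build the 6×6 generator at the current proportions, solve
for its stationary distribution (dense null-space solve with the
normalization row replacing one redundant balance equation), mix back with
damping 0.5; iterate to residual < 10⁻¹². The solver starts from the
product measure built on the one-site solution; a handful of seeded
Dirichlet starts probe for fixed-point multiplicity and, if distinct
solutions appear, the principal branch is chosen by continuation in `y`
from the unique `y = 0.1` regime. In all regimes probed (`x ≤ 100`,
`y ≤ 2`, including the `y = 1` transition at `x = 50`) the fixed point was
unique.

Site-level statistics follow from the pair proportions: means by splitting
mixed pairs evenly; `⟨vw⟩ = μ₂ + 2μ₆ + 3μ₄ + 4μ₃ + 6μ₅ + 9μ₁` gives the
neighbour covariance `⟨vw⟩ − μ_z²`; and the site variance comes from the
pair-level variance of `(v + w)/2` via `σ²(z) = 2σ²(ẑ) − Covar(v, w)`.

**Sensitivities.** Relative sensitivity `S_p(Q) = (p/Q)·∂Q/∂p` by central
differences with step `0.01·p`, applied to the two statistics inference
consumes (`μ_z`, `σ²(z)`); the scalar x-to-y ratio is the Euclidean norm
of `(S_x(μ_z), S_x(σ²))` over the same for `y`. On the grid
`x ∈ {0.1, 1, 5, 50} × y ∈ {0.3 … 1.7}` the ratio is everywhere below
one: the model is more sensitive to methylation strength than to
collaborativity, which is why `y` is recovered more accurately.

## Inference

ABC-SMC with the OPMF moment prediction as a deterministic forward model
(a few hundred microseconds per evaluation, so likelihood-free inference
is desk-fast). Distance: sum of absolute relative errors of the mean and
variance of `z`, data moments in the denominators. Priors: independent
uniforms `U(0, 100)` for `x`, `U(0, 2)` for `y`. Defaults: 200 particles;
first population sampled directly from the prior; subsequent tolerances at
the 30th percentile of the previous population's accepted distances;
perturbation kernel a bivariate Gaussian with covariance `2×` the weighted
sample covariance of the previous population (the posterior is a thin
ridge with `corr(x, y)` up to ~0.99 in demethylation-dominant regimes, so
an axis-aligned kernel cannot track it); standard SMC importance weights
(uniform priors make the numerator constant; proposals outside the support
are rejected).

**Final tolerance.** A tolerance schedule must not tighten below what the
model can achieve on the data at hand. The recovery pipeline therefore
computes the *true distance* between the data moments and the OPMF
prediction at the generating parameters and sets the final tolerance to
1.5× that value; the adaptive 30th-percentile schedule then runs past the
default five populations (capped at 40) until the final tolerance is
reached. Typical runs use 9–14 populations and finish in seconds to tens
of seconds per dataset.

**Summaries.** Point estimates are weighted posterior means. The 95%
interval trims exactly 2.5% of the posterior mass from each tail: the
lower endpoint is the smallest sample whose cumulative weight strictly
exceeds 0.025 (symmetric at the top). For equal weights this reproduces
"drop the lowest and highest 2.5% of samples" exactly.

## Problem sizes

The test suite and the acceptance script use desk-scale versions of the
study design: oracle comparisons at `N ∈ {2, 3, 4}` with 10⁵ snapshots;
the model-comparison grid at `N = 200`, `T = 5000` snapshots, 5
replicates, `x ∈ {0.1, 1, 5} × y ∈ {0.3, 0.7, 1.0, 1.3, 1.7}`; recovery
at `N = 1000`, 10⁴-snapshot pool, coverage 30, for
`x ∈ {0.1, 1} × y ∈ {0.3, 1, 1.7}`. These sizes reproduce the qualitative
structure (transition at `y = 1`, correlation peak, sensitivity ordering)
and the recovery accuracy of the full-scale study while completing in
minutes on one CPU.

## Known limitations

* Collaborativity is strictly nearest-neighbour; distance-dependent or
  all-to-all mediation and replication/cell-cycle dynamics are out of
  scope.
* The pair models truncate correlations at adjacent pairs; cluster sizes
  and higher-order statistics beyond the seven summary statistics are not
  predicted.
* Inference uses only two moments; regimes where `(x, y)` trace a long
  flat distance ridge (strong demethylation, `y ≪ 1`) are weakly
  identified — posteriors there are honest but wide, and `x` can be off
  by factors of 2–8 while `y` stays within ~20%.
* The read emulator captures sparse, unlinked sampling but no assay noise.
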