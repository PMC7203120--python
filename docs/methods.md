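# Methods

## The generating model

A binary character and the phylogeny are simulated jointly under BiSSE.
At any instant a lineage in state *i* ∈ {0, 1} undergoes

* speciation at rate λ_i (both daughters inherit *i*),
* extinction at rate µ_i,
* character transition at rate q_ij (i → j, j = 1 − i).

All rates are per lineage per unit time and constant in time. One lineage
begins in state 0 at time zero, so state 0 is the ancestral state and any
directional bias (q01 ≠ q10, µ0 ≠ µ1, λ0 ≠ λ1) is defined relative to it.

Events are drawn exactly (Gillespie): the total rate across extant lineages
sets an exponential waiting time and the event/lineage is chosen
proportionally to its rate — no time discretisation. The simulation stops at
the instant the target extant-tip count *n* is first reached; attempts whose
clade dies earlier are rejected and counted (this is the survival
conditioning). We also measured the main alternative stopping rule —
continuing past *n* until the next speciation is drawn while at *n* — and
found the two indistinguishable at the study's rates (differences < 0.1
percentage points in tip-state statistics and < 0.01 time units in depth),
so the simpler rule is used.

After acceptance, lineages without extant descendants are removed,
single-child nodes are suppressed (their incident branch lengths summed),
and the tree is re-rooted at the earliest bifurcation with surviving
descendants on both sides. The true state at every node (the lineage's
state at that time point) is retained, as is the number of character
transitions lying on branches of the pruned tree — the covariate the error
regressions use. A flag switches to counting all transition events of the
accepted simulation instead (including on extinct lineages); with pruned
counting, a variant tip character implies at least one counted transition,
which keeps the regression's log(transitions) defined for every analysed
tree.

Trees whose tip character is invariant are simulated, flagged and *then*
excluded from analysis (not resampled), so exclusion statistics are
observable. Per-tree seeds are derived by hashing (global seed, scenario id,
replicate), making every tree independently reproducible and runs resumable
and order-independent.

## The scenario grid

Extinction rates µ0, µ1 ∈ {0.01, 0.25, 0.5, 0.8}; transition rates
q01, q10 ∈ {0.01, 0.05, 0.1}; speciation pairs (λ0, λ1) ∈ {(0.2, 1.8),
(0.5, 1.5), (1, 1), (1.5, 0.5), (1.8, 0.2)} — 16 × 9 × 5 = 720 scenarios,
400-tip trees, 500 replicates at full scale. Mean speciation is pinned to 1,
so time is measured in expected speciation waiting times, and λ/q ≥ 10
keeps reconstruction theoretically feasible. Named subsets: the 144
state-independent-speciation scenarios (λ0 = λ1 = 1), the 360
*expanding-clade* scenarios (µ_i < λ_i for both states), and 32 *corner*
settings (q and µ at their extremes, µ_i ≤ λ_i) used for the tree-size
analysis. The corner construction is ambiguous about which speciation pairs
it spans: over all five pairs it yields 48 settings, over
{(0.2, 1.8), (1, 1), (1.8, 0.2)} it yields exactly the published count of
32, so the three-pair version is the default and the five-pair variant sits
behind a flag.

## Reconstruction methods

**MPR (maximum parsimony).** Unit symmetric change cost, branch lengths
ignored. For each internal node we report the *set* of states the node takes
across all globally minimum-change labelings — 0, 1 or ambiguous — via two
sweeps: subtree cost vectors bottom-up, rest-of-tree cost vectors top-down;
a state is attainable iff the two sum to the global minimum. This per-node
set semantics (unlike single-pass Fitch final states) is validated against
exhaustive enumeration on all tree shapes up to 5 tips and sampled 7-tip
shapes.

**Mk2.** Two-state Markov chain on the fixed tree; likelihood by
Felsenstein pruning with the closed-form 2×2 transition matrix (no matrix
exponentials needed), per-node rescaling against underflow. Marginal
ancestral probabilities come from one extra outside pass (root-ward partial
likelihoods), equivalent to re-evaluating the likelihood with each node's
state fixed; equivalence with brute-force summation over all internal-state
assignments is tested to 1e-10 on ≤ 6-tip trees.

**BiSSE.** Along each branch the extinction probabilities E_i(t) and data
partial likelihoods D_i(t) are integrated (equations in the README) with an
embedded Cash–Karp Runge–Kutta 4(5) integrator, relative tolerance 1e-8,
absolute 1e-10 (halving the tolerances moves fixture log-likelihoods by
< 1e-6, and a single branch agrees with scipy's reference integrator to
1e-7). At internal nodes D_i ← λ_i D_i^L D_i^R with rescaling; at the root,
states combine with the root prior after optionally dividing by
λ_i (1 − E_i)² per state — survival conditioning, ON by default to match
the simulation protocol. Marginal reconstruction fixes a node's state by
zeroing the other state's D and re-propagates only the node's root-ward
path against cached subtree quantities; both fixings share one scale
factor stream, so their ratio is exact. Zero-length branches transport
E/D unchanged.

**Root prior.** Flat (½, ½) by default for both likelihood methods, in the
likelihood and in the marginal reconstruction; "observed" (weights
proportional to the root's conditional likelihoods) and "stationary"
(equilibrium of the transition subprocess) are selectable. The flat default
is the simplest defensible choice and, at study scales, reproduces the
published error levels; the switch preserves comparability if a different
convention is preferred.

**Fitting.** All rates are optimized on the log scale with Nelder–Mead
(function/parameter tolerances 1e-6, rates bounded to [1e-8, 1e3]), from
three random starts drawn as *truth × U(0.5, 1.5)* per parameter — the
protocol of a simulation study where the generating rates are known. For
empirical trees Mk2 defaults its start center to one expected change per
total tree length; BiSSE requires an explicit center. The returned optimum
is never worse than any start's initial point. A calibration worth knowing:
on 400-tip trees generated at q01 = q10 = 0.05 with root state 0, the
forward rate q01 is recovered within a factor of 2 about 95% of the time,
but q10 much less often (reversions are rare on root-state-dominated
trees), so joint factor-2 recovery happens in only ~55% of replicates. This is a
property of the data, not the optimizer: the fitted likelihood always
dominates the likelihood at the truth.

## Error metrics and aggregation

Raw score: 1 − p(true state) for probability methods; 0 / 0.5 / 1 for MP
correct / ambiguous / wrong. (Defined this way, a perfectly reconstructed
node scores 0; the alternative reading in which p(true) = 0.85 scores 0.15
*against* the truth is internally inconsistent and is not used.) Quantised
call: 1 if p₁ > 0.7, 0 if p₁ < 0.3, ambiguous between — boundary values are
ambiguous; an outright error is a non-ambiguous wrong call. Per tree,
internal nodes are ranked by age (ties by node id) and split into ten
equal-count groups, remainder to the deepest groups, root always in the
deepest; an equal-width age-bin alternative is available. Scenario summaries
average per-tree decile means across trees (each tree weighted equally);
pooled-node averaging is available behind a flag and differs when trees
contribute unequal node counts.

The regression table has one row per analysed tree per method with the
binary response "any outright error in the tree". Model 1 regresses on
µ0, µ1, q01, q10 and log(true transitions), each interacting with Method
(categorical, reference BiSSE when present); Model 2 adds λ0 as a
categorical main effect (its effect is not monotone in λ0) with the Method
interaction; λ1 is omitted as it is determined by λ0. Trees with zero
counted transitions would have undefined log(transitions) and are dropped
with a recorded count — with pruned-tree transition counting this set is
exactly the excluded invariant trees. Fitting is a binomial GLM with logit
link (statsmodels); perfect separation and constant responses raise
explicit errors suggesting more replication.

## Problem sizes

The default test suite and the acceptance script are scaled-down versions of
the full 720 × 500 × 3 design (which is cluster-scale and supported as
configuration): grid counts are exact at any scale; deep-node error rates
use 50 trees per scenario for the Mk2/MP arms and 2 per scenario (over all
20 high-rate scenarios) for the BiSSE arm; the bound checks use 8–9
scenarios × 10–20 trees; simulator statistics use 100/50 trees per corner
setting (100/400 tips), 4000 trees at the worst invariant setting and 60 per
expanding scenario. At these sizes the statistics reproduce the full-scale
values within a few percent (sampling error dominates; all averaging is
scenario-first, matching the full design).

## What the generator does and does not emulate

It emulates: state-dependent speciation/extinction/transition, root
constrained to the ancestral state, survival conditioning to a fixed tip
count, pruning of extinct lineages, and exclusion of invariant characters.
It does **not** emulate: time-varying or lineage-varying rates, hidden
states, more than two character states, incomplete/biased taxon sampling,
phylogenetic estimation error (the true tree is handed to the methods), or
fossil tips. Passing tests therefore speak to method behaviour when the
tree is known and rates are homogeneous — real-data error rates will
generally be worse, and the regressions quantify scenario effects, not
tree-uncertainty effects.

## Known limitations

* BiSSE marginal reconstruction costs O(depth) branch integrations per node
  (with cached subtrees); it is exact but the slowest component, so the
  scaled-down presets run the BiSSE arm at lower replication.
* One simulator statistic resists reproduction: at the setting λ0 = 1.8,
  λ1 = 0.2, µ = 0.01, q01 = 0.01, q10 = 0.1, the invariant-character
  fraction computes to ≈ 12% (validated against an independent analytic
  oracle: the probability of leaving no state-1 tips by time T satisfies a
  two-type Riccati ODE solvable with scipy, and matches the unconditioned
  simulator to Monte-Carlo error), versus a published figure of 16%. The
  corresponding check is reported honestly rather than adjusted.
* The experiment runner executes serially; parallelism would not change
  results (per-tree seeding) but is not implemented.
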