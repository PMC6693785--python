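# Methods

This note documents the models, estimation procedures, numerical choices
and known limitations of `cpmpaths`, in the spirit of the methods sections
of simulation-heavy scientific packages.

## Fitness landscapes

A landscape maps each genotype over K driver genes (bitmask; bit i = gene i
mutated) to a clonal birth rate; death rates are shared by all genotypes
(see below), so birth rate is fitness at any population size.

**Representable landscapes.** A random DAG of restrictions is drawn by
sampling a uniform random topological order of the genes and including each
forward gene→gene edge independently with probability `density` (default
0.3); genes left parentless depend only on the implicit Root.  Relations are
conjunctive (AND): a gene may mutate only when *all* its parents are
mutated.  This prior spans trees through dense posets with a single knob;
the exact in-degree distribution of the original study's generator is not
published, so `density` is exposed rather than guessed.  The fitness graph
contains every genotype compatible with the DAG, with edges between
genotypes differing by one added mutation.  Birth rates are assigned
iteratively: wild type 1; each descendant's rate is the maximum rate among
its fitness-graph parents times an independent U(1.01, 1.19) draw — a mean
multiplicative fitness increase of 0.1 per driver.  Incompatible genotypes
have rate exactly 0 and are never instantiated by the simulator.

**Local-maxima landscapes.** Before rate assignment, a random selection of
fitness-graph edges is removed under the constraint that every genotype
stays reachable from the wild type: edges are shuffled, removed one at a
time, and a removal is kept only if reachability survives, until a fraction
`removal_fraction` (default 0.5, not fixed by the source study) of the edges
has been processed.  The procedure is repeated 50 times per DAG and the
pruning with the most out-degree-0 nodes (candidate peaks) is kept.  Rates
are then assigned on the pruned graph, so a genotype can be fitter than a
one-mutation neighbor it can no longer be reached from.

**Rough Mount Fuji.** `log birth rate = −c·d(g, reference) + ε_g`, with d
the Hamming distance to a uniformly chosen reference genotype and ε_g iid
Normal(0, σ²).  The draw is repeated until the reference is the unique
global maximum, and rates are rescaled so the wild type has rate 1.  The
multiplicative (log-linear) form of the additive component is a documented
choice; `c = 0` gives a pure House of Cards landscape, `σ = 0` a smooth
single-peaked one.  Defaults `c = σ = 0.05` give rugged landscapes with
several peaks at K = 7.

**Local maxima and evolutionary traps.** For DAG-derived landscapes the
allowed uphill moves are exactly the fitness-graph edges, so local maxima
are the graph's sinks.  For RMF landscapes `landscape_stats` uses the
classic definition — no fitter genotype among all K single-bit neighbors —
while the simulator's stopping set is the *forward* version (no fitter
neighbor among mutation-adding moves), since back mutations cannot occur;
every Hamming local maximum is also a forward trap, but not conversely.
K ≤ 14 is enforced throughout (2^K genotype enumeration).

## Evolutionary simulation

The growth model is a multi-type continuous-time birth–death process with
logistic-like density dependence: a clone of genotype g divides at rate
b(g) and every cell dies at rate `D(N) = log(1 + N/Kc)`, with Kc chosen so
the wild-type population starts at demographic equilibrium
(`Kc = N0/(e−1)`, so `D(N0) = b(wild type) = 1`).  Population size at
equilibrium grows roughly logarithmically with accumulated drivers, which
is what makes log tumor size the natural axis for detection.  On each
division every unmutated gene mutates independently with its per-gene rate
(10⁻⁵ under the constant regime; iid log-uniform on [0.2, 5]·10⁻⁵ under the
variable regime, giving geometric mean 10⁻⁵, arithmetic mean 1.5·10⁻⁵ and a
maximal rate ratio of 25); simultaneous double mutations are ignored
(probability ~10⁻¹⁰) and offspring with birth rate 0 are discarded.

**Numerics.** The process is advanced by Poisson tau-leaping over clones
(default `tau = 0.25` in units of 1/wild-type birth rate; deaths are
clamped at clone size).  Whenever the population is monomorphic — the
common state while waiting for the next successful mutant — the simulator
draws the time to the next *viable* mutation from its exponential law and
jumps there directly, holding the clone at its quasi-stationary size.  This
leap is what makes thousands of runs per landscape affordable; it ignores
demographic drift during waiting periods, which affects neither the LOD
nor, materially, the snapshot sizes.  A run ends when a trap genotype holds
at least `theta = 0.99` of the population (the study's own fixation
criterion is not published; θ is configurable).  Extinction or exceeding
the time guard (10⁶ time units) restarts the run on a fresh substream, up
to 20 attempts.

**Lines of descent.** Every mutation event creates a clone that records its
parent clone, and the LOD is the ancestry of the most populated clone of
the fixated genotype at the final time.  This is the actual genealogy, not
the first-arrival approximation (tracing the first time each genotype
arose); the two can differ when a genotype arises repeatedly, e.g. under
clonal interference.

**Snapshots** are recorded at fixed intervals (default every 25 time units)
and whenever total population changes by ≥ 5% since the last snapshot — at
N₀ = 2000 the demographic noise is ~2%, so a tighter trigger would record
noise.  `batch_simulate` also reports whether every gene appeared in some
clone across runs; callers regenerate the landscape when it did not (the
benchmark does this automatically, up to 10 tries).

## Detection and data sets

For each trajectory a Beta deviate — B(1,1) uniform, B(5,3) large, B(3,5)
small — is rescaled to the [min, max] of log population sizes pooled across
all snapshots of the batch; the snapshot with log size closest to the
target (earlier snapshot on ties) contributes the genotype of its most
abundant clone.  Pooling across trajectories is the default reading of
"the log-transformed distribution of observed tumor sizes"; a
per-trajectory mode is available via `pooled=False`.  Genotypes are stacked
into a binary subjects × genes matrix (CSV: comma-separated, header row, no
row names; all-zero columns retained) and split into pairwise-disjoint
subsets per sample size by drawing without replacement from a fresh
permutation.  `top_features` keeps the most frequently mutated columns
(thresholds 7/10/12 in the reliability analyses), breaking frequency ties
by column order.

## Cancer progression models

**Oncogenetic tree.** Pairwise weights
`w(i→j) = log[ p_i/(p_i+p_j) · p_ij/(p_i p_j) ]` combine the relative
frequency of the putative parent with the observed association of the pair;
root attachment has weight `−log(1+p_j)`.  Marginals are clamped to
[0.5/n, 1−0.5/n] and joints below 0.25/n² are clamped up to that floor (so
never-co-occurring pairs signal repulsion rather than association);
degenerate columns are clamped and logged.  The maximum-weight branching is
found by Edmonds' arborescence algorithm (networkx); since the root has no
in-edges the branching is necessarily rooted there.  For path extraction
each edge carries the estimated conditional probability of the child event
given the parent, `p_ij/p_i`.

**Conjunctive Bayesian network.** Given a poset, feature j occurs at rate
λ_j once all its parents have occurred, the tumor is observed at an Exp(1)
time (the standard identifiability convention — λ are in units of the
observation rate), and each observed bit is flipped with probability ε.
The genotype distribution is exact: on the lattice of poset-compatible
genotypes with generator Q, the Green's function of the chain killed at
rate 1 is `G = (I − Q)⁻¹`; row 0 of G is the genotype distribution at
observation, and `G[0,s]·G[s,y]/G[0,y]` is the expected time spent in
state s conditional on ending in y.  EM uses these identities directly:
the E-step weights hidden true genotypes by `P(y)·ε^d(x,y)(1−ε)^(K−d)`,
the M-step sets ε to the expected flip fraction and λ_j to expected
firings over expected enabled time.  Each EM iteration provably does not
decrease the likelihood (asserted in the tests).  Structure search is
simulated annealing over add/delete/swap moves on edges with geometric
cooling (defaults: 4 restarts × 2000 proposals, T from 10 to 0.1, 2 warm-
started EM iterations per proposal, full EM polish of the best state); the
first restart starts from the empty poset — whose fully EM-polished fit
seeds the incumbent, so the returned log-likelihood never falls below the
empty-poset fit — and later restarts from sparse random posets.  Pure
maximum likelihood is the default, BIC available via `penalty="bic"`.
The reported poset is the transitive reduction (posets with equal closure
define identical models).  Degenerate columns are excluded from the search
and re-attached as isolated features with clamped rates (10⁻⁶ / 10⁶).
Parameter-recovery behavior: on data simulated from a 4-gene diamond poset
(λ = 1, ε = 0.05, n = 2000) the true poset is recovered in ≥ 80% of seeded
replicates, and rate ratios are recovered within 20% at n = 10⁴ (the
acceptance suite runs exactly these checks).

`ExternalCpmAdapter` wraps third-party CPM output (MCCBN, CAPRI, CAPRESE:
a DAG plus optional rates) for the path machinery; those tools themselves
are out of scope.

## Paths and their probabilities

The paths to the maximum of a poset/tree are its linear extensions
(equivalently the source-to-sink paths of its fitness graph), enumerated by
DFS with a configurable cap (default 10⁶) and a lazy iterator for dense
10-gene posets.  CBN fits are weighted by competing exponentials: at each
step the next feature among the available set A occurs with probability
`λ_j / Σ_{a∈A} λ_a`.  OT fits use edge weights normalized proportionally
among available features at each step (default); an alternative `product`
mode scores a path by the plain product of its edge weights, normalized at
the end — the choice matters because OT weights are occurrence
probabilities by observation time, not transition rates, and the
proportional reading is the package default.  CPMs that cannot produce
weights fall back to `uniform_path_distribution`.

## Performance statistics

JS is computed with base-2 logarithms (so it is scaled to [0, 1]);
entropies S_p and S_c use natural logarithms; exp(S) is the equivalent
number of equiprobable paths.  When LOD lengths differ from the CPM path
length K_C, LODs are grouped by terminal length k; within a group each LOD
path is prefix-matched against the CPM paths, the longer side's probability
is split into a matched fraction `min(k,K_C)/max(k,K_C)` and an unmatched
remainder (accumulated into a single entry, which leaves JS unchanged), and
group statistics are combined with weights w_k, the LOD frequency of
terminal length k.  The conditional LOD distribution within each group is
renormalized to sum to 1 before the per-group comparison; this reading is
consistent with the w_k weighting and reduces exactly to the plain
statistics when all lengths agree.  The alternative (raw within-group
flows) is implemented behind `renormalize=False` and exercised in the
tests.  A literal straight-line transcription of the procedure, with JS
delegated to scipy, lives in the test suite as the oracle for the
implementation.  The most-common-LOD statistic counts recovery if *any*
modal path (ties included) is prefix-matched by a CPM path.

## Reliability (JS_o,b)

Bootstrap replicates resample subjects with replacement at the original
sample size; the full fit (structure and parameters, including ε) is
repeated per replicate, and JS_o,b is the mean JS between the original
fit's path distribution and each replicate's.  Replicate seeds are split
deterministically from the caller's generator; fitter failures are logged,
skipped and counted.  When a feature threshold is used, the most-common
columns are selected once on the original data and the same columns are
used for every replicate.

## The benchmark and its scales

`enumerate_design("full")` reproduces the complete factorial design — 2
gene counts × 3 landscape kinds × 3 initial sizes × 2 mutation regimes ×
35 replicates = 1260 landscapes; × 3 detection regimes × 3 sample sizes ×
5 splits = 56700 data sets, 20000 runs per landscape — and
`run_benchmark` executes any design reproducibly from a master seed
(per-landscape derived streams, so execution order is irrelevant).  The
desk scale used as default (7 genes, N₀ = 2000, constant mutation rates, 5
replicates, 1000 runs, sample sizes 50/200/1000) keeps every pipeline stage
and factor semantics at workstation cost.  The acceptance tests run a
further-reduced version of the same pipeline — 3 landscapes per kind, 500
runs each, sample sizes 50 and 250, 2 splits, a 2-restart × 400-proposal
annealing schedule, and B = 25 for the bootstrap trend — sizes chosen so
the whole suite completes in minutes while leaving the directional effects
(JS falling with sample size on single-peaked landscapes,
probability-weighted beating uniform paths, RMF degrading performance and
inflating S_c/S_p, JS_o,b falling with n) comfortably outside Monte-Carlo
noise.

## What the synthetic data does and does not emulate

The generator reproduces the *shape* of real cross-sectional cancer data —
binary subjects × drivers matrices, skewed per-feature frequencies, small
n, detection-time biases — under a known ground truth, which is exactly
what evaluating CPM predictions requires.  It does not emulate copy-number
events, back mutations or genotype reversions, spatial or multi-sample
structure, inter-patient heterogeneity in the restriction structure,
passenger mutations, or feature-selection errors upstream of the matrix.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative behavior of CPMs under the modeled violations (multi-peakedness,
detection bias, sampling noise), not performance on any particular real
tumor type.

## Known limitations

* Tau-leaping with the monomorphic leap is an approximation to the exact
  process; establishment probabilities of borderline-neutral mutants are
  slightly distorted at the default `tau`.  Reduce `tau` for accuracy.
* The CBN search is stochastic; with small annealing budgets it can return
  a poset with the same transitive closure as, or close to, the maximum-
  likelihood one rather than the exact optimum.
* Exact lattice computations limit CBN fits to K ≤ 14 in principle and
  K ≲ 10 in practice (lattice size up to 2^K).
* OT and CBN are the two CPM families implemented; CAPRI and CAPRESE enter
  only through `ExternalCpmAdapter`.
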