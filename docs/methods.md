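# Methods

This note documents the models, algorithms and numerical choices behind
`emtlogic`, and what the synthetic-data tests do and do not establish.

## The logical model

A Boolean model is a set of named nodes; each non-input node carries a rule
over its regulators built from `!`, `&`, `|` with precedence NOT > AND > OR.
N-ary chains are canonicalised to left-folded binary trees, which fixes a
deterministic left-to-right index for every binary operator occurrence — the
coordinate system used by the robustness analysis. Inputs (`ECMicroenv`,
`DNAdamage`) have no rules: the dynamics holds them at their initial value,
and stable-state enumeration branches over every input combination.

Mutations are clamps: a gain-of-function clamp holds a node ON, a
loss-of-function clamp OFF, regardless of its rule. Clamped nodes never
flip. Pathway-level mutants clamp every member of the pathway module
(e.g. TGFb_pthw = {TGFbeta, SMAD}), which reproduces module-level
perturbation semantics on the detailed network without needing a separately
specified reduced model.

The rule file format (`NodeName = expr`, `input`, `alias`, `#` comments) is
documented by the bundled `metastasis_rules.txt`; a BoolNet-style
"targets, factors" export is provided for interoperability.

## Stable-state enumeration

Fixed points satisfy `x_i = f_i(x)` for every unclamped ruled node. The
solver is a determining-set method rather than a naive 2^n sweep or a
per-variable DFS:

1. Compute once a feedback vertex set (FVS) of the ruled-node regulatory
   graph (greedy removal of high-degree nodes in strongly connected
   components, then a minimisation pass; the bundled model needs 8 of 30
   nodes).
2. Lay out all assignments of inputs + FVS as rows of a bit matrix
   (2^10 = 1024 rows for the bundled model).
3. Fill in every other node by vectorised truth-table propagation in
   topological order.
4. Keep rows whose FVS nodes reproduce themselves under their rules.

Completeness follows because any fixed point, restricted to the determining
set, propagates back to exactly itself. The method is exact, and because the
FVS depends only on *which* nodes regulate which — not on the AND/OR
structure — it is computed once and shared by all operator-swap variants,
which is what makes the 8001-variant census run in seconds. The test suite
validates the solver against an independent exhaustive 2^n oracle on
hundreds of random models (up to 16 nodes), with and without clamps.

Output order is lexicographic in the node-order bit vector, so tables are
stable across runs.

## Stochastic simulation

The continuous-time Markov interpretation assigns each eligible flip (an
unclamped node whose rule disagrees with its value) a rate; all rates
default to 1 per time unit, as in the published analyses. Trajectories are
simulated by Gillespie's algorithm: exponential waiting time at the total
rate, flip chosen proportionally to rate; a trajectory ends on absorption in
a stable state or at the time horizon (`max_time`, default 100 time units —
far beyond the mixing time of the 32-node network at unit rates). Phenotype
probabilities are endpoint averages; `fraction_absorbed` flags conditions
where cyclic attractors or slow mixing leave trajectories unabsorbed, since
probabilities are asymptotic laws only when absorption is complete.

Randomness discipline: one master seed spawns an independent PCG64 stream
per trajectory (`SeedSequence(seed, spawn_key=(condition,))`), each
trajectory consuming two uniforms per step (waiting time, then choice). The
vectorised batch engine and the scalar reference engine therefore produce
bit-identical trajectories, estimates do not depend on how conditions are
batched, and raising `n_trajectories` extends rather than reshuffles the
sample. The default initial condition draws every node i.i.d. uniform;
named nodes can be pinned (mixed policies), and a "resting" policy starts
all non-input nodes OFF.

For models whose free-node state space fits in 2^12 states, an exact
absorption solver builds the embedded jump chain and solves the linear
system for the endpoint law; it raises on cyclic attractors. It serves as
the independent cross-check for the Monte-Carlo engine (agreement within 3
Monte-Carlo standard errors in the tests) and as an automatic fallback in
the screen for sufficiently small clamped models.

## The mutant screen

The default mutatable set is every node except the two inputs and the four
final/intermediate outputs (Apoptosis, Invasion, Migration, Metastasis) —
26 genes, giving 52 single and 1300 double mutants. All are simulated under
one shared configuration.

Screen study conditions: trajectories start from the resting state (all
non-input nodes OFF, environment inputs random) and endpoints are read at a
horizon of 20 time units. The horizon is part of the modelled experiment,
not a numerical shortcut: the model contains double mutants whose every
stable state is metastatic but which absorb an order of magnitude more
slowly than the Notch-driven synergies (p ≈ 0.9 at t = 20 versus exactly 1),
and the published screen's separation of "probability 1" mutants from the
rest implies a finite readout on this scale. With this design the screen
finds exactly four fully penetrant synergistic double mutants
(NICD⁺/p53⁻, NICD⁺/p73⁺, NICD⁺/SNAI2⁺, AKT2⁺/NICD⁺).

"Reaches probability 1" is operationalised as: estimated p ≥ 0.995 *and*
every stable state of the clamped model shows the phenotype (exact
confirmation). This turns a stochastic claim into a checkable one: a mutant
trapped by a cyclic attractor (e.g. AKT2⁺/SNAI1⁻, which holds ~half its
probability mass in a cycle) or one that has not converged by the horizon
does not qualify, however favourable its attractor structure.

Epistasis uses the multiplicative null on the no-metastasis event; records
with ε < −0.2 or ε > 0.3 (configurable) are exported to SIF/GraphML
networks with nodes sized by single-mutant probability and edges weighted by
|ε|. Gene pairs are classified into the five qualitative cancellation
patterns (any-GoF-cancels, any-LoF-cancels, double-GoF-cancels,
double-LoF-cancels, only-mixed-amplifies) using a "cancelled" tolerance of
p < 0.05; the published percentage shares of these clusters depend on
unprinted tolerances and are treated as a soft diagnostic only. The mutant
landscape embedding is an ordinary 2-component PCA of each mutant's
phenotype-combination distribution (combinations with mean prevalence
> 1% retained, wild type included), with deterministic sign convention;
non-linear manifold methods are out of scope.

## Robustness census

Variants differ from the wild type by one operator swap, two swaps in the
same rule, or one swap in each of two rules: 126 + 283 + 7592 = 8001 for
the bundled model's 126 operator sites. A swap flips the operator character
in the rule *as written* (minimal parentheses) and re-reads the rule under
standard precedence, so a flipped operator regroups its chain the way the
written expression dictates. This convention was chosen over flipping a
fixed site of the frozen binary tree because the two differ measurably on a
whole-census scale and the as-written convention reproduces the published
reproducibility percentages (59% of pooled stable-state occurrences
identical to a wild-type state, 13% at Hamming distance 1); the frozen-tree
alternative inflates the census by ~4%. Percentages are computed over
occurrences with multiplicity and rounded to integers. Census totals under
this implementation: 69 760 occurrences, 1182 distinct states, maximum
DIST_TO_WT 13 (attained by CTNNB1-rule variant pairs; single-rule CTNNB1
and NICD modifications reach 12).

The phenotype-probability sweep simulates any (sub)sample of variants under
a shared configuration and reports per-phenotype distributions; the
tolerance behind "minor or no effect" statements is exposed as a parameter,
not asserted.

## Expression matching (EBP)

Gene-to-node mapping is case-insensitive through a bundled table: most
nodes map to their own symbol; EGFR and MAPK1 proxy the GF and ERK nodes,
SMAD3/TGFB1 the SMAD/TGFbeta nodes, and the phenotype read-outs map through
biomarkers (CASP9, CDC42, MMP2). All of it is overridable.

Binarization defaults to an exact per-gene 1-D two-means split (threshold =
midpoint of the cluster means) applied after replicate averaging; a global
quantile method is available and makes the ranking invariant under strictly
monotone transforms. A gene whose range never exceeds `min_dynamic_range`
(default 1.0 log2 unit) is flagged always-ON/always-OFF against the global
threshold rather than errored. Constant genes still contribute their bit to
the score (full-vector comparison); a switch restricts scoring to the
dynamic genes.

The EBP score is the integer agreement count per (timepoint, stable state);
argmax sets are reported with ties preserved. Note that the two metastatic
stable states differ only in the DNA-damage input, which no expression gene
maps to, so they tie structurally.

## Synthetic data

The time-course generator produces log2-scale expression with additive
Gaussian noise (multiplicative on the raw scale): 11 dynamic genes follow
sigmoids (E-cadherin repressed; CDH2, VIM, ZEB1, SNAI2, MMP2, TGFB1, SMAD3,
EGFR, MAPK1, CTNNB1 induced) with midpoints at 12 or 18 h (slope 0.35/h,
amplitude 4 log2 units ≈ 16-fold, noise SD 0.3), so the 8-h sample sits
near the decision boundary; 13 constitutive genes are split so that half
match the apoptotic stable-state pattern and half the metastatic one,
leaving the argmax transition to the dynamic genes. Under the default
design the EBP argmax moves from the apoptotic states at 0/8 h to the
metastatic states at 24/72 h, emulating the qualitative trajectory of a
TGF-β induction experiment. What passing these tests shows is that the
pipeline recovers planted structure at realistic noise; it does not show
that real array data binarizes as cleanly, that probe-level artefacts are
handled, or that the 11-gene dynamic set generalises to other cell lines.

The cohort generator plants module-level shifts (in pooled-SD units) on top
of i.i.d. Gaussian gene backgrounds for 88 + 17 samples. It emulates group
structure and effect direction only — no gene-gene correlation within
modules beyond the shift, no batch effects, no heavy tails — so the
module-activity tests establish sign recovery and power under idealised
noise, not performance on real tumour cohorts. With a 1-SD planted effect,
Welch-test power exceeds 0.9 at 50 vs 50 samples; at the imbalanced 88 vs 17
design a single-gene module recovers the correct sign essentially always
but reaches significance in only ~90% of replicates, which is why the
corresponding tests aggregate over repeated cohorts.

Random Boolean models (≤ 16 nodes, 1–4 regulators, random negations and
connectives) are emitted through the package's own grammar and serve purely
as oracle fodder for the exact solvers.

## Numerical and design choices

- Exact integer/bit arithmetic everywhere in the logical core; no floating
  tie-breaks. Stable-state output order is lexicographic; screen and census
  orders are fixed by gene/site enumeration order.
- The two-means threshold uses an exact scan over split points
  (deterministic; no k-means initialisation noise).
- PCA sign conventions: module-activity scores are oriented by positive
  correlation with mean module expression; landscape axes by making the
  largest-|loading| coefficient positive.
- Welch's t-test is the default for differential activity (group sizes are
  imbalanced by design); pooled-variance is switchable.
- Degenerate inputs: empty clamp sets, single-replicate timepoints,
  constant genes, modules without measured genes and empty record sets all
  take defined, logged paths rather than raising.

## Known limitations

- The operator-swap convention is the package's reading of an
  under-specified procedure; census totals under other defensible
  conventions differ by a few percent (see above).
- Phenotype probabilities for non-degenerate conditions depend on the
  initial-condition policy and horizon; only the extreme outcomes (0 and 1)
  are policy-independent, and only those are asserted.
- No GINsim file parsing, no non-linear (elastic-map) embeddings, no
  heterogeneous per-node rates, and no cyclic-attractor *enumeration* —
  cycles are detected (via absorption failure or the exact solver) but not
  characterised.
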