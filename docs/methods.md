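# Methods

## Model and scope

The package learns discrete Bayesian networks: a DAG `G = (V, E)` over
categorical variables plus one conditional probability table (CPT) per node,
with joint density `P(x_1..x_n) = ∏_i P(x_i | pa_i)`. It targets gene
regulatory network reconstruction from discretized expression data, where the
central difficulty is the "large p, small n" regime: conditional-independence
tests with large conditioning sets (as in constraint-based skeleton learners)
need sample sizes exponential in the conditioning-set size, whereas the
neighbor selection used here relies only on *pairwise* mutual information.
Continuous networks, belief-propagation inference, and iterative candidate
re-estimation are out of scope.

## Neighbor selection (FPNS)

**Flooding.** For target `T`, the m = n−1 MI values to all other nodes are
sorted ascending (ties broken by node index). Under the no-breakpoint null all
values come from one Gaussian; under the alternative the vector splits at
position k into two Gaussians fitted by MLE. The statistic
`Q(k) = 2[logL(M_1..k) + logL(M_k+1..m) − logL(M_1..m)]` is evaluated at every
k in [1, m−1] and the related set `R_T` is everything right of the argmax.
Design choices:

- **No significance threshold.** Q is used only to locate the split; a
  breakpoint is always declared. This favors a deterministic, parameter-free
  phase but means that on a fully connected graph (no noise cluster at zero)
  the scan necessarily cuts at the largest MI gap — see Limitations.
- **Variance floor 1e-12.** Segment variances are floored so single-point and
  constant segments stay finite. The floor makes a run of exactly-zero MIs
  (d-separated or disconnected nodes under exact MI) an overwhelmingly
  preferred segment, which is what makes the zero/nonzero split exact in the
  oracle regime.
- **Ties in argmax go to the smallest k** (largest related set, favoring
  recall); the search range [1, m−1] keeps the related set non-empty, so leaf
  targets with a single true neighbor remain representable.
- Vectors with m < 3 raise: with so few nodes, callers should treat every
  node as related.

**Pruning.** Members of `R_T` are processed in descending-MI order (the data
processing inequality `MI(T;X_i) ≤ min(MI(T;X_a), MI(X_a;X_i))` can only hold
when the predecessor `X_a` has the larger MI to `T`, so the descending order
makes each test meaningful). The DPI Level of the first member is 1; each
later member's level is one more than the maximum level among preceding
members that satisfy the inequality (non-strict, as ties carry no information
either way), or 1 if none does. Pruning keeps members with level ≤ θ: with
strict `<` a depth of θ=1 would keep nothing, contradicting the intended
"keep only level-1 candidates" reading, so the inclusive rule is used.

**θ policy.** Fixed θ (1 = most specific, 3–4 balanced) or the per-node
"mode" rule: the most frequent level in `R_T` (ties to the smallest level),
floored at 2. The floor trades a little specificity for sensitivity on small
related sets where the mode is degenerate.

**Symmetrization.** Neighbor sets are made undirected for the search with a
union rule (pair allowed if either endpoint proposes it); an intersection
rule is available. Union is the default because a weak edge is often visible
from only one endpoint's MI vector, and recall of the mask upper-bounds
everything the search can recover.

All of FPNS is deterministic: no RNG, explicit tie-breaks everywhere.
Worst-case cost per target is O(|V|) for the scan over k on top of the
O(|V|^2) MI vector work and O(|V|^2) DPI triplet tests, i.e. O(|V|^4) overall
in the worst case; an empirical log-log slope check on random MI matrices
sits far below that bound.

## Mutual information

Plug-in (maximum-likelihood) estimation on integer-coded categories, natural
logarithms throughout. Zero cells contribute nothing; results are clamped at
a −1e-12 floor. Summation over cells happens in sorted order so the estimate
is bit-identical under argument exchange. No bias correction is applied by
default (a Miller–Madow term is available but off), because only the ordering
of MI values feeds the downstream phases. The exact-MI oracle marginalizes
the enumerated joint table (refused above 2^20 entries) and is the "MI
estimated with no errors" regime used in the identifiability tests.

## Structure search

BDeu with equivalent sample size 1 (likelihood-equivalent: Markov-equivalent
DAGs score identically, which the tests assert to 1e-9). Parent-configuration
counts q_i use the full cartesian product of parent cardinalities;
configurations with zero data counts contribute nothing beyond the prior
terms. Cardinalities are fixed per column before search so every parent set
sees the same r_i and q_i. Greedy hill climbing starts from the empty graph,
evaluates add/delete/reverse moves via local-score deltas, accepts the single
best move with delta > 1e-9, and breaks ties by first occurrence in
(operator, edge) lexicographic order — reproducibility over aesthetics. No
tabu list or restarts. `max_iter` exhaustion flags the result non-converged
instead of raising.

## Evaluation

Neighbor selection is scored over unordered node pairs after union
symmetrization (per-node counting would double-count every pair and make the
totals depend on the symmetrization direction). SHD compares completed PDAGs
— v-structure orientation plus Meek-rule closure, validated against
exhaustive equivalence-class enumeration — counting one unit per pair whose
adjacency, orientation status, or direction differs; USHD compares skeletons
only. The F-score defaults to skeleton mode (a directed mode exists) since
orientation inside an equivalence class is not identifiable from
observational data.

## Synthetic benchmarks

Generators provide: random recursive trees (each node takes one uniformly
chosen earlier parent — connected, collider-free, the setting where the
DPI-level guarantees are exact); the duplicate-path motifs (feed-forward,
feedback, parallel channel, duplicate parents) and the target-relation cases
(direct, indirect, collider, common cause); random sparse DAGs with capped
in-degree; and symmetric-Dirichlet CPTs whose concentration sets dependence
strength (0.25 default: strong but not deterministic edges; ties between
exact MIs then have probability zero). Variables default to 3 states
(under/normal/over-expressed). The feedback motif is cyclic by construction
and exists only for cycle-detection behavior, never for sampling. Benchmark
runs use 10 replicate datasets per sample size, sizes spanning 50–10,000, on
8-node trees — sizes chosen so the full claim suite enumerates exact joints
and exhaustive DAG/orientation oracles comfortably on one CPU.

What the fixtures do *not* emulate: ODE-driven expression kinetics,
measurement noise structure, feedback regulation, or realistic network
sizes. Passing tests demonstrate the algorithmic contracts and small-scale
statistical behavior, not field performance on real expression compendia.

## Known limitations

- **Forced breakpoint on connected graphs.** When every node is related to
  the target (e.g. an 8-node connected tree), the MI vector has no noise
  cluster, yet a breakpoint is still declared; the scan then cuts at the
  largest MI gap and weak true edges can fall below it from both endpoints'
  perspectives. On such desk-scale fixtures measured neighbor sensitivity
  plateaus around 0.86 even with exact MIs or 10,000 samples, and the
  restricted search can trail plain hill climbing, which already handles
  8-node spaces nearly optimally. The selection advantage is designed for
  networks large and sparse enough that most pairs are unrelated.
- The DPI Level inflates inside feed-forward/feedback neighborhoods (the
  motivation for θ > 1); siblings sharing two or more parents can survive
  even θ=1 pruning (reproduced by the duplicate-parents motif test).
- Plug-in MI is biased upward at small n; since only orderings matter the
  phases tolerate this, but very small samples blur the breakpoint.
- BIF support is a deliberately small dialect subset (discrete variables,
  table/parenthesized rows) intended for interchange of alarm-style
  networks, not a full parser.
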