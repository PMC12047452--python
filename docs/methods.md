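# Methods

## The ST code and its similarity

An ST code classifies one directed interaction of a signal-transduction
pathway at four levels: cellular location of the event (level 1, six
categories), action type (level 2, a location-dependent range — e.g.
twelve action types under "intracellular signal transduction events" but
a single catch-all under "cytoplasm to nucleoplasm"), entity-pair
characteristic (level 3) and serial number (level 4). Levels 1–2 form a
closed 39-row taxonomy shipped as a TSV inside the package
(`stpath/data/st_categories.tsv`) so it can be audited or overridden;
levels 3–4 are open-ended positive integers with no enumerated
vocabulary, and the toolkit treats them as opaque.

Code similarity is the length of the common prefix of the two
four-level vectors, scaled by 0.25:

    σ(α, β) = 0.25 · |common prefix|  ∈ {0, 0.25, 0.5, 0.75, 1}.

σ is symmetric, equals 1 iff the codes are identical, and drops to 0 as
soon as the location categories differ — two events in different cell
compartments are considered wholly dissimilar regardless of action type.

## Pathway alignment

Pathways are compared through their ST-code sequences alone; entity
names play no role in scoring. The raw score is the maximum of Σσ over
*monotone matchings* — sets of index pairs strictly increasing on both
sides — with gaps free of charge. This is computed by the dynamic
programming recurrence

    H[i][j] = max(H[i−1][j−1] + σ(aᵢ, bⱼ), H[i−1][j], H[i][j−1]),

with zero boundary. Because σ ≥ 0 and gaps cost nothing, H is monotone
non-decreasing along rows and columns, so the global value H[L1][L2]
equals the Smith–Waterman-style local maximum — the local/global
distinction is vacuous in this scoring scheme, and the toolkit
implements the global recurrence. The normalized similarity divides by
the longer length, f = raw / max(L1, L2), so f ∈ [0, 1] with f = 1
exactly when the code sequences are identical.

Traceback ties are resolved diagonal-first, then query-advance, then
subject-advance, so the reported matching (not just the score) is
deterministic. An exhaustive enumerator over all monotone matchings
(`brute_force_score`, feasible to length 8) serves as an independent
oracle in the tests; the DP agrees with it exactly on hundreds of random
pairs.

Collection ranking sorts alignment results by similarity descending
with ties broken by subject id, giving a reproducible "high to low"
results list.

## Network construction

Selected pathways merge into one directed network with an edge per
distinct (source, target, ST code) triple; parallel edges between the
same node pair with different codes stay distinct, each annotated with
its level-1 category digit (the class used for edge coloring in
visual front-ends) and the ids of the pathways supporting it.

Edge weighting is a genuinely open design point: the ranking algorithm
below needs weights, but nothing in the encoding prescribes them. The
default scheme, `multiplicity`, weighs each edge by the number of
distinct pathways containing that interaction, so interactions recurring
across many pathways exert proportionally more influence on the
ranking; `unit` assigns weight 1 throughout and reproduces an
unweighted analysis. Supplying the same pathway id twice never inflates
a weight. Both schemes are exposed in the API and CLI.

Export formats are GraphML (via networkx) and a node-link JSON document;
both carry st_code, weight, category and category_label per edge and
round-trip back to an equal network.

## Key-factor ranking

Nodes are scored by a damped PageRank-style importance NR. Parallel
ST-coded edges are first collapsed to per-node-pair weights w_ij (the
weight of the edge from node j to node i). The iteration

    R ← d · M · R + (1 − d)/n,   R₀ = (1/n, …, 1/n)

runs until ‖R′ − R‖ < ε in the configured norm (L1 default; L∞
available) or a 10 000-iteration cap. Defaults d = 0.85 and ε = 1e-8.
NR values are reported exactly as the fixed point of this recurrence —
not rescaled to sum to one — and ranked descending with ties broken by
node id.

Two transition-matrix normalizations are provided because the
weight-aware formulation admits both readings and they are *not*
equivalent:

- `in_weights` (default): m_ij = w_ij / Σ_k w_ik, the sum over the
  in-neighbors k of node i — each node's incoming weights are normalized
  among themselves. Rows of in-degree-0 nodes are zero, so source nodes
  sit exactly at the teleport floor (1 − d)/n; no dangling correction is
  needed, and the rank total is not conserved.
- `out_weights`: the standard column-stochastic weighted PageRank,
  m_ij = w_ij / out-weight(j), with out-degree-0 nodes redistributing
  their rank uniformly; here Σ NR = 1 at the fixed point, and the
  result matches networkx's weighted `pagerank` (an independent
  cross-check in the test suite).

With d < 1 the iteration map is a contraction in both modes, so the
fixed point is unique and independent of the starting vector; the tests
verify this by iterating from random starts. On a directed cycle with
uniform weights the fixed point is exactly 1/n per node. No eigen-solver
shortcut is used — the iteration loop is the algorithm, and its
iteration count and final residual are reported with every result.

## Synthetic data generator

The generator emulates the shape of a curated pathway database at desk
scale: an interaction catalog of random distinct ordered entity pairs
(defaults: 30 entities, 90 interactions) with taxonomy-valid codes, and
pathway sets drawn as random walks over the catalog's directed relation
(default 20 pathways of 3–8 steps, restarting at a random edge on
dead-ends so requested lengths are always met). Level-3/4 values are
sampled in 1..5 so that codes differing only at level 4 — the 0.75
similarity branch — occur at useful frequency. Every generator is a pure
function of its configuration; the same seed yields byte-identical TSV
output.

What it deliberately does not emulate: real entity nomenclature,
the topology of any curated disease pathway collection, or empirical
code-frequency distributions. Passing tests therefore demonstrate
algorithmic correctness and statistical behaviour under a controlled
model, not biological conclusions about any particular pathway set.

### Perturbation model

`perturb_pathway` mutates each step's code independently, top-down by
level: level k changes with probability p_k into a different valid
value, and once some level has changed all deeper levels are resampled
uniformly over their valid ranges (keeping the code
taxonomy-consistent). A level with a single-valued range — e.g. the
action type under location category 5 — cannot change, and the model
accounts for that.

The probability that the first k levels all survive is Π r_m with
r_m = 1 − p_m (or 1 where no alternative exists), so the expected
per-position similarity has the closed form

    E[σ] = 0.25 · (r1 + r1·r2 + r1·r2·r3 + r1·r2·r3·r4),

averaged over the pathway's actual codes
(`expected_position_similarity`). This closed form models the
*position-wise* similarity; the DP alignment similarity is bounded below
by it, since realignment can only add score. At the moderate rates used
in the statistical tests (0.2 per level) the realignment gain is
statistically negligible and the DP mean agrees with the closed form
within Monte-Carlo error; at aggressive rates (e.g. certain level-1
change) the positional similarity drops to 0 while the aligner can
still harvest incidental off-diagonal matches — the tests distinguish
the two statistics accordingly.

## Numerical and interface choices

- Similarity values are multiples of 0.25 and the DP adds at most
  min(L1, L2) of them, so scores are exact in double precision; DP/oracle
  agreement is asserted with `==`, not a tolerance.
- Entities are case-sensitive opaque strings; no identifier
  normalization is attempted, avoiding silent collisions.
- Pathways whose consecutive steps do not chain (target ≠ next source)
  load with a warning, not an error — branching upstream topologies are
  legal.
- Code-string queries get synthetic endpoint names (`query_n0`, …) so
  they can participate in network construction; mixing them with
  named-entity pathways warns.
- CLI exit codes: 0 success, 1 domain error (validation, unresolvable
  entities, empty inputs), 2 I/O or usage error. All randomness flows
  through explicit seeds; repeated invocations are byte-identical.
- Problem sizes in the test suite (catalogs ≤ 2000 interactions,
  networks ≤ 500 nodes, 200–500 Monte-Carlo replicates) are chosen so
  the full suite completes in seconds while still exercising every
  convergence and statistical property.

## Known limitations

- The alignment has no affine gap model, no multiple (>2) pathway
  alignment, and no significance statistics; scores are descriptive.
- The `in_weights` normalization follows the weight-aware rank
  formulation literally; whether a deployed system would instead use
  the standard out-weight form is application-dependent, which is why
  both are first-class options rather than one being "the" default
  semantics.
- Level-3/4 semantics are opaque to the toolkit; codes are inputs, and
  no attempt is made to assign them from reaction descriptions.
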