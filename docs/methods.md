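# Methods

## Model

The aligner treats two undirected, confidence-weighted PPI networks G₁ and
G₂ plus a cross-network similarity table as a single weighted graph and asks
for pairs of subgraphs (one per network) that are simultaneously cohesive
within their network and mutually conserved across it. Three ingredients
carry the method.

**Markov-chain node correspondence.** All n = n₁ + n₂ nodes become states of
one Markov chain. The raw transition mass between two nodes of the same
network is their interaction confidence w ∈ [0, 1]; between networks it is
`cross_weight × similarity` (similarity ≥ 0, e.g. −log BLAST e-value). Each
row is divided by its sum; rows with no mass (isolated, un-crosslinked nodes)
are flagged dangling. Damped power iteration

    p ← α·pT + (α·(p·q) + 1 − α)·u/n,  then p ← p/‖p‖₁

(q the dangling indicator, u the all-ones vector) converges to a stationary
distribution; the teleport term enters with a positive sign, as required for
the iterate to remain a probability distribution. A cross-linked pair's
global score multiplies each node's stationary mass by the *share* of its
cross-network mass pointing at the partner, sums both directions, and scales
by n, so an exclusive reciprocal pair at uniform p scores exactly 2. In the
second share term the row index is the network-2 node — the only indexing
consistent with its row-sum denominator. Scores are mapped into [0, 1] by
log_b(1 + S) with b = ⌈1 + max S⌉, floored at 2 so the base stays valid when
all scores are below 1.

**Graph entropy.** For a member set C, each node's inner-link probability
p_i(v) is the weighted fraction of its edges entering C; the network's
entropy is the sum of binary entropies h(p_i(v)) over *all* nodes. Isolated
nodes contribute 0 (no neighbours, no information). A seed's initial cluster
is seed + neighbours, then each original neighbour is visited once in
decreasing weighted-degree order (ties lexicographic) and removed iff the
entropy strictly drops. Removing r only perturbs h(p_i) at r's neighbours, so
the implementation evaluates exactly that neighbourhood sum; the test suite
asserts this equals the full recomputation to 1e−9. Strictness uses an
absolute guard of 1e−12 so float noise in symmetric configurations cannot
masquerade as a decrease.

**Match/gap local score and expansion.** Against a partner cluster, an edge
is a *match* when some pair of aligned partners ("aligned" = any positive
cross-link-derived score, no threshold) is adjacent in the partner cluster,
and a *gap* when, failing that, partners are joined through exactly one
intermediate member aligned to nothing in the first cluster; longer detours
confer nothing, and an edge qualifying both ways counts once as a match.
S_intra averages matched weight (gaps discounted by β) over the cluster's
edge count — edgeless clusters score 0 — and S_inter averages each node's
best normalised global score into the partner; S_local mixes them with γ.
Expansion alternates passes over the two clusters: the outer boundary is
enumerated per pass in descending unweighted degree (ties lexicographic) and
a node is accepted iff it strictly raises that cluster's own directional
score; both directional scores are refreshed after any acceptance and the
loop stops when a full pass accepts nothing. Per-candidate scores are
evaluated from scratch rather than incrementally: clusters stay small (tens
of nodes), and the from-scratch evaluation is by construction identical to
the score definition the tests oracle-check.

A seed pair is skipped only when *both* endpoints already belong to emitted
clusters. Emitted pairs need ≥ 2 members per side and both directional
scores ≥ 0.02; the floor suppresses large, weakly-supported clusters.

## Parameters

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 1.0 | seed threshold on raw S_global; higher → fewer, cleaner clusters. 0.1 suits sparsely cross-linked pairs with few known orthologs |
| β (`beta`) | 1.0 | gap discount in S_intra; accuracy is insensitive to it |
| γ (`gamma`) | 0.25 | weight of S_inter vs S_intra |
| α (`alpha`) | 0.85 | damping factor; the standard random-surfer convention, configurable because upstream global aligners do not all agree |
| `cross_weight` | 1.0 | multiplier taking sequence scores into the transition matrix |
| `tol`, `max_iter` | 1e−10, 1000 | L1 convergence of power iteration from a uniform start |
| `min_size`, `discard` | 2, 0.02 | output filters |

## Synthetic generator

`SyntheticSpec`/`generate_pair` plant `n_modules` dense modules
(`p_in = 0.9`, weights U(0.6, 1.0)) in network 1 over a sparse background
(20 extra nodes, `p_bg = 0.05`, weights U(0.05, 0.4)); network 2 carries
relabelled module copies with 10 % per-edge dropout plus its own background.
Counterpart nodes are cross-linked at a jittered high score (level 50, always
strictly above the spurious level) and spurious cross-links are added at half
the counterpart count (level ≤ 2). Module edge sets are redrawn (logged) in
the rare event the realised density fails to beat the background. All
randomness comes from the spec's single seed.

The generator emulates the density contrast and orthology signal of real
conserved complexes, not realistic interactome topology: no scale-free degree
distribution, no correlated false-negative interactions, no paralog
families beyond the optional many-to-many cross-links. Passing recovery
tests therefore demonstrates algorithmic correctness on planted structure,
not expected accuracy on genome-scale data, where precision is dominated by
catalog incompleteness and network noise.

## Numerical and design notes

- Duplicate edges or cross-link lines keep the maximum score (conservative
  confidence merge); weights outside [0, 1] are an error, not clamped.
- All orderings that affect output (seed queue, removal order, boundary
  enumeration, serialisation) carry lexicographic tie-breaks, making runs
  byte-reproducible.
- Conserved-edge counts are directional (counted from C1's edges); the
  evaluation report exposes both directions. One edge conserved by several
  partner edges counts once per distinct partner edge, and functional
  consistency requires semantic similarity strictly above 0.2 at both
  endpoints.
- Overlap filtering keeps, among clusters with pairwise Jaccard > 0.4, the
  largest (greedy by descending size, ties lexicographic); the filter is
  idempotent.
- Degenerate inputs: an isolated seed yields a singleton cluster that the
  size filter removes; an empty seed list returns an empty alignment with a
  warning; an empty score map cannot be normalised and raises.

## Verification problem sizes

Oracle checks run on random instances of ≤ 50 nodes (20 instances for the
stationary distribution against a dense power-method oracle, ≥ 100 triples
for entropy locality, ≥ 1000 draws for score bounds); recovery checks use
the generator defaults (3 modules × 6 nodes over 20 seeds, and a
noise-free variant with complete cliques, zero dropout and no background for
the exact-identity case). These sizes make the whole suite run in seconds
while exercising every code path at genome-relevant density contrasts.

## Known limitations

- Single-threaded; seed pairs are processed sequentially even though cluster
  formation per seed is independent.
- Exactly two networks; no multi-network alignment.
- Greedy expansion admits one node at a time, so two mutually dependent
  missing members (each scoring poorly without the other) can remain
  stranded; many-to-many cross-links mitigate this in practice.
- The global stage's score normalisation depends on the realised maximum, so
  S_norm values are comparable within one run, not across runs.
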