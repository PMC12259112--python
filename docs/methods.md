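# Methods

## Data model

The input is a directed weighted graph G(V, E, w): neurons, synaptic
connections, synapse counts. Edge tables may list one row per connection
or per synapse; duplicate (source, target) rows are summed at load, so
e(A, B) — the total weight from node set A to node set B — is always a
weighted sum over distinct ordered pairs. Zero-weight rows are dropped
and negative weights rejected. Self-loops are allowed and count toward
both the out and in coordinate of their node. Node identifiers are
opaque strings kept in first-appearance order; every deterministic
tie-break in the package (nearest-seed ties, argmax/argmin ties,
median-distance ties) resolves by this order, which makes every solver
output a pure function of its inputs. Labeled nodes absent from the
graph are retained as isolated nodes with a warning by default; a strict
mode rejects them.

## Embeddings and distance

Given a k-partition, the degree-count embedding of u is
f(u) = [e(u,C₁)…e(u,C_k), e(C₁,u)…e(C_k,u)]. The first k coordinates
sum to u's out-strength and the last k to its in-strength regardless of
the partition (a conservation property asserted in tests). Embeddings
are computed as two sparse matrix products (adjacency × cluster
indicator), so a full embedding pass is O(m + nk).

Weighted Jaccard distance D_J(a,b) = 1 − Σmin/Σmax is a true metric on
non-negative vectors, bounded in [0,1], and scale-sensitive — a neuron
with twice the synapse budget of another is *not* at distance zero from
it, which is deliberate: synapse counts carry signal. The indeterminate
case D_J(0,0) is defined as 0: two isolated neurons have
indistinguishable (empty) connectivity. Pairwise distances use the
identity Σmax = Σa + Σb − Σmin and are evaluated in row blocks sized to
bound the broadcast intermediate; the blocked path agrees with the
scalar formula to better than 1e-12 and is compared against a naive
double loop in the acceptance suite.

Cluster centroids are coordinate-wise medians by default (even
cardinality: midpoint of the central order statistics). The true Jaccard
median — the minimizer of summed Jaccard distances — is NP-hard; the
coordinate-wise median is the standard practical surrogate and keeps the
key equivalence below. Coordinate-wise means are available but weaken
that equivalence (guaranteed only for odd cluster sizes).

## Exact equitable partitions

A partition is equitable when all members of every cluster have
identical embeddings. The coarsest equitable partition is unique and is
computed by iterative refinement from the trivial partition (split
clusters by exact embedding equality until stable; at most n rounds).
Comparison is exact equality: input weights that are integers stay
exactly representable through the sparse summations, so refinement is
not affected by floating-point drift. For non-integral weights the
comparison is still bitwise on deterministically-ordered sums; users
with noisy real-valued weights should expect (correctly) a near-discrete
partition and use the approximate solver instead.

The Jaccard cost of a partition, cost(𝒫) = Σᵢ Σ_{v∈Cᵢ} D_J(f(v), Mᵢ),
is zero iff the partition is equitable (median centroids) — asserted on
every test fixture. The average cost (divided by n) is reported for
comparability across graph sizes.

## Seeded solver

Algorithm: initialize every non-seed to one arbitrary label (the first
of the sorted label universe — the choice is arbitrary in principle and
exposed only as a hidden knob for sensitivity checks), then repeat up to
`iterations` times: embed with the current labeling; reassign each
non-seed to the label of its Jaccard-nearest seed; stop early when no
label changes. Seeds never move. Default `iterations` = 15; on the
synthetic benchmarks convergence typically occurs in 3–7 sweeps.

The ranked variant sorts each node's distances to all seeds (stable in
seed node order), keeps the first occurrence of each label, and truncates
to k_top entries, so per-row distances are non-decreasing and the rank-1
label of a non-seed equals the solver's assignment.

Known limitation: the cold start can reach a poor fixed point or a short
limit cycle on graphs where intermediate labelings make distinct types
temporarily indistinguishable — more likely the smaller the graph, the
fewer the seeds, and the more symmetric the wiring. The noise-free
planted benchmark with one seed per type recovers all labels in ≥ 9 of
10 draws; occasional failures of this kind are expected and tolerated in
the acceptance thresholds rather than patched with restarts, keeping the
procedure deterministic.

## Unseeded solver

Grows seeds s₁..s_k one per cluster. Initialization: the trivial
partition; s₁ is the node whose 2-dimensional embedding [out-strength,
in-strength] is Jaccard-closest to the coordinate-wise median of all
embeddings. Each step: (1) score every candidate v by
score(v) = Σ_u max(0, D_J(f(u), M_{ℓ(u)}) − D_J(f(u), f(v))) — the cost
reduction contributed by the nodes that are closer to v than to their
current cluster median, holding medians fixed; the sum runs over all
nodes including v itself and current seeds; (2) add the argmax as a new
seed and re-run the seeded solver with each seed carrying a unique
singleton label (capped at R = 12 iterations); (3) recompute every
cluster's seed as its best representative — the member closest to its
cluster median. The seed set is rebuilt from scratch each step, so a
previous seed can be displaced by a better representative. We note the
score is written here in cost-reduction orientation (larger = more cost
removed) so the argmax reads naturally; an equivalent sign-flipped
rendering with argmin appears in the literature.

Costs are recorded per step, and because adding a cluster can *increase*
cost, the solver returns both the final k-cluster partition and the
minimum-cost intermediate partition (`return_best`, default on). The
best-partition cost equals the minimum over the recorded trace exactly.

The optional speed parameter T ∈ (0,1] restricts seed candidates to the
⌈T·n⌉ nodes farthest from their cluster medians, gathered round-robin
across clusters (farthest of each cluster first, then second-farthest,
…). On the planted benchmark, T = 0.1 changes mean matched accuracy by
less than 0.05 relative to T = 1.

Degenerate inputs worth knowing about: on graphs with an exact symmetry
that makes entire blocks equivalent under the score (all scores tie),
the deterministic node-order tie-break can select a second seed inside
an already-seeded block and the greedy growth then cannot reach the
planted optimum — the minimal 8-node two-block fixture in the test suite
is exactly such a case, and it is certified by exhaustive bipartition
enumeration to have a unique zero-cost 2-partition that the heuristic
misses. Generic (asymmetric) wiring removes the ties; this is a
worst-case property of greedy seed growth, not of the cost model.

## Evaluation protocol

Unsupervised output has arbitrary cluster labels, so clusters are first
matched to ground-truth types by maximum-weight bipartite matching on
overlap counts |A∩B| (scipy's Hungarian solver; equal to brute-force
enumeration over injections in tests). Matched accuracy = matched
overlap / n; when the prediction has fewer clusters than the truth has
types, unmatched types are simply never predicted, and surplus predicted
clusters contribute zero. Accuracy, top-k accuracy (hit if the true
label is among the k closest unique labels), adjusted Rand index and
support-weighted F1 (scikit-learn) complete the report. Seeded-mode
accuracy excludes the seed nodes by default — they are inputs, not
predictions — with a flag to include them; both conventions are exposed
because published curves rarely state which they use.

## Synthetic benchmark generator

The generator plants a k-block partition: block sizes n₁..n_k and a
non-negative integer matrix D where every block-i node sends total
weight D[i][j] to block j. The constraint nᵢ·D[i][j] ≡ 0 (mod nⱼ)
guarantees every block-j node also *receives* a constant total
nᵢ·D[i][j]/nⱼ, making the planted partition exactly equitable (cost 0)
before noise. Wiring is circulant by default — node r of block i targets
nodes (r·D[i][j] + t) mod nⱼ, t < D[i][j], which tiles targets exactly
and needs no randomness — with a seeded random-wiring mode that shuffles
target assignment under the same exact totals. A spec is *generic* when
the k concatenated out/in block profiles are pairwise distinct, i.e. the
types are distinguishable from connectivity in principle; the random
spec generator (equal block sizes, entries 1–6 at density 0.6) resamples
until generic.

Noise: each edge is independently rewired to a uniformly random target
with probability `noise_p` (preserves edge count and out-strengths,
breaks equitability — emulating biological variability and
reconstruction errors), and/or weights are jittered by a log-normal
factor (preserves topology). Both are deterministic given the seed.

What the benchmark does *not* emulate: heavy-tailed degree and type-size
distributions, spatial structure, reciprocity patterns, and annotation
biases of real connectomes. Passing the planted benchmarks shows the
solvers recover structure their cost model can represent, under
controlled noise, at desk scale (n = 200–300, k = 5–6, chosen so the
whole suite runs in seconds); it does not certify accuracy levels on
real reconstructions.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `SeededConfig.iterations` | 15 | max embed/assign sweeps |
| `SeededConfig.early_stop` | on | stop at a fixpoint |
| `UnseededConfig.R` | 12 | seeded sweeps per subproblem |
| `UnseededConfig.T` | 1.0 | candidate-pool fraction |
| `UnseededConfig.return_best` | on | also return min-cost partition |
| `UnseededConfig.centroid_method` | median | cluster centroid rule |
| `PlantedSpec.edge_weight` | 1 | synapse-count multiplier |
| `PlantedSpec.noise_p` | 0.0 | edge rewiring probability |
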