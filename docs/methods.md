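# Methods

## Model and procedure

`motifcensus` implements exhaustive network-motif detection on loop-free
simple directed graphs. Reciprocal arc pairs `(u,v),(v,u)` are legal and
model one bidirectional edge; self-loops and parallel arcs are not
representable (loops in input edge lists are dropped with a warning,
duplicates deduplicated). All subgraph counting is of *induced* subgraphs on
weakly connected vertex subsets, and distinct copies may overlap.

The detection pipeline is the standard four-step scheme: census of the input
network, generation of a degree-matched random ensemble of size `M`, census
of each ensemble member restricted to the classes seen in the input, and
per-class statistics (frequency, concentration, ensemble mean/sd, Z-score,
empirical p-value). The p-value is the pure ensemble proportion
`#{i : N_i ≥ f}/M`; an `(r+1)/(M+1)` variant is available behind a flag.
The Z-score uses the sample (`M−1`) standard deviation and is reported as
undefined (`NA`) whenever the ensemble counts are constant — at `k = 5, 6`
the number of isomorphism classes is so large that all-zero ensemble count
vectors are routine, and ±∞ would be noise. No normality is implied by the
Z-score and no multiple-testing correction is applied; the verbose count
matrix exists precisely so users can run their own diagnostics.

## Canonical labeling

A `k`-node digraph with an ordered vertex set is encoded as its graphID: the
`k×k` adjacency matrix read row-major as a binary number, MSB = entry (1,1).
The canonical ID of an isomorphism class is the minimum graphID over all
`k!` relabelings. This is the convention of the classic motif literature
(feed-forward loop = 38, complete triad = 238); it was validated by checking
the full set of published 3-node class IDs {6, 12, 14, 36, 38, 46, 74, 78,
98, 102, 110, 238}.

For `k ≤ 5` a pretreatment pass computes the canonical ID of every loop-free
`k`-node digraph. Tables are indexed by the `k(k−1)` off-diagonal bits only
(the packing is monotone, so orbit minima are preserved), giving 64 / 4096 /
2^20 entries for `k` = 3/4/5. The build is an orbit fixpoint: each adjacent
vertex transposition induces a permutation of the packed index space, and
sweeps of `canon[x] ← min(canon[x], canon[t(x)])` over the `k−1` generators
converge to the orbit minimum (generators are involutions, so the relation
is symmetric; orbits have at most `k!` elements and the sweep count is small
in practice). Vectorized over the whole index space with NumPy, the `k = 5`
table builds in roughly a second and is cached to a versioned `.npy` file
under the user cache directory (`MOTIFCENSUS_CACHE` overrides; `--no-cache`
forces a rebuild). Correctness is pinned by two independent re-derivations:
a pure-Python minimum over all `k!` relabelings, and a vectorized exhaustive
minimum (`canonical_ids_exhaustive`) that shares no code path with the
fixpoint build.

## Deck-based classification at k = 6

A full 6-node table (2^30 entries) is out of reach, so 6-node subgraphs are
keyed by their *deck*: the sorted multiset of canonical IDs of the six
vertex-deleted 5-node cards, computed by bit extraction plus six lookups in
the `k = 5` table. Equal decks almost always mean isomorphic graphs, but not
always — an exhaustive survey shipped as `scripts/verify_deck_theorem.py`
enumerates all 1,540,944 isomorphism classes of loop-free 6-node digraphs
(the 1,530,843 weakly connected ones by one-vertex growth from the 9,364
connected 5-node classes; the 10,101 disconnected ones by block-diagonal
composition of smaller connected classes) and lists the deck collisions:
there are exactly nine colliding pairs, and they are frozen into the test
suite, where each is checked to share a deck, fail isomorphism, and be kept
apart by the classifier. Because collisions exist, the classifier never
trusts the deck alone: the
subgraph list is bucketed by a 64-bit FNV-1a hash of the deck, and within a
bucket a candidate must match the stored deck *and* pass an explicit
isomorphism test against the stored representative. Classification is
therefore exact regardless of the collision list; a collision costs one
extra comparison. The stored representative is the first subgraph of its
class encountered in the input network, kept verbatim (it is generally not
in canonical form), and only classes present in the input network are
tracked — comparison-graph subgraphs of unseen classes are ignored.

## Subgraph enumeration

Connected `k`-subsets are enumerated by the rooted level-composition scheme:
for each root (ascending), candidate vertices are gathered level by level
from the undirected neighborhoods of the previous level, restricted to
labels greater than the root; all candidates of a level are marked visited
before its subsets are explored and unmarked afterwards. Each connected
subset is produced exactly once, rooted at its minimum label, with a
deterministic emission order (level sizes ascending, combinations
lexicographic). The "revolving door" combination ordering used by some
implementations is deliberately not reproduced; only exactly-once
enumeration is contractual, and the census is invariant to enumeration
order.

## Null models

All methods preserve every vertex's in- and out-degree exactly. The
switching methods run a single Markov chain started at the input network; a
proposal picks two arcs `u→v, x→y` and replaces them with `u→y, x→v` unless
a loop or parallel arc would arise. Method-specific handling of reciprocal
(bidirectional) edges:

* `nr` — proposals over all arcs, no further constraint;
* `gc` — proposals over all arcs; those changing the *global* reciprocal
  pair count are rejected;
* `f` — only non-reciprocal arcs are proposed, and proposals creating a new
  reciprocal pair are rejected, so the reciprocal pair *set* is frozen;
* `lc` — two sub-pools chosen with probability proportional to their number
  of unordered proposal pairs: non-reciprocal arcs switch as in `f`, and
  reciprocal pairs switch as undirected edges (`{u,v},{x,y} →
  {u,x},{v,y}` or `{u,y},{v,x}`, rejected on loops or any pre-existing arc),
  so every vertex's reciprocal degree is conserved.

Each ensemble member is the chain state after `ceil(switches_per_arc · m)`
further proposals (default `switches_per_arc = 3`, a widespread convention;
exposed as a flag). `burnin = b` discards the first `b` outputs so the
ensemble does not start at the input network itself. Proposal randomness for
chain segment `j` comes from a stream seeded by `(seed, j)`, which makes
comparison graph `i` reproducible from `(seed, i)` by deterministic replay —
the property behind the thread-count-invariant reports. Switching samples
degree-matched graphs non-uniformly; that is inherent to the method.

`ulc` is exactly uniform over the `lc` constraint set. It is a
configuration-model variant with three stub types per vertex (pure-out,
pure-in, reciprocal): pure-out stubs are matched to pure-in stubs by a
random bijection and reciprocal stubs by a random perfect matching, and the
whole draw is rejected if any loop, repeated arc, accidental reciprocal pair
among single arcs, or single/bidirectional overlap appears. Every simple
realization corresponds to the same number of stub matchings (a product of
per-vertex stub factorials and global matching factors independent of the
realization), so accepted draws are uniform. Acceptance degrades quickly
with density; after 200,000 rejections the sampler raises an explicit error
recommending a switching method. The directed 3-cycle profile (two
realizations at 0.5 each) and a chi-square test over a brute-force
enumerated realization set calibrate the sampler in the test suite.

## Parallelism and determinism

The input-network census runs in serial. Comparison-graph censuses are
independent tasks — one graph per task — dispatched to a thread pool of
user-chosen size, with results collected by index. Comparison graphs are
generated before dispatch from the per-segment seeded streams, so the report
is byte-identical for any thread count at a fixed seed. In CPython the pool
buys modest wall-clock gains (the census is pure Python), but the
scheduling contract — bounded workers, index-keyed results, no shared
mutable state — is the load-bearing part and is what the tests pin down.

## Synthetic data

The fixture generator produces the three network kinds the tests run on:
complete digraphs (`K_n`, whose census has the closed form `C(n,k)` copies
of a single class — `K_50` at `k = 3` gives 19,600 copies of class 238);
seeded Erdős–Rényi-style digraphs (each ordered pair an arc independently
with probability `density`); and motif-implanted networks, which append
`copies` fresh vertex triples wired internally as a chosen 3-node class
(each tied to the background by one outgoing arc, which cannot perturb the
triple's induced subgraph), so the implanted class count is at least
`copies`. Oracle-equivalence testing uses random digraphs with `n ≤ 12` and
densities 0.1–0.5, which keeps the `C(n,k)·k!` brute-force cost inside a
test budget while covering sparse-to-dense regimes; ULC calibration uses
sparser graphs (density ≈ 0.2) because wholesale rejection is the price of
exact uniformity. What these fixtures do not emulate: real regulatory
networks' heavy-tailed degree distributions, hub structure, and sparsity at
scale — passing tests demonstrate correctness of counting and sampling, not
biological claims.

## Numerical and edge-case choices

* `p < α` is strict; the motif call also requires `f ≥ min_frequency`.
* σ̂ = 0 → Z undefined (`NA`), never ±∞.
* Report rows sort by descending frequency, ties by ascending class ID.
* Graphs with fewer than two arcs cannot switch; ensembles then consist of
  copies of the input and every p-value is 1 (also the `switches_per_arc=0`
  debug mode, used as a fixture in the tests).
* `k` outside 3–6 is a usage error; the enumeration utilities additionally
  support undirected classes to 7 nodes and directed classes to 6.
* Exit codes: 0 success, 1 bad input/usage, 2 internal error.

## Known limitations

Single-machine, in-memory; no colored or weighted graphs; no subgraph
sampling (complete enumeration only); switching-chain mixing is not
diagnosed (choose `burnin` and `switches_per_arc` conservatively for
strongly constrained networks — the directed 3-cycle is an extreme case
whose chain cannot move at all); ULC can be infeasibly slow on dense or
reciprocal-heavy networks.
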