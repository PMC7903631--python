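# Methods

This note records the modelling and numerical choices behind ontorec, what
the synthetic data does and does not emulate, and the known limitations.

## Semantic similarity

**Graph.** Ontologies are read from OBO 1.2/1.4 flat files (via obonet).
Only `is_a` edges are traversed by default; other relationship types (e.g.
ChEBI's `has_role`) can be enabled through an allow-list but are excluded
from the tested contract because mixing relation semantics changes what
"common ancestor" means. Obsolete terms are dropped at parse time. Secondary
accessions (`alt_id`) resolve to their primary term by default; a strict
mode treats them as unknown, reproducing the behaviour of similarity engines
indexed on primary ids only — useful when diagnosing why a known-relevant
item fails to appear in recommendations.

**Information content.** The intrinsic formulation
IC(t) = −log₂((desc(t)+1)/N), where desc(t) counts strict descendants and N
is the ontology size. A term's probability is thus the fraction of the
ontology it subsumes: the root gets IC 0, leaves get log₂N. Base 2 is fixed
and documented because Resnik values enter the mean-fusion hybrid
unnormalized, so their magnitude matters downstream. An annotation-frequency
(extrinsic) IC would need a corpus, which the input format does not carry;
the extrinsic option on ``compute_ic`` accepts per-term annotation counts
(Laplace-smoothed, normalized by the root's mass) when such a corpus is
available, but with the intrinsic default the similarity layer is a pure
function of the ontology.

**Shared IC.** The most-informative-common-ancestor (MICA) convention: the
maximum IC over the intersection of ancestor-or-self sets. Terms in disjoint
components share IC 0. A disjunctive-common-ancestor variant
(``shared="dca"``) averages the IC of common ancestors with distinct
path-count differences, softening MICA's winner-takes-all behaviour under
multiple inheritance; MICA remains the default and the tested contract, and
the two coincide on trees. The Jiang–Conrath distance d is mapped to a
similarity by 1/(1+d), which is 1 exactly at d = 0 and stays in (0,1];
other mappings (linear rescaling, exp(−d)) would change absolute scores but
not the ordering of candidates, which is what the recommender consumes.

**Numerical notes.** All three measures are exact compositions of a max and
a handful of float operations; symmetry holds exactly (not to tolerance)
because both orders evaluate the same expression. The brute-force oracle in
the test suite recomputes ancestor sets by naive recursion and IC by
counting, independent of the production path, and agrees to 1e-12.

## The similarity store

All U(U+1)/2 unordered pairs (self-pairs included, so every lookup a
downstream scorer can make is defined) are computed once and persisted in a
single-file sqlite database — an embedded replacement for a client–server
SQL store that removes the service dependency. Pairs are canonicalized
lexicographically, so symmetric lookups hit the same row. Parallel builds
partition the deterministic pair enumeration into fixed chunks (default
10,000 pairs); each pair's floating-point path is worker-independent and
rows are inserted in enumeration order, so stores built with 1, 2 or 8
workers are record-identical. Missing pairs raise rather than returning 0 —
a similarity of zero is meaningful (disjoint branches) and must not be
conflated with absence.

## Collaborative filtering

**ALS** follows the confidence-weighted implicit formulation: preference
p = 1[r>0], confidence c = 1+α·r, alternating exact ridge solves. Defaults
α = 40, λ = 0.01, f = 150 factors, 15 sweeps; α and λ are not derivable
from the input data and follow the values customary in the implicit-ALS
literature; f = 150 suits a tens-of-thousands-item catalogue and should be
lowered for small universes (the built-in study uses f = 16 on a 72-item
universe — 150 factors there would be badly over-parameterized). The exact
objective (computed densely) is non-increasing across sweeps; this is
verified by direct evaluation, not assumed.

**BPR** maximizes Σ ln σ(x̂_ui − x̂_uj) − λ‖Θ‖² by SGD over uniformly
sampled (user, positive, negative) triplets, one interaction's worth of
samples per epoch. Defaults lr = 0.01, λ = 1e-4, 100 epochs. Users whose
positives cover the whole universe cannot supply a negative and are excluded
with a warning. Factors initialize uniform(0, 1/√f) from the seed; identical
seeds give bit-identical models.

**Scoring policy.** Items never observed in training cannot be scored by
CF. The default policy drops them (the honest statement of CF's cold-start
limitation); a `zero` policy keeps them at score 0 so the hybrid's content
side can still rank them. A BPR score shift of +1 is available as a flag
because some implementations offset ranking scores this way; it changes
nothing for BPR-alone rankings but moves mean-fusion hybrids, so it is off
by default.

## ONTO and fusion

ONTO sorts a candidate's similarities to the user profile descending (ties
broken by ascending item id, so the n-cutoff is deterministic), keeps
min(n, profile size), and averages. n = 5 by default: small n scores by
local neighbourhood and is sharper; large n flattens toward the profile
mean. n is the main sensitivity knob and {1, 5, 10, 15, 20, 25, 30, all}
are supported.

Metric1 (product) is invariant to rescaling either side, so an unbounded
Resnik S_CB cannot drown the CF signal. Metric2 (mean) is range-sensitive:
with Resnik scores of several bits against CF scores below 1, the mean is
dominated by the semantic side. Both behaviours are exposed deliberately
rather than normalized away; an optional min-max normalization exists but
the default reproduces the raw-fusion behaviour, with the asymmetry captured
as a property test. Items scored by only one module are dropped by default
(`cb_only_fallback` keeps CB-only items at their CB score).

## Evaluation protocol

Users and items are independently shuffled (seeded) into q = 5 blocks; fold
f tests user-block f against item-block f. Test ratings are those of test
users on test items; everything else trains. Each test user's candidate
universe is *all* test items, rated or not; relevance is binary (any
positive count) because an implicit count of 5 does not make an item more
relevant than a count of 1. Users with no relevant test item are excluded
from that fold's averages. Metrics are macro-averaged: mean over users
within fold, then over folds. The paired user-block/item-block reading (as
opposed to crossing every user block with every item block) keeps each
rating in exactly one test set. k starts at 1 (precision@0 is undefined).

## Synthetic data

The generator emulates the *structure* of a literature-derived
compound-ratings dataset: a single-root `is_a` DAG grown by attaching each
term to 1–2 earlier terms (biased toward recent terms, so depth develops);
every user rating ≥ 20 items; ratings as small counts (capped at 5 — the
cap is irrelevant under binarization and kept for realism); power-law item
popularity (many items with a single rater). The ontology–preference link
is a per-user anchor subtree: with concentration 0.9, 90% of a user's items
come from one semantic neighbourhood, which is the signal ONTO exploits;
concentration 0 severs the link and is the negative control under which
ONTO must not beat random ranking (and, by test, does not).

What it does **not** emulate: real ChEBI's scale (hundreds of thousands of
terms, 10+ levels, multiple inheritance everywhere), annotation sparsity
patterns of real authorship data, or correlated user communities. Passing
tests on this generator therefore demonstrate contract correctness and the
*direction* of the hybrid effect under a strong content signal, not absolute
metric values on any real dataset.

A second generator produces rank-1 preference data (shared latent item
quality, per-user noise in the top-n selection) as the ground truth for
ranking-recovery checks: BPR reaches held-out pairwise AUC above 0.8 on it,
and ALS recovers the item ordering on a fully observed noiseless instance.

**Study sizing.** The built-in study runs 36 users × 72 items over 150
terms with f = 16 and 10 ALS sweeps — the smallest shape at which the
5-fold user×item split leaves every fold with test users, test items, and
usable train profiles, chosen so the full study iterates in seconds.

## Known limitations

- Extrinsic IC takes a ready-made term→count mapping; there is no bundled
  corpus reader to produce one.
- The similarity store materializes all pairs up front: fine to ~10⁴ items
  (~10⁸ pairs is already a large build), beyond which on-demand computation
  with memoization would be the right trade.
- BPR's Python-loop SGD is deterministic and fast at desk scale but not
  tuned for millions of interactions.
- The similarity store always persists the MICA-based measures; the DCA
  variant is available on the function layer only.
- Absolute hybrid scores are not comparable across measures (Resnik vs Lin)
  or across CF learners; only within-run rankings are.
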