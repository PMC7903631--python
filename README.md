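# ontorec

A hybrid semantic recommender for items annotated in an ontology — built for
the scenario where the items are chemical compounds in a ChEBI-like `is_a`
DAG and the "ratings" are implicit counts (e.g., how many articles a
researcher wrote about a compound). Given such a ratings table, the package
answers: *which items should be put in front of this user next, and why?*

It is a library first: import it from Python, or drive the same pipeline
through the thin `ontorec` command-line tool.

## The model

Two scoring modules are fused per candidate item:

**Content-based (ONTO).** Term similarity is grounded in information
content, IC(t) = −log₂((desc(t)+1)/N) in bits, with three classic measures
over the most informative common ancestor (MICA):

- Resnik: sim(a,b) = IC(MICA) — unbounded above;
- Lin: 2·IC(MICA) / (IC(a)+IC(b)) ∈ [0,1];
- Jiang–Conrath: distance d = IC(a)+IC(b)−2·IC(MICA), similarity 1/(1+d) ∈ (0,1].

A candidate item *t* is scored against a user's rated items i₁…i_m as the
mean of the n highest similarities:

    S_CB(t) = (Sim(t, i₁) + … + Sim(t, i_n)) / n,  n = 5 by default.

Because S_CB needs no rating of the candidate itself, new items with zero
ratings anywhere remain recommendable (no item cold start). All pairwise
similarities are precomputed once — in parallel — into a sqlite store so
scoring is a lookup.

**Collaborative filtering.** Implicit-feedback ALS (confidence
c = 1 + α·r, binary preference, alternating ridge solves) and BPR
(pairwise SGD on (user, observed, unobserved) triplets), implemented in
numpy and deterministic under a seed.

**Fusion.** Per item, Metric1 = S_CF·S_CB (product, scale-invariant per
side) or Metric2 = (S_CF+S_CB)/2 (mean, range-sensitive). Ranked lists are
evaluated under 5-fold user×item cross-validation with binary relevance:
precision@k, recall@k, F-measure, MRR, and nDCG for k = 1…20.

## Worked example

`examples/05_hybrid_evaluation.py` generates the package's synthetic study
conditions (36 users × 72 items over a 150-term ontology; every user rates
≥ 20 items; 90% of each user's items come from one subtree) and compares
three algorithms:

```
36 users x 71 items, 876 ratings

ALS
  k= 1  precision 0.471  recall 0.109  mrr 0.471  ndcg 0.471
  k=10  precision 0.358  recall 0.774  mrr 0.672  ndcg 0.644
ONTO_LIN
  k= 1  precision 0.554  recall 0.122  mrr 0.554  ndcg 0.554
  k=10  precision 0.378  recall 0.802  mrr 0.708  ndcg 0.653
ALS_ONTO_LIN_m2
  k= 1  precision 0.643  recall 0.150  mrr 0.643  ndcg 0.643
  k=10  precision 0.380  recall 0.815  mrr 0.779  ndcg 0.698
```

Reading it: at k=1, ALS alone puts a relevant item first for 47% of test
users; averaging in the Lin-based semantic score lifts that to 64%, and
nDCG@10 rises from 0.64 to 0.70 — the semantic side pulls ontologically
coherent unseen items up the list. The other examples (`examples/01`–`04`)
walk through each layer separately.

The same pipeline from the shell:

```bash
ontorec synth --n-terms 150 --n-users 36 --n-items 72 --seed 1 \
        --out-obo onto.obo --out-ratings ratings.csv
ontorec simcache build --obo onto.obo --items ratings.csv --out sims.db --workers 4
ontorec run --algorithm ALS_ONTO_LIN_m2 --ratings ratings.csv --store sims.db \
        --outdir out --f 16 --seed 1
```

## Layout

- `src/ontorec/ontology.py` — OBO parsing (via obonet), IC, the three measures
- `src/ontorec/simstore.py` — parallel pairwise precomputation, sqlite store
- `src/ontorec/cf.py` — ratings container, implicit ALS, BPR
- `src/ontorec/onto.py` — the ONTO content-based scorer
- `src/ontorec/hybrid.py` — score fusion and deterministic ranking
- `src/ontorec/evaluation.py` — fold splitting and the top@k metric suite
- `src/ontorec/synthetic.py` — ontology/ratings generators and toy fixtures
- `src/ontorec/benchmarks.py` — the built-in synthetic study
- `src/ontorec/workflow.py`, `src/ontorec/cli.py` — orchestration and CLI

See `docs/methods.md` for modelling decisions, parameter meanings, and
limitations.
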