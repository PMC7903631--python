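"""Fit ALS and BPR on implicit count data and score candidates for a user.

Generates rank-1 preference data (a shared latent item ordering), fits both
learners, and prints the top-5 recommendations for one user from each.
"""

from ontorec import fit_als, fit_bpr, rank_items, score_items_cf
from ontorec.synthetic import gen_rank1_preferences

data, quality = gen_rank1_preferences(n_users=20, n_items=30, n_pos=10, seed=5)
user = data.users[0]
print(f"{data.n_users} users x {data.n_items} items, "
      f"{data.matrix.nnz} implicit ratings; scoring for {user}")

als = fit_als(data, f=8, alpha=40.0, lam=0.01, iterations=10, seed=0)
bpr = fit_bpr(data, f=8, lr=0.05, epochs=30, seed=0)

for name, model in [("ALS", als), ("BPR", bpr)]:
    scores = score_items_cf(model, user, data.items)
    top = rank_items(scores).ranking[:5]
    rated = set(data.items_of_user(user))
    print(f"\n{name} top-5 (* = already rated by {user}):")
    for item, s in top:
        print(f"  {item}{' *' if item in rated else '  '}  score {s:.4f}")

# Both learners put the user's own high-count items and the globally
# high-quality items first; BPR optimizes pairwise ranking rather than
# squared error, so its raw scores live on a different scale.
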