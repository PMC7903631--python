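"""Parse a small ontology and compare terms with the three IC-based measures.

Builds the bundled 5-term toy DAG (root R; branches A, B; leaves C, D under
A), computes intrinsic information content, and prints Resnik, Lin and
Jiang-Conrath similarities for a few pairs.
"""

from ontorec import compute_ic, sim_jc, sim_lin, sim_resnik
from ontorec.synthetic import fixture_toy

graph, _ = fixture_toy()
ic = compute_ic(graph)

print("information content (bits):")
for term in sorted(graph.terms):
    print(f"  {term}: {ic[term]:.4f}")

pairs = [("T:C", "T:D"), ("T:C", "T:B"), ("T:C", "T:C"), ("T:C9", "T:D")]
print("\npair            resnik     lin      jc")
for a, b in pairs:
    print(
        f"{a:>5} vs {b:<5} {sim_resnik(graph, ic, a, b):8.4f}"
        f" {sim_lin(graph, ic, a, b):8.4f} {sim_jc(graph, ic, a, b):8.4f}"
    )

# C and D are sibling leaves under A: their shared information is IC(A)
# (Resnik), a third of their summed IC (Lin ~0.32), and a JC distance of
# ~3.17 bits (similarity ~0.24).  C vs B share only the root, so Resnik is 0.
# T:C9 is a secondary accession of T:C and resolves to the same scores.
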