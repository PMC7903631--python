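"""Ontology parsing, information content, and the three similarity measures."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontorec import (
    CycleError,
    OntologyError,
    UnknownTermError,
    compute_ic,
    parse_obo,
    shared_ic,
    sim_jc,
    sim_lin,
    sim_resnik,
)
from ontorec.ontology import SIM_FUNCTIONS

from conftest import brute_ic, brute_similarities, random_dag

CHAIN = """format-version: 1.2
ontology: chain

[Term]
id: T1
name: one

[Term]
id: T2
name: two
alt_id: A9
is_a: T1

[Term]
id: T3
name: three
is_a: T2
"""


class TestParseObo:
    def test_minimal_chain(self):
        g = parse_obo(CHAIN)
        assert g.n_terms == 3
        assert sorted(g.edges) == [("T2", "T1"), ("T3", "T2")]
        assert g.roots() == ["T1"]

    def test_alt_id_registered(self):
        g = parse_obo(CHAIN)
        assert g.alt_id_map == {"A9": "T2"}

    def test_cycle_rejected(self):
        doc = CHAIN + "\n[Term]\nid: T4\nis_a: T5\n\n[Term]\nid: T5\nis_a: T4\n"
        with pytest.raises(CycleError):
            parse_obo(doc)

    def test_duplicate_primary_id_rejected(self):
        doc = CHAIN + "\n[Term]\nid: T1\nname: again\n"
        with pytest.raises(OntologyError, match="duplicate"):
            parse_obo(doc)

    def test_obsolete_terms_dropped(self):
        doc = CHAIN + "\n[Term]\nid: T9\nname: gone\nis_obsolete: true\n"
        assert "T9" not in parse_obo(doc).terms

    def test_diamond_ancestors(self):
        doc = """format-version: 1.2
ontology: diamond

[Term]
id: A

[Term]
id: B
is_a: A

[Term]
id: C
is_a: A

[Term]
id: D
is_a: B
is_a: C
"""
        g = parse_obo(doc)
        assert g.ancestors_or_self("D") == {"D", "B", "C", "A"}
        assert g.ancestors_or_self("A") == {"A"}


class TestResolveId:
    def test_primary_is_identity(self):
        g = parse_obo(CHAIN)
        assert g.resolve_id("T2") == "T2"

    def test_secondary_resolves_to_primary(self):
        g = parse_obo(CHAIN)
        assert g.resolve_id("A9") == "T2"

    def test_strict_mode_rejects_secondary(self):
        # a similarity engine indexed on primary ids only cannot score a
        # query made with a superseded accession
        g = parse_obo(CHAIN)
        with pytest.raises(UnknownTermError):
            g.resolve_id("A9", strict=True)

    def test_unknown_id(self):
        g = parse_obo(CHAIN)
        with pytest.raises(UnknownTermError):
            g.resolve_id("NOPE")


class TestInformationContent:
    def test_root_has_zero_ic(self, toy):
        graph, ic, _ = toy
        assert ic["T:R"] == pytest.approx(0.0)

    def test_leaf_ic_is_log2_n(self, toy):
        graph, ic, _ = toy
        assert ic["T:C"] == pytest.approx(math.log2(5), abs=1e-12)

    def test_inner_node_ic(self, toy):
        graph, ic, _ = toy
        assert ic["T:A"] == pytest.approx(-math.log2(3 / 5), abs=1e-12)

    def test_nonincreasing_along_child_parent_paths(self, toy):
        graph, ic, _ = toy
        for child, parent in graph.edges:
            assert ic[parent] <= ic[child] + 1e-12

    def test_extrinsic_ic_from_annotation_counts(self, toy):
        import math

        graph, _, _ = toy
        # counts: C=3, D=1 -> mass(A)=4, mass(R)=4, total=5
        ic = compute_ic(graph, annotations={"T:C": 3, "T:D": 1})
        assert ic["T:R"] == pytest.approx(0.0)
        assert ic["T:A"] == pytest.approx(-math.log2(5 / 5))
        assert ic["T:C"] == pytest.approx(-math.log2(4 / 5))
        assert ic["T:B"] == pytest.approx(-math.log2(1 / 5))

    def test_extrinsic_ic_unknown_term_rejected(self, toy):
        graph, _, _ = toy
        with pytest.raises(UnknownTermError):
            compute_ic(graph, annotations={"T:NOPE": 1})


class TestSimilarityExamples:
    """Frozen values derived from the brute-force ancestor oracle on the toy DAG."""

    def test_shared_ic_cd(self, toy):
        graph, ic, _ = toy
        assert shared_ic(graph, ic, "T:C", "T:D") == pytest.approx(
            -math.log2(3 / 5), abs=1e-12
        )

    def test_shared_ic_across_branches_is_zero(self, toy):
        graph, ic, _ = toy
        assert shared_ic(graph, ic, "T:C", "T:B") == 0.0

    def test_shared_ic_self(self, toy):
        graph, ic, _ = toy
        assert shared_ic(graph, ic, "T:C", "T:C") == ic["T:C"]

    def test_resnik(self, toy):
        graph, ic, _ = toy
        assert sim_resnik(graph, ic, "T:C", "T:D") == pytest.approx(0.7369655941662062)
        assert sim_resnik(graph, ic, "T:C", "T:B") == 0.0
        assert sim_resnik(graph, ic, "T:C", "T:C") == pytest.approx(math.log2(5))

    def test_lin(self, toy):
        graph, ic, _ = toy
        assert sim_lin(graph, ic, "T:C", "T:C") == 1.0
        assert sim_lin(graph, ic, "T:C", "T:D") == pytest.approx(0.31739380551401475)
        assert sim_lin(graph, ic, "T:R", "T:B") == 0.0

    def test_jc(self, toy):
        graph, ic, _ = toy
        assert sim_jc(graph, ic, "T:C", "T:C") == 1.0
        assert sim_jc(graph, ic, "T:C", "T:D") == pytest.approx(0.23981246656813146)
        assert sim_jc(graph, ic, "T:C", "T:B") == pytest.approx(
            1.0 / (1.0 + 2 * math.log2(5))
        )

    def test_similarity_via_alt_id(self, toy):
        graph, ic, _ = toy
        assert sim_lin(graph, ic, "T:C9", "T:D") == sim_lin(graph, ic, "T:C", "T:D")


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
def test_measures_match_brute_force_oracle(seed, n):
    """All three measures agree with full ancestor-set enumeration on random DAGs."""
    g = random_dag(n, seed)
    ic = compute_ic(g)
    bic = brute_ic(g)
    assert ic == pytest.approx(bic, abs=1e-12)
    terms = sorted(g.terms)
    rng_pairs = [(terms[i], terms[j]) for i in range(0, n, 3) for j in range(i, n, 5)]
    for a, b in rng_pairs:
        br, bl, bj = brute_similarities(g, a, b)
        assert sim_resnik(g, ic, a, b) == pytest.approx(br, abs=1e-12)
        assert sim_lin(g, ic, a, b) == pytest.approx(bl, abs=1e-12)
        assert sim_jc(g, ic, a, b) == pytest.approx(bj, abs=1e-12)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_symmetry_ranges_and_self_maximality(seed):
    g = random_dag(25, seed)
    ic = compute_ic(g)
    terms = sorted(g.terms)
    for a in terms[::4]:
        for b in terms[::3]:
            for name, fn in SIM_FUNCTIONS.items():
                v = fn(g, ic, a, b)
                assert v == fn(g, ic, b, a)  # exact symmetry
                assert v >= 0.0
                if name in ("lin", "jc"):
                    assert v <= 1.0
            assert sim_resnik(g, ic, a, a) >= sim_resnik(g, ic, a, b)
        if ic[a] > 0:
            assert sim_lin(g, ic, a, a) == 1.0
        assert sim_jc(g, ic, a, a) == 1.0


class TestDisjunctiveSharedIC:
    """The DCA variant equals MICA on trees and averages extra disjunctive

    ancestors under multiple inheritance."""

    def test_coincides_with_mica_on_a_tree(self, toy):
        from ontorec import shared_ic, shared_ic_dca

        graph, ic, _ = toy
        for a in graph.terms:
            for b in graph.terms:
                assert shared_ic_dca(graph, ic, a, b) == shared_ic(graph, ic, a, b)

    def test_diamond_averages_in_the_second_ancestor(self):
        from ontorec import shared_ic, shared_ic_dca

        doc = """format-version: 1.2
ontology: dca

[Term]
id: A

[Term]
id: B
is_a: A

[Term]
id: C
is_a: A

[Term]
id: D1
is_a: B
is_a: C

[Term]
id: D2
is_a: B
"""
        g = parse_obo(doc)
        ic = compute_ic(g)
        # common ancestors of D1, D2 are {B, A}; D1 reaches A twice, D2 once,
        # so A is disjunctive and its IC is averaged in
        mica = shared_ic(g, ic, "D1", "D2")
        dca = shared_ic_dca(g, ic, "D1", "D2")
        assert mica == ic["B"]
        assert dca == pytest.approx((ic["B"] + ic["A"]) / 2)
        assert dca < mica

    def test_self_shared_ic_is_own_ic(self, toy):
        from ontorec import shared_ic_dca

        graph, ic, _ = toy
        assert shared_ic_dca(graph, ic, "T:C", "T:C") == ic["T:C"]

    def test_measures_accept_the_flag(self, toy):
        graph, ic, _ = toy
        assert sim_lin(graph, ic, "T:C", "T:D", shared="dca") == sim_lin(
            graph, ic, "T:C", "T:D"
        )
        with pytest.raises(ValueError):
            sim_lin(graph, ic, "T:C", "T:D", shared="bogus")


def test_structural_twins_equal_similarity():
    """Two leaves with identical parent sets and descendant counts are

    indistinguishable to every measure against any third term."""
    doc = """format-version: 1.2
ontology: twins

[Term]
id: X:ROOT

[Term]
id: X:MID
is_a: X:ROOT

[Term]
id: X:OTHER
is_a: X:ROOT

[Term]
id: X:L1
is_a: X:MID

[Term]
id: X:L2
is_a: X:MID
"""
    g = parse_obo(doc)
    ic = compute_ic(g)
    for third in g.terms:
        if third in ("X:L1", "X:L2"):
            continue
        for fn in SIM_FUNCTIONS.values():
            assert fn(g, ic, "X:L1", third) == fn(g, ic, "X:L2", third)
    # and the twins are each other's nearest non-self neighbours symmetrically
    for fn in SIM_FUNCTIONS.values():
        assert fn(g, ic, "X:L1", "X:L2") == fn(g, ic, "X:L2", "X:L1")
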