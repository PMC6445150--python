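import itertools

import pytest

from funact.ontology import (
    DrugCase,
    OntologyDAG,
    OntologyError,
    expand_positives,
    infer_negatives,
    load_dag,
    zero_similarity,
)
from funact.synthetic import SimConfig, generate_dag

from oracles import brute_force_negatives

BP = "biological_process"


def chain_dag():
    # root <- a <- b
    return OntologyDAG(
        {"root": set(), "a": {"root"}, "b": {"a"}},
        {t: BP for t in ("root", "a", "b")},
    )


def star_dag():
    """root with two disjoint subtrees (x under u; y under v) plus sibling s."""
    parents = {
        "root": set(),
        "u": {"root"},
        "v": {"root"},
        "s": {"root"},
        "x1": {"u"},
        "x2": {"u"},
        "x3": {"u"},
        "y1": {"v"},
        "y2": {"v"},
    }
    return OntologyDAG(parents, {t: BP for t in parents})


class TestDag:
    def test_chain_ancestors(self):
        dag = chain_dag()
        assert dag.ancestors("b") == {"b", "a", "root"}
        assert dag.roots == {BP: "root"}

    def test_cycle_detected(self):
        with pytest.raises(OntologyError):
            OntologyDAG(
                {"a": {"b"}, "b": {"a"}, "root": set(), },
                {"a": BP, "b": BP, "root": BP},
            )

    def test_unknown_namespace_rejected(self):
        with pytest.raises(OntologyError):
            OntologyDAG({"a": set()}, {"a": "weird_namespace"})

    def test_tsv_round_trip(self, tmp_path):
        dag = generate_dag(SimConfig(seed=5))
        dag.to_tsv(tmp_path / "dag.tsv")
        again = load_dag(tmp_path / "dag.tsv")
        assert again.terms == dag.terms
        assert again.parents == dag.parents
        assert again.namespace == dag.namespace

    def test_obo_equals_tsv(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: a\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! root\n\n"
            "[Term]\nid: GO:0000003\nname: b\nnamespace: biological_process\n"
            "is_a: GO:0000002 ! a\n\n"
            "[Term]\nid: GO:0000004\nname: c\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! root\n\n"
            "[Term]\nid: GO:0000005\nname: d\nnamespace: biological_process\n"
            "is_a: GO:0000002 ! a\nis_a: GO:0000004 ! c\n"
        )
        tsv = tmp_path / "mini.tsv"
        tsv.write_text(
            "child_id\tparent_id\tnamespace\n"
            "GO:0000001\t\tbiological_process\n"
            "GO:0000002\tGO:0000001\tbiological_process\n"
            "GO:0000003\tGO:0000002\tbiological_process\n"
            "GO:0000004\tGO:0000001\tbiological_process\n"
            "GO:0000005\tGO:0000002\tbiological_process\n"
            "GO:0000005\tGO:0000004\tbiological_process\n"
        )
        a, b = load_dag(obo), load_dag(tsv)
        assert a.terms == b.terms and a.parents == b.parents


class TestExpandPositives:
    def test_root_alone_expands_to_nothing(self):
        assert expand_positives(chain_dag(), {"root"}) == set()

    def test_chain_closure(self):
        assert expand_positives(chain_dag(), {"b"}) == {"b", "a"}

    def test_empty_input(self):
        assert expand_positives(chain_dag(), set()) == set()

    def test_descendant_mode(self):
        assert expand_positives(chain_dag(), {"a"}, mode="descendants") == {"a", "b"}

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            expand_positives(chain_dag(), {"nope"})


class TestZeroSimilarity:
    def test_siblings_under_root_have_zero_similarity(self):
        dag = star_dag()
        assert zero_similarity(dag, "u", "v") is True

    def test_parent_child_share_more_than_root(self):
        dag = star_dag()
        assert zero_similarity(dag, "x1", "u") is False

    def test_symmetric_and_irreflexive(self):
        dag = generate_dag(SimConfig(seed=2, dag_terms={BP: 25}))
        terms = sorted(dag.terms)
        root = dag.roots[BP]
        for a, b in itertools.combinations(terms, 2):
            assert zero_similarity(dag, a, b) == zero_similarity(dag, b, a)
        for t in terms:
            if t != root:
                assert zero_similarity(dag, t, t) is False

    def test_cross_namespace_rejected(self):
        dag = generate_dag(SimConfig(seed=1))
        ns = sorted({dag.namespace[t] for t in dag.terms})
        assert len(ns) == 2
        a = min(t for t in dag.terms if dag.namespace[t] == ns[0])
        b = min(t for t in dag.terms if dag.namespace[t] == ns[1])
        with pytest.raises(OntologyError):
            zero_similarity(dag, a, b)


class TestInferNegatives:
    def test_below_three_positives_yields_nothing(self):
        assert infer_negatives(star_dag(), {"x1", "x2"}) == set()

    def test_shared_nonroot_ancestor_blocks_everything(self):
        # all terms sit under one non-root hub: nothing is dissimilar to it
        parents = {"root": set(), "hub": {"root"}}
        for i in range(5):
            parents[f"t{i}"] = {"hub"}
        dag = OntologyDAG(parents, {t: BP for t in parents})
        assert infer_negatives(dag, {"t0", "t1", "t2"}) == set()

    def test_disjoint_subtrees_are_negatives(self):
        dag = star_dag()
        # positives fill the u-subtree; negatives are exactly the v-subtree + s
        assert infer_negatives(dag, {"x1", "x2", "x3"}) == {"v", "y1", "y2", "s"}

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        dag = generate_dag(SimConfig(seed=seed, dag_terms={BP: 30}))
        terms = sorted(dag.terms)
        positives = set(terms[5:9])
        assert infer_negatives(dag, positives) == brute_force_negatives(
            dag, positives
        )

    def test_disjoint_from_expanded_positives(self):
        dag = generate_dag(SimConfig(seed=9, dag_terms={BP: 40}))
        positives = set(sorted(dag.terms)[10:14])
        negs = infer_negatives(dag, positives)
        assert negs.isdisjoint(positives)
        assert negs.isdisjoint(expand_positives(dag, positives))

    def test_adding_a_positive_never_grows_the_negative_set(self):
        dag = generate_dag(SimConfig(seed=4, dag_terms={BP: 35}))
        terms = sorted(dag.terms)
        base = set(terms[6:9])
        negs = infer_negatives(dag, base)
        for extra in terms[12:18]:
            if extra in base:
                continue
            assert infer_negatives(dag, base | {extra}) <= negs


class TestDrugCase:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DrugCase("d", frozenset(), frozenset({"p"}), frozenset({"f"}))
        with pytest.raises(ValueError):
            DrugCase(
                "d",
                frozenset({"t"}),
                frozenset({"p"}),
                frozenset({"f"}),
                frozenset({"f"}),
            )

    def test_json_round_trip_and_negative_inference(self, tmp_path):
        dag = star_dag()
        case = DrugCase(
            "drug1",
            targets=frozenset({"t1"}),
            indications=frozenset({"i1"}),
            positives=frozenset({"x1", "x2", "x3"}),
        )
        path = tmp_path / "case.json"
        case.to_json(path)
        loaded = DrugCase.from_json(path, dag=dag)
        assert loaded.negatives == {"v", "y1", "y2", "s"}
        with pytest.raises(ValueError):
            DrugCase.from_json(path, dag=None)
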