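import itertools

import numpy as np
import pytest

from funact.hetnet import (
    FUNCTION,
    MOLECULE,
    PHENOTYPE,
    HeteroNetwork,
    NetworkSchema,
    SchemaRelation,
    default_schema,
)
from funact.metapath import (
    Conventions,
    FeatureTriple,
    MetaPath,
    MetaPathStep,
    enumerate_metapaths,
    find_paths,
    path_features,
    pdp,
)
from funact.synthetic import SimConfig, generate_network, synthetic_schema

from conftest import ANNOT, PPI, REG
from oracles import dp_metapath_count, naive_find_paths, naive_pdp

GO = "CODA|GO|undirected_link"
BIOGRID = "CODA|BioGRID|undirected_link"


class TestEnumerate:
    def test_single_relation_schema(self):
        schema = NetworkSchema(
            [SchemaRelation(GO, MOLECULE, FUNCTION, directed=False)]
        )
        mps = enumerate_metapaths(schema, MOLECULE, FUNCTION, 1)
        assert [m.canonical_string for m in mps] == [f"M-[{GO}]-F"]

    def test_two_relation_schema_exhaustive(self):
        # hand enumeration: M-GO-F and M-BioGRID-M-GO-F are the only options
        schema = NetworkSchema(
            [
                SchemaRelation(BIOGRID, MOLECULE, MOLECULE, directed=False),
                SchemaRelation(GO, MOLECULE, FUNCTION, directed=False),
            ]
        )
        mps = enumerate_metapaths(schema, MOLECULE, FUNCTION, 2)
        assert [m.canonical_string for m in mps] == [
            f"M-[{GO}]-F",
            f"M-[{BIOGRID}]-M-[{GO}]-F",
        ]

    def test_empty_schema_yields_nothing(self):
        assert enumerate_metapaths(NetworkSchema([]), MOLECULE, FUNCTION, 3) == []

    def test_reverse_direction_is_a_distinct_metapath(self):
        schema = NetworkSchema(
            [
                SchemaRelation(REG, MOLECULE, MOLECULE, directed=True),
                SchemaRelation(GO, MOLECULE, FUNCTION, directed=False),
            ]
        )
        mps = enumerate_metapaths(schema, MOLECULE, FUNCTION, 2)
        strings = [m.canonical_string for m in mps]
        assert f"M>[{REG}]>M-[{GO}]-F" in strings
        assert f"M<[{REG}]<M-[{GO}]-F" in strings

    @pytest.mark.parametrize("calibrated", [False, True])
    @pytest.mark.parametrize("reverse_steps", [False, True])
    @pytest.mark.parametrize("max_len", [1, 2, 3])
    def test_count_matches_dp_oracle(self, calibrated, reverse_steps, max_len):
        """Enumerator size equals the closed-form DP count for every convention."""
        schema = default_schema(calibrated=calibrated)
        conv = Conventions(reverse_steps=reverse_steps)
        for src, dst in ((MOLECULE, FUNCTION), (FUNCTION, PHENOTYPE)):
            got = len(enumerate_metapaths(schema, src, dst, max_len, conv))
            assert got == dp_metapath_count(schema, src, dst, max_len, conv)

    def test_output_sorted_and_unique(self):
        schema = synthetic_schema()
        mps = enumerate_metapaths(schema, MOLECULE, FUNCTION, 3)
        keys = [(m.length, m.canonical_string) for m in mps]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)


class TestFindPaths:
    def test_edgeless_network(self, tiny_schema):
        net = HeteroNetwork(tiny_schema)
        net.add_node("m1", MOLECULE)
        net.add_node("f1", FUNCTION)
        mp = enumerate_metapaths(tiny_schema, MOLECULE, FUNCTION, 1)[0]
        assert find_paths(net, ["m1"], "f1", mp) == []

    def test_discriminating_metapath_counts(self, two_path_network):
        """Two M-M-F paths reach the positive function, none the negative."""
        mp = MetaPath(
            (
                MetaPathStep(PPI, MOLECULE, MOLECULE, "undirected"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        to_f1 = find_paths(two_path_network, ["ace"], "f1", mp)
        to_f2 = find_paths(two_path_network, ["ace"], "f2", mp)
        assert [p.node_ids for p in to_f1] == [
            ("ace", "mA", "f1"),
            ("ace", "mB", "f1"),
        ]
        assert to_f2 == []

    def test_type_mismatch_raises(self, two_path_network):
        mp = enumerate_metapaths(
            two_path_network.schema, MOLECULE, FUNCTION, 1
        )[0]
        with pytest.raises(TypeError):
            find_paths(two_path_network, ["f1"], "f2", mp)
        with pytest.raises(TypeError):
            find_paths(two_path_network, ["ace"], "mA", mp)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_dfs(self, seed):
        """Optimized traversal equals a naive all-nodes DFS on small networks."""
        net, schema = generate_network(
            SimConfig(n_molecules=9, n_functions=8, n_phenotypes=6,
                      edge_counts={PPI: 14, REG: 7, ANNOT: 12,
                                   "sim|CoFunction|undirected_link": 8,
                                   "sim|FunctionDisease|undirected_link": 8,
                                   "sim|Comorbidity|undirected_link": 5},
                      seed=seed)
        )
        sources = net.nodes_of_type(MOLECULE)[:2]
        for mp in enumerate_metapaths(schema, MOLECULE, FUNCTION, 3):
            for f in net.nodes_of_type(FUNCTION)[:4]:
                got = [p.node_ids for p in find_paths(net, sources, f, mp)]
                assert got == naive_find_paths(net, sources, f, mp)


class TestPdp:
    def _unit_network(self):
        schema = NetworkSchema(
            [
                SchemaRelation(REG, MOLECULE, MOLECULE, directed=True),
                SchemaRelation(ANNOT, MOLECULE, FUNCTION, directed=False),
            ]
        )
        net = HeteroNetwork(schema)
        for n, t in {"a": MOLECULE, "b": MOLECULE, "f": FUNCTION}.items():
            net.add_node(n, t)
        net.add_edge("a", REG, "b")
        net.add_edge("b", ANNOT, "f")
        mp = MetaPath(
            (
                MetaPathStep(REG, MOLECULE, MOLECULE, "forward"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        return net, mp

    def test_all_unit_degrees_give_one(self):
        net, mp = self._unit_network()
        (path,) = find_paths(net, ["a"], "f", mp)
        assert pdp(net, path, w=0.5) == pytest.approx(1.0)

    def test_w_zero_gives_one(self):
        net, mp = self._unit_network()
        (path,) = find_paths(net, ["a"], "f", mp)
        assert pdp(net, path, w=0.0) == 1.0

    def test_negative_w_rejected(self):
        net, mp = self._unit_network()
        (path,) = find_paths(net, ["a"], "f", mp)
        with pytest.raises(ValueError):
            pdp(net, path, w=-0.1)

    def test_hand_computed_product(self):
        """m1(out 4) -> m2(in 1, out 9) -> f1(in 1), w=0.5 gives 1/6."""
        schema = NetworkSchema(
            [
                SchemaRelation(REG, MOLECULE, MOLECULE, directed=True),
                SchemaRelation(ANNOT, MOLECULE, FUNCTION, directed=False),
            ]
        )
        net = HeteroNetwork(schema)
        net.add_node("m1", MOLECULE)
        net.add_node("m2", MOLECULE)
        for i in range(3):
            net.add_node(f"x{i}", MOLECULE)
        for i in range(9):
            net.add_node(f"f{i}", FUNCTION)
        net.add_edge("m1", REG, "m2")
        for i in range(3):
            net.add_edge("m1", REG, f"x{i}")  # m1 out-degree 4
        for i in range(9):
            net.add_edge("m2", ANNOT, f"f{i}")  # m2 annotation degree 9
        mp = MetaPath(
            (
                MetaPathStep(REG, MOLECULE, MOLECULE, "forward"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        (path,) = find_paths(net, ["m1"], "f0", mp)
        assert pdp(net, path, w=0.5) == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_tally_oracle_and_monotone_in_w(self, seed):
        net, schema = generate_network(
            SimConfig(n_molecules=10, n_functions=8, n_phenotypes=6,
                      edge_counts={PPI: 18, REG: 8, ANNOT: 14,
                                   "sim|CoFunction|undirected_link": 8,
                                   "sim|FunctionDisease|undirected_link": 8,
                                   "sim|Comorbidity|undirected_link": 5},
                      seed=seed)
        )
        sources = net.nodes_of_type(MOLECULE)[:3]
        ws = [0.0, 0.25, 0.5, 1.0, 2.0]
        for mp in enumerate_metapaths(schema, MOLECULE, FUNCTION, 2):
            for f in net.nodes_of_type(FUNCTION)[:3]:
                for path in find_paths(net, sources, f, mp):
                    values = [pdp(net, path, w) for w in ws]
                    assert values[0] == 1.0
                    assert all(a >= b for a, b in zip(values, values[1:]))
                    assert values[2] == pytest.approx(
                        naive_pdp(net, mp, path.node_ids, 0.5), abs=1e-12
                    )


class TestPathFeatures:
    def test_no_paths_is_zero_triple(self, two_path_network):
        mp = MetaPath(
            (
                MetaPathStep(PPI, MOLECULE, MOLECULE, "undirected"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        assert path_features(two_path_network, ["ace"], "f2", mp) == FeatureTriple.ZERO

    def test_triple_aggregates_over_paths(self, two_path_network):
        mp = MetaPath(
            (
                MetaPathStep(PPI, MOLECULE, MOLECULE, "undirected"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        paths = find_paths(two_path_network, ["ace"], "f1", mp)
        values = [pdp(two_path_network, p, 0.5) for p in paths]
        triple = path_features(two_path_network, ["ace"], "f1", mp, w=0.5)
        assert triple.path_count == 2
        assert triple.pdp_sum == pytest.approx(sum(values))
        assert triple.pdp_max == pytest.approx(max(values))
        # invariants: each PDP lies in (0, 1]
        assert triple.pdp_max <= triple.pdp_sum <= triple.path_count

    def test_w_zero_collapses_to_path_count(self, two_path_network):
        mp = MetaPath(
            (
                MetaPathStep(PPI, MOLECULE, MOLECULE, "undirected"),
                MetaPathStep(ANNOT, MOLECULE, FUNCTION, "undirected"),
            )
        )
        triple = path_features(two_path_network, ["ace"], "f1", mp, w=0.0)
        assert triple.pdp_sum == triple.path_count
        assert triple.pdp_max == 1.0
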