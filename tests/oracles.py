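"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's traversal indices and optimized code
paths: path search walks the raw edge set, the meta-path counter is a
dynamic program over step multiplicities, and AUROC counts concordant pairs
directly.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from funact.hetnet import HeteroNetwork, NetworkSchema
from funact.metapath import (
    FORWARD,
    REVERSE,
    UNDIRECTED,
    Conventions,
    MetaPath,
)


def edge_exists(net: HeteroNetwork, u: str, rel: str, v: str, orientation: str) -> bool:
    """Check a traversal u->v over the raw edge set (no adjacency index)."""
    directed = any(r.directed for r in net.schema.relations_named(rel))
    if directed:
        if orientation == REVERSE:
            return (v, rel, u) in net.edges
        return (u, rel, v) in net.edges
    if orientation == FORWARD:
        return (u, rel, v) in net.edges
    if orientation == REVERSE:
        return (v, rel, u) in net.edges
    return (u, rel, v) in net.edges or (v, rel, u) in net.edges


def naive_find_paths(
    net: HeteroNetwork,
    src_nodes,
    dst_node: str,
    metapath: MetaPath,
    simple: bool = True,
) -> list[tuple[str, ...]]:
    """Exhaustive DFS over all typed nodes; returns sorted node-id tuples."""
    out: list[tuple[str, ...]] = []
    nodes_by_type: dict[str, list[str]] = {}
    for n, t in net.nodes.items():
        nodes_by_type.setdefault(t, []).append(n)

    def rec(prefix: tuple[str, ...]) -> None:
        depth = len(prefix) - 1
        if depth == metapath.length:
            if prefix[-1] == dst_node:
                out.append(prefix)
            return
        step = metapath.steps[depth]
        for v in nodes_by_type.get(step.to_type, ()):
            if simple and v in prefix:
                continue
            if edge_exists(net, prefix[-1], step.relation, v, step.orientation):
                rec(prefix + (v,))

    for s in sorted(set(src_nodes)):
        rec((s,))
    return sorted(out)


def naive_pdp(net: HeteroNetwork, metapath: MetaPath, nodes, w: float) -> float:
    """Degree product from direct tallies over the edge set."""

    def tally(node: str, rel: str, orientation: str) -> int:
        directed = any(r.directed for r in net.schema.relations_named(rel))
        n = 0
        for a, t, b in net.edges:
            if t != rel:
                continue
            if directed:
                if orientation == "out" and a == node:
                    n += 1
                elif orientation == "in" and b == node:
                    n += 1
            else:
                if node in (a, b):
                    n += 1
        return n

    val = 1.0
    for i, step in enumerate(metapath.steps):
        u, v = nodes[i], nodes[i + 1]
        if step.orientation == REVERSE:
            du, dv = tally(u, step.relation, "in"), tally(v, step.relation, "out")
        else:
            du, dv = tally(u, step.relation, "out"), tally(v, step.relation, "in")
        val *= du ** (-w) * dv ** (-w)
    return val


def dp_metapath_count(
    schema: NetworkSchema,
    src_type: str,
    dst_type: str,
    max_len: int,
    conventions: Conventions,
) -> int:
    """Count type-level meta-paths by matrix powers over step multiplicities."""
    types = ["molecule", "function", "phenotype"]
    A = np.zeros((3, 3), dtype=np.int64)
    for rel in schema:
        i, j = types.index(rel.src_type), types.index(rel.dst_type)
        if rel.directed:
            A[i, j] += 1
            if conventions.reverse_steps:
                A[j, i] += 1
        elif rel.oriented:
            A[i, j] += 1
            A[j, i] += 1
        else:
            A[i, j] += 1
            if i != j:
                A[j, i] += 1
    v = np.zeros(3, dtype=np.int64)
    v[types.index(src_type)] = 1
    total = 0
    for _ in range(max_len):
        v = v @ A
        total += int(v[types.index(dst_type)])
    return total


def mann_whitney_auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative; ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_negatives(dag, positives) -> set[str]:
    """Direct re-derivation of the zero-similarity negative rule."""
    pos = set(positives)
    by_ns: dict[str, set[str]] = {}
    for t in pos:
        by_ns.setdefault(dag.namespace[t], set()).add(t)
    roots = set(dag.roots.values())
    out: set[str] = set()
    for ns, ns_pos in by_ns.items():
        if len(ns_pos) < 3:
            continue
        for t in dag.terms:
            if dag.namespace[t] != ns or t in pos or t in roots:
                continue
            if all(
                len(set(dag.ancestors(t)) & set(dag.ancestors(p))) == 1
                for p in ns_pos
            ):
                out.add(t)
    return out
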