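"""Meta-path enumeration and path statistics (path count, PDP sum, PDP max).

A meta-path is a type-level sequence of node types and (oriented) edge types;
every concrete path in the network instantiates exactly one meta-path.  Three
statistics summarise the set of instances of a meta-path between a drug's
access points (targets or indications) and a candidate function:

* the path count,
* the sum of path-degree products (PDPs), and
* the maximum PDP,

where the PDP of a path multiplies, over every traversed hop, the step-wise
degrees of its endpoints raised to the power ``-w``.  The damping exponent
``w`` (default 0.5) discounts paths that run through hub nodes; ``w = 0``
recovers the raw path count.

Directed relation types may be traversed against their direction; such a
reverse traversal is a distinct step in the meta-path identity (canonical
strings mark it with ``<``).  Undirected relations normally contribute a
single orientation-free step (``-``); relations whose schema entry is marked
``oriented`` instead behave like a stored orientation with a mechanical
reverse step, which matters only for meta-path identity, not connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .hetnet import (
    FUNCTION,
    MOLECULE,
    PHENOTYPE,
    TYPE_LETTER,
    HeteroNetwork,
    NetworkSchema,
    SchemaRelation,
)

FORWARD = "forward"
REVERSE = "reverse"
UNDIRECTED = "undirected"


@dataclass(frozen=True)
class Conventions:
    """Tunable traversal/enumeration conventions.

    ``reverse_steps``: whether directed relations may be traversed backwards
    (as distinct meta-path steps).  ``simple_paths``: restrict instances to
    paths with no repeated node.  ``pdp_degree_mode``: ``metaedge`` uses the
    degree of each node with respect to the traversed edge type and
    orientation (every factor >= 1); ``global`` uses whole-network in/out
    degrees, with zero degrees treated as 1.
    """

    reverse_steps: bool = True
    simple_paths: bool = True
    max_len_target: int = 3
    max_len_indication: int = 2
    w: float = 0.5
    pdp_degree_mode: str = "metaedge"


DEFAULT_CONVENTIONS = Conventions()


@dataclass(frozen=True)
class MetaPathStep:
    relation: str
    from_type: str
    to_type: str
    orientation: str  # forward | reverse | undirected

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE, UNDIRECTED):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def token(self) -> str:
        mark = {FORWARD: ">", REVERSE: "<", UNDIRECTED: "-"}[self.orientation]
        return f"{mark}[{self.relation}]{mark}{TYPE_LETTER[self.to_type]}"


@dataclass(frozen=True)
class MetaPath:
    steps: tuple[MetaPathStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a meta-path needs at least one step")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.to_type != b.from_type:
                raise ValueError("meta-path steps do not chain on node types")

    @property
    def src_type(self) -> str:
        return self.steps[0].from_type

    @property
    def dst_type(self) -> str:
        return self.steps[-1].to_type

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def canonical_string(self) -> str:
        return TYPE_LETTER[self.src_type] + "".join(s.token for s in self.steps)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.canonical_string


@dataclass(frozen=True)
class PathInstance:
    node_ids: tuple[str, ...]
    metapath: MetaPath

    def __post_init__(self) -> None:
        if len(self.node_ids) != self.metapath.length + 1:
            raise ValueError("node count must equal meta-path length + 1")


@dataclass(frozen=True)
class FeatureTriple:
    path_count: int
    pdp_sum: float
    pdp_max: float

    ZERO = None  # set below

    def as_tuple(self) -> tuple[int, float, float]:
        return (self.path_count, self.pdp_sum, self.pdp_max)


FeatureTriple.ZERO = FeatureTriple(0, 0.0, 0.0)

STAT_NAMES = ("path_count", "pdp_sum", "pdp_max")


def schema_steps(
    schema: NetworkSchema,
    from_type: str,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> list[MetaPathStep]:
    """All legal meta-path steps leaving a node of ``from_type``."""
    steps: list[MetaPathStep] = []
    for rel in schema:
        if rel.directed:
            if rel.src_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.dst_type, FORWARD)
                )
            if conventions.reverse_steps and rel.dst_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.src_type, REVERSE)
                )
        elif rel.oriented:
            # stored orientation retained: forward and reverse are distinct
            if rel.src_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.dst_type, FORWARD)
                )
            if rel.dst_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.src_type, REVERSE)
                )
        else:
            if rel.src_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.dst_type, UNDIRECTED)
                )
            elif rel.dst_type == from_type:
                steps.append(
                    MetaPathStep(rel.name, from_type, rel.src_type, UNDIRECTED)
                )
    return steps


def enumerate_metapaths(
    schema: NetworkSchema,
    src_type: str,
    dst_type: str,
    max_len: int,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> list[MetaPath]:
    """All type-consistent meta-paths of length 1..max_len, sorted.

    Sorted by (length, canonical string); an empty schema yields an empty
    list.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    results: list[MetaPath] = []
    frontier: list[tuple[str, tuple[MetaPathStep, ...]]] = [(src_type, ())]
    for _ in range(max_len):
        nxt: list[tuple[str, tuple[MetaPathStep, ...]]] = []
        for node_type, prefix in frontier:
            for step in schema_steps(schema, node_type, conventions):
                seq = prefix + (step,)
                nxt.append((step.to_type, seq))
                if step.to_type == dst_type:
                    results.append(MetaPath(seq))
        frontier = nxt
    results.sort(key=lambda mp: (mp.length, mp.canonical_string))
    return results


def _step_neighbors(net: HeteroNetwork, node: str, step: MetaPathStep) -> set[str]:
    if step.orientation == FORWARD:
        # for oriented-undirected relations the schema may legalise rows in
        # either order, but traversal still follows storage orientation
        return net.neighbors(node, step.relation, "out")
    if step.orientation == REVERSE:
        return net.neighbors(node, step.relation, "in")
    return net.neighbors(node, step.relation, "any")


def find_paths(
    network: HeteroNetwork,
    src_nodes: Iterable[str],
    dst_node: str,
    metapath: MetaPath,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> list[PathInstance]:
    """All path instances of ``metapath`` from any source to ``dst_node``.

    Sources are pooled (a drug may have several targets or indications) and
    results are returned in lexicographic order of their node-id sequences.
    By default instances are simple paths (no node repeated).
    """
    sources = sorted(set(src_nodes))
    for s in sources:
        if s not in network.nodes:
            raise KeyError(f"unknown source node {s!r}")
        if network.node_type(s) != metapath.src_type:
            raise TypeError(
                f"source {s!r} has type {network.node_type(s)}, "
                f"meta-path starts at {metapath.src_type}"
            )
    if dst_node not in network.nodes:
        raise KeyError(f"unknown destination node {dst_node!r}")
    if network.node_type(dst_node) != metapath.dst_type:
        raise TypeError(
            f"destination {dst_node!r} has type {network.node_type(dst_node)}, "
            f"meta-path ends at {metapath.dst_type}"
        )
    out: list[PathInstance] = []
    steps = metapath.steps

    def extend(prefix: tuple[str, ...]) -> None:
        depth = len(prefix) - 1
        if depth == len(steps):
            if prefix[-1] == dst_node:
                out.append(PathInstance(prefix, metapath))
            return
        step = steps[depth]
        candidates = _step_neighbors(network, prefix[-1], step)
        if depth == len(steps) - 1:
            candidates = candidates & {dst_node}
        for nxt in sorted(candidates):
            if conventions.simple_paths and nxt in prefix:
                continue
            extend(prefix + (nxt,))

    for s in sources:
        extend((s,))
    out.sort(key=lambda p: p.node_ids)
    return out


def pdp(
    network: HeteroNetwork,
    path: PathInstance,
    w: float = DEFAULT_CONVENTIONS.w,
    degree_mode: str = DEFAULT_CONVENTIONS.pdp_degree_mode,
) -> float:
    """Path-degree product of one concrete path.

    Every traversed hop contributes the degree of its source node in the
    step's leaving orientation and the degree of its target node in the
    arriving orientation, each raised to ``-w``.  Intermediate nodes thus
    contribute both their arriving and leaving degrees, matching the
    in-degree/out-degree product over all nodes of the path.
    """
    if w < 0:
        raise ValueError("damping exponent w must be >= 0")
    if degree_mode not in ("metaedge", "global"):
        raise ValueError(f"unknown pdp degree mode {degree_mode!r}")
    value = 1.0
    for i, step in enumerate(path.metapath.steps):
        u, v = path.node_ids[i], path.node_ids[i + 1]
        if degree_mode == "metaedge":
            if step.orientation == REVERSE:
                du = network.degree(u, step.relation, "in")
                dv = network.degree(v, step.relation, "out")
            else:
                du = network.degree(u, step.relation, "out")
                dv = network.degree(v, step.relation, "in")
        else:
            du = network.global_degree(u, "out") or 1
            dv = network.global_degree(v, "in") or 1
        value *= float(du) ** (-w) * float(dv) ** (-w)
    return value


def path_features(
    network: HeteroNetwork,
    src_nodes: Iterable[str],
    dst_node: str,
    metapath: MetaPath,
    w: float = DEFAULT_CONVENTIONS.w,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> FeatureTriple:
    """(path count, PDP sum, PDP max) over all instances; zeros if none."""
    paths = find_paths(network, src_nodes, dst_node, metapath, conventions)
    return triple_from_paths(network, paths, w, conventions.pdp_degree_mode)


def triple_from_paths(
    network: HeteroNetwork,
    paths: Sequence[PathInstance],
    w: float,
    degree_mode: str = "metaedge",
) -> FeatureTriple:
    if not paths:
        return FeatureTriple.ZERO
    values = [pdp(network, p, w, degree_mode) for p in paths]
    return FeatureTriple(len(paths), float(sum(values)), float(max(values)))


def write_metapaths_tsv(
    path: str | Path, metapaths: Iterable[tuple[MetaPath, str]]
) -> None:
    """Write ``canonical_string<TAB>length<TAB>side`` rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metapath\tlength\tside\n")
        for mp, side in metapaths:
            fh.write(f"{mp.canonical_string}\t{mp.length}\t{side}\n")
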