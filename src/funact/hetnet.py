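"""Typed heterogeneous (multi-level) biological networks.

The network substrate is a typed graph over three node types — molecules
(genes/proteins), functions (GO terms) and phenotypes (diseases) — whose
edges carry named relation types such as ``CODA|BioGRID|undirected_link``.
A :class:`NetworkSchema` catalogues which relation types may connect which
node-type pairs and whether they are directed; every loaded edge is checked
against it.  All path and degree computations used by the meta-path feature
machinery run on the indices built here.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

MOLECULE = "molecule"
FUNCTION = "function"
PHENOTYPE = "phenotype"
NODE_TYPES: tuple[str, ...] = (MOLECULE, FUNCTION, PHENOTYPE)

#: single-letter labels used in canonical meta-path strings
TYPE_LETTER = {MOLECULE: "M", FUNCTION: "F", PHENOTYPE: "P"}


class NetworkFormatError(ValueError):
    """Base class for malformed network input; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownNodeTypeError(NetworkFormatError):
    """A node row declares a type outside {molecule, function, phenotype}."""


class UnknownNodeError(NetworkFormatError):
    """An edge references a node id that was never declared."""


class SchemaViolationError(NetworkFormatError):
    """An edge's (type, endpoint types) combination matches no schema relation."""


@dataclass(frozen=True)
class SchemaRelation:
    """One relation type on one allowed node-type pair.

    A relation type name (database|resource|category) may legally appear on
    several node-type pairs (e.g. UMLS NCI links molecules, functions and
    phenotypes); each pair is its own :class:`SchemaRelation`.

    ``oriented`` applies to undirected relations only: it marks relations
    whose source rows carry a meaningful storage orientation that is retained
    in meta-path identities (see :mod:`funact.metapath`).  It has no effect
    on connectivity or degrees.
    """

    name: str
    src_type: str
    dst_type: str
    directed: bool
    oriented: bool = False

    def __post_init__(self) -> None:
        for t in (self.src_type, self.dst_type):
            if t not in NODE_TYPES:
                raise UnknownNodeTypeError(f"unknown node type {t!r}")
        if not self.directed and not self.oriented:
            # canonical storage for plain undirected relations
            if self.src_type > self.dst_type:
                s, d = self.src_type, self.dst_type
                object.__setattr__(self, "src_type", d)
                object.__setattr__(self, "dst_type", s)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.src_type, self.dst_type)


class NetworkSchema:
    """Catalogue of relation types × allowed node-type pairs × directedness."""

    def __init__(self, relations: Iterable[SchemaRelation]):
        self.relations: tuple[SchemaRelation, ...] = tuple(relations)
        seen: set[tuple[str, str, str]] = set()
        for rel in self.relations:
            key = (rel.name, *sorted(rel.pair))
            if key in seen:
                raise ValueError(f"duplicate schema relation {key}")
            seen.add(key)
        self._by_name: dict[str, list[SchemaRelation]] = {}
        for rel in self.relations:
            self._by_name.setdefault(rel.name, []).append(rel)

    def __len__(self) -> int:
        return len(self.relations)

    def __iter__(self) -> Iterator[SchemaRelation]:
        return iter(self.relations)

    @property
    def edge_type_names(self) -> tuple[str, ...]:
        """Distinct relation type names, in first-appearance order."""
        return tuple(self._by_name)

    def relations_named(self, name: str) -> list[SchemaRelation]:
        if name not in self._by_name:
            raise KeyError(f"unknown edge type {name!r}")
        return list(self._by_name[name])

    def match(self, src_type: str, name: str, dst_type: str) -> SchemaRelation | None:
        """Relation legalising an edge stored as src_type --name--> dst_type."""
        for rel in self._by_name.get(name, ()):
            if rel.directed or rel.oriented:
                if rel.pair == (src_type, dst_type):
                    return rel
            else:
                if set(rel.pair) == {src_type, dst_type} or rel.pair == (
                    src_type,
                    dst_type,
                ):
                    return rel
        # an undirected oriented relation still legalises rows in either order
        for rel in self._by_name.get(name, ()):
            if not rel.directed and rel.pair == (dst_type, src_type):
                return rel
        return None

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path: str | Path | io.TextIOBase) -> "NetworkSchema":
        """Read ``edge_type  src_type  dst_type  directed  [oriented]``."""
        close = False
        if isinstance(path, (str, Path)):
            handle = open(path, newline="", encoding="utf-8")
            close = True
        else:
            handle = path
        try:
            reader = csv.DictReader(handle, delimiter="\t")
            rels = []
            for i, row in enumerate(reader, start=2):
                try:
                    rels.append(
                        SchemaRelation(
                            name=row["edge_type"],
                            src_type=row["src_type"],
                            dst_type=row["dst_type"],
                            directed=bool(int(row["directed"])),
                            oriented=bool(int(row.get("oriented", 0) or 0)),
                        )
                    )
                except UnknownNodeTypeError as exc:
                    raise UnknownNodeTypeError(str(exc), line=i) from None
            return cls(rels)
        finally:
            if close:
                handle.close()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write("edge_type\tsrc_type\tdst_type\tdirected\toriented\n")
            for rel in self.relations:
                fh.write(
                    f"{rel.name}\t{rel.src_type}\t{rel.dst_type}"
                    f"\t{int(rel.directed)}\t{int(rel.oriented)}\n"
                )


def default_schema(calibrated: bool = False) -> NetworkSchema:
    """The shipped 18-edge-type multi-level network schema.

    The plain variant stores every undirected relation as an unordered pair.
    The calibrated variant marks undirected relations from CODA resources and
    the UMLS NCI thesaurus as orientation-retaining, which is the convention
    under which the enumerator reproduces the published meta-path totals (see
    docs/methods.md).
    """
    fname = "multilevel_schema_calibrated.tsv" if calibrated else "multilevel_schema.tsv"
    ref = resources.files("funact.data").joinpath(fname)
    with ref.open("r", encoding="utf-8") as fh:
        return NetworkSchema.from_tsv(fh)


@dataclass
class NetworkSummary:
    node_counts: dict[str, int]
    edge_counts: dict[tuple[str, str, str], int]  # (edge_type, src_t, dst_t) -> n

    @property
    def n_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def n_edges(self) -> int:
        return sum(self.edge_counts.values())

    def edge_counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (name, _, _), n in self.edge_counts.items():
            out[name] = out.get(name, 0) + n
        return out

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "node_counts": dict(self.node_counts),
            "edge_counts": {
                f"{name}\t{s}\t{d}": n for (name, s, d), n in self.edge_counts.items()
            },
        }


class HeteroNetwork:
    """Typed nodes + typed edges with per-(node, edge type) degree indices.

    Edges are stored once, in their load orientation.  Undirected relations
    are traversable (and counted in degrees) in both orientations.
    """

    def __init__(self, schema: NetworkSchema):
        self.schema = schema
        self.nodes: dict[str, str] = {}
        self.edges: set[tuple[str, str, str]] = set()
        # (node, edge_type) -> {"out": set(), "in": set()} per storage orientation
        self._adj: dict[tuple[str, str], dict[str, set[str]]] = {}
        # unordered dedup key for undirected relations
        self._undirected_seen: set[tuple[str, str, str]] = set()

    # ------------------------------------------------------------- building
    def add_node(self, node_id: str, node_type: str, line: int | None = None) -> None:
        if node_type not in NODE_TYPES:
            raise UnknownNodeTypeError(
                f"node {node_id!r} has unknown type {node_type!r}", line=line
            )
        prev = self.nodes.get(node_id)
        if prev is not None and prev != node_type:
            raise NetworkFormatError(
                f"node {node_id!r} redeclared as {node_type!r} (was {prev!r})",
                line=line,
            )
        self.nodes[node_id] = node_type

    def add_edge(
        self, src: str, edge_type: str, dst: str, line: int | None = None
    ) -> bool:
        """Add one edge; returns False if it collapsed onto an existing edge."""
        for n in (src, dst):
            if n not in self.nodes:
                raise UnknownNodeError(
                    f"edge references undeclared node {n!r}", line=line
                )
        if src == dst:
            raise SchemaViolationError(
                f"self-loop on {src!r} via {edge_type!r} is not allowed", line=line
            )
        rel = self.schema.match(self.nodes[src], edge_type, self.nodes[dst])
        if rel is None:
            raise SchemaViolationError(
                f"edge {src!r} --{edge_type}--> {dst!r} "
                f"({self.nodes[src]}-{self.nodes[dst]}) matches no schema relation",
                line=line,
            )
        if not rel.directed:
            key = (edge_type, *sorted((src, dst)))
            if key in self._undirected_seen:
                return False
            self._undirected_seen.add(key)
        elif (src, edge_type, dst) in self.edges:
            return False
        self.edges.add((src, edge_type, dst))
        self._adj.setdefault((src, edge_type), {"out": set(), "in": set()})[
            "out"
        ].add(dst)
        self._adj.setdefault((dst, edge_type), {"out": set(), "in": set()})[
            "in"
        ].add(src)
        return True

    # ------------------------------------------------------------- querying
    def node_type(self, node_id: str) -> str:
        return self.nodes[node_id]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t == node_type)

    def _relation_is_directed(self, edge_type: str) -> bool:
        return any(rel.directed for rel in self.schema.relations_named(edge_type))

    def neighbors(self, node: str, edge_type: str, orientation: str = "out") -> set[str]:
        """Nodes reachable from ``node`` over ``edge_type``.

        ``orientation`` is interpreted against storage order: ``out`` follows
        stored edges, ``in`` runs against them, ``any`` ignores it.  For
        undirected relations ``any`` is the natural traversal.
        """
        if node not in self.nodes:
            raise UnknownNodeError(f"unknown node {node!r}")
        adj = self._adj.get((node, edge_type))
        if adj is None:
            # still validate the edge type name
            self.schema.relations_named(edge_type)
            return set()
        if orientation == "out":
            return set(adj["out"])
        if orientation == "in":
            return set(adj["in"])
        if orientation == "any":
            return adj["out"] | adj["in"]
        raise ValueError(f"orientation must be out/in/any, got {orientation!r}")

    def degree(self, node: str, edge_type: str, orientation: str = "out") -> int:
        """Number of ``edge_type`` edges incident to ``node``.

        For directed relation types the storage orientation is respected; for
        undirected types each incident edge counts in both orientations, so
        out- and in-degree coincide.
        """
        if orientation not in ("out", "in"):
            raise ValueError(f"orientation must be out or in, got {orientation!r}")
        if self._relation_is_directed(edge_type):
            return len(self.neighbors(node, edge_type, orientation))
        return len(self.neighbors(node, edge_type, "any"))

    def global_degree(self, node: str, orientation: str) -> int:
        """Degree across all edge types (undirected edges count both ways)."""
        total = 0
        for (n, et), adj in self._adj.items():
            if n != node:
                continue
            if self._relation_is_directed(et):
                total += len(adj[orientation])
            else:
                total += len(adj["out"] | adj["in"])
        return total

    def summarize(self) -> NetworkSummary:
        node_counts = {t: 0 for t in NODE_TYPES}
        for t in self.nodes.values():
            node_counts[t] += 1
        edge_counts: dict[tuple[str, str, str], int] = {}
        for src, et, dst in self.edges:
            st, dt = self.nodes[src], self.nodes[dst]
            rel = self.schema.match(st, et, dt)
            assert rel is not None
            key = (et, *rel.pair)
            edge_counts[key] = edge_counts.get(key, 0) + 1
        return NetworkSummary(node_counts=node_counts, edge_counts=edge_counts)

    def copy(self) -> "HeteroNetwork":
        new = HeteroNetwork(self.schema)
        new.nodes = dict(self.nodes)
        for src, et, dst in self.edges:
            new.add_edge(src, et, dst)
        return new


def load_network(
    nodes_path: str | Path, edges_path: str | Path, schema: NetworkSchema
) -> HeteroNetwork:
    """Load a network from node and edge TSV files, validating against schema.

    ``nodes.tsv``: header ``node_id<TAB>node_type``;
    ``edges.tsv``: header ``source_id<TAB>edge_type<TAB>target_id``.
    Duplicate edge rows collapse to one edge.  Violations raise subclasses of
    :class:`NetworkFormatError` that carry the offending 1-based line number.
    """
    if len(schema) == 0:
        raise ValueError("schema is empty")
    net = HeteroNetwork(schema)
    with open(nodes_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[:1] != ["node_id"]:
            # headerless file: first row is data
            _add_node_row(net, header, 1)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            _add_node_row(net, row, i)
    with open(edges_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[:1] != ["source_id"]:
            _add_edge_row(net, header, 1)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            _add_edge_row(net, row, i)
    return net


def _add_node_row(net: HeteroNetwork, row: list[str], line: int) -> None:
    if len(row) < 2:
        raise NetworkFormatError(f"node row needs 2 columns, got {row!r}", line=line)
    net.add_node(row[0], row[1], line=line)


def _add_edge_row(net: HeteroNetwork, row: list[str], line: int) -> None:
    if len(row) < 3:
        raise NetworkFormatError(f"edge row needs 3 columns, got {row!r}", line=line)
    net.add_edge(row[0], row[1], row[2], line=line)


def save_network(
    net: HeteroNetwork, nodes_path: str | Path, edges_path: str | Path
) -> None:
    with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
        fh.write("node_id\tnode_type\n")
        for node_id in sorted(net.nodes):
            fh.write(f"{node_id}\t{net.nodes[node_id]}\n")
    with open(edges_path, "w", newline="", encoding="utf-8") as fh:
        fh.write("source_id\tedge_type\ttarget_id\n")
        for src, et, dst in sorted(net.edges):
            fh.write(f"{src}\t{et}\t{dst}\n")


def summarize(net: HeteroNetwork) -> NetworkSummary:
    """Module-level convenience mirroring :meth:`HeteroNetwork.summarize`."""
    return net.summarize()
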