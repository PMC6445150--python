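"""GO-style DAG handling, positive-example expansion, negative inference.

Positive examples of a drug's functional actions are GO terms; they are
expanded along the hierarchy (true-path rule).  Negative examples are the
terms whose topology-based similarity to *every* positive is zero — i.e.
terms sharing only the namespace root with each positive — inferred per
namespace and only when that namespace holds at least three positives.

The DAG is deliberately independent of the traversal network: hierarchy
edges never participate in meta-path search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: minimum positives in a namespace before negatives are inferred there
MIN_POSITIVES_PER_NAMESPACE = 3


class OntologyError(ValueError):
    pass


class OntologyDAG:
    """An is_a DAG with one root per namespace.

    ``parents`` maps each term to its direct is_a parents; ``ancestors(t)``
    is the reflexive-transitive closure (``t`` included), which by validation
    always contains the namespace root.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        namespace: Mapping[str, str],
        part_of: Mapping[str, Iterable[str]] | None = None,
        use_part_of: bool = False,
    ):
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        if use_part_of and part_of:
            for t, ps in part_of.items():
                self.parents[t] = self.parents.get(t, frozenset()) | frozenset(ps)
        self.namespace: dict[str, str] = dict(namespace)
        self.terms: frozenset[str] = frozenset(self.namespace)
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._validate()

    def _validate(self) -> None:
        for t in self.parents:
            if t not in self.terms:
                raise OntologyError(f"term {t!r} has parents but no namespace")
        for t, ns in self.namespace.items():
            if ns not in NAMESPACES:
                raise OntologyError(f"term {t!r} has unknown namespace {ns!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise OntologyError(f"parent {p!r} of {child!r} is undeclared")
                if self.namespace[p] != self.namespace[child]:
                    raise OntologyError(
                        f"cross-namespace is_a edge {child!r} -> {p!r}"
                    )
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"hierarchy contains a cycle: {cycle}")
        self.roots: dict[str, str] = {}
        for t in sorted(self.terms):
            if not self.parents.get(t):
                ns = self.namespace[t]
                if ns in self.roots:
                    raise OntologyError(
                        f"namespace {ns} has several roots: "
                        f"{self.roots[ns]!r}, {t!r}"
                    )
                self.roots[ns] = t
        for ns in {self.namespace[t] for t in self.terms}:
            if ns not in self.roots:  # pragma: no cover - acyclic => has a root
                raise OntologyError(f"namespace {ns} has no root")

    def ancestors(self, term: str) -> frozenset[str]:
        """``term`` plus all transitive is_a parents."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, ps in self.parents.items():
            for p in ps:
                children[p].add(c)
        out = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for c in children[t]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return frozenset(out)

    # ----------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child_id\tparent_id\tnamespace\n")
            for t in sorted(self.terms):
                ps = sorted(self.parents.get(t, ()))
                if not ps:
                    fh.write(f"{t}\t\t{self.namespace[t]}\n")
                for p in ps:
                    fh.write(f"{t}\t{p}\t{self.namespace[t]}\n")


def _load_dag_tsv(path: str | Path) -> OntologyDAG:
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("child_id"):
            raise OntologyError("DAG TSV must start with a child_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            child, parent, ns = line.split("\t")
            namespace[child] = ns
            parents.setdefault(child, set())
            if parent:
                parents[child].add(parent)
                namespace.setdefault(parent, ns)
    return OntologyDAG(parents, namespace)


def _load_dag_obo(path: str | Path) -> OntologyDAG:
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    part_of: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    default_ns = None
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise OntologyError(f"OBO term {term} lacks a namespace")
        namespace[term] = ns
        parents.setdefault(term, set())
        part_of.setdefault(term, set())
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
        elif key == "part_of":
            part_of[child].add(parent)
    return OntologyDAG(parents, namespace, part_of=part_of)


def load_dag(path: str | Path) -> OntologyDAG:
    """Load a DAG from child-parent TSV or an OBO 1.2 file."""
    p = Path(path)
    if p.suffix.lower() == ".obo":
        return _load_dag_obo(p)
    with open(p, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("format-version") or first.startswith("[Term]"):
        return _load_dag_obo(p)
    return _load_dag_tsv(p)


def expand_positives(
    dag: OntologyDAG, positives: Iterable[str], mode: str = "ancestors"
) -> set[str]:
    """Hierarchy closure of the positives, namespace roots excluded.

    ``mode='ancestors'`` applies the true-path rule (a drug affecting a
    specific process also affects its more general parents);
    ``mode='descendants'`` closes downwards instead.
    """
    if mode not in ("ancestors", "descendants"):
        raise ValueError(f"unknown expansion mode {mode!r}")
    closure: set[str] = set()
    for t in positives:
        if t not in dag.terms:
            raise KeyError(f"unknown term {t!r}")
        closure |= dag.ancestors(t) if mode == "ancestors" else dag.descendants(t)
    return closure - set(dag.roots.values())


def zero_similarity(dag: OntologyDAG, a: str, b: str) -> bool:
    """True iff the two terms share only one ancestor (the namespace root)."""
    if dag.namespace[a] != dag.namespace[b]:
        raise OntologyError(
            f"cross-namespace comparison: {a!r} ({dag.namespace[a]}) vs "
            f"{b!r} ({dag.namespace[b]})"
        )
    return len(dag.ancestors(a) & dag.ancestors(b)) == 1


def infer_negatives(dag: OntologyDAG, positives: Iterable[str]) -> set[str]:
    """Terms with zero topology similarity to every positive of a namespace.

    Only namespaces holding at least three positives contribute; namespace
    roots and the positives themselves are never returned.
    """
    pos = set(positives)
    for t in pos:
        if t not in dag.terms:
            raise KeyError(f"unknown term {t!r}")
    by_ns: dict[str, set[str]] = {}
    for t in pos:
        by_ns.setdefault(dag.namespace[t], set()).add(t)
    negatives: set[str] = set()
    roots = set(dag.roots.values())
    for ns, ns_pos in by_ns.items():
        if len(ns_pos) < MIN_POSITIVES_PER_NAMESPACE:
            continue
        pos_anc = [dag.ancestors(p) for p in sorted(ns_pos)]
        for t in dag.terms:
            if dag.namespace[t] != ns or t in pos or t in roots:
                continue
            t_anc = dag.ancestors(t)
            if all(len(t_anc & pa) == 1 for pa in pos_anc):
                negatives.add(t)
    return negatives


@dataclass
class DrugCase:
    """Targets, indications and labelled example functions for one drug."""

    drug_id: str
    targets: frozenset[str]
    indications: frozenset[str]
    positives: frozenset[str]
    negatives: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
        self.indications = frozenset(self.indications)
        self.positives = frozenset(self.positives)
        self.negatives = frozenset(self.negatives)
        if not self.targets:
            raise ValueError("a drug case needs at least one target")
        if not self.indications:
            raise ValueError("a drug case needs at least one indication")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "drug_id": self.drug_id,
            "targets": sorted(self.targets),
            "indications": sorted(self.indications),
            "positives": sorted(self.positives),
            "negatives": sorted(self.negatives),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(
        cls, path: str | Path, dag: OntologyDAG | None = None
    ) -> "DrugCase":
        """Load a case; if negatives are absent they are inferred from ``dag``."""
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        negatives = doc.get("negatives")
        if not negatives:
            if dag is None:
                raise ValueError(
                    "drug case lists no negative examples; provide an ontology "
                    "DAG so they can be inferred, or list them explicitly"
                )
            negatives = sorted(infer_negatives(dag, doc["positives"]))
        return cls(
            drug_id=doc["drug_id"],
            targets=frozenset(doc["targets"]),
            indications=frozenset(doc["indications"]),
            positives=frozenset(doc["positives"]),
            negatives=frozenset(negatives),
        )
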