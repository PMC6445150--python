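"""Seeded generators for networks, ontologies and drug cases.

These stand in for the curated multi-level network (molecule/function/
phenotype nodes; protein interaction, annotation and disease-association
edges) so that every pipeline stage can be exercised without external
downloads.  A generated drug case plants a signal: positive example
functions (and a few unlabelled "planted" candidates) are preferentially
wired to the drug's targets via a target-side signal meta-path
(PPI then annotation) and to its indications via a direct
function-disease edge, while negatives and the remaining candidates are
wired at a background rate only.  The ground truth of which unlabelled
functions carry signal is returned for benchmarking.

All generators are deterministic functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .hetnet import (
    FUNCTION,
    MOLECULE,
    PHENOTYPE,
    HeteroNetwork,
    NetworkSchema,
    SchemaRelation,
)
from .ontology import DrugCase, OntologyDAG

PPI = "sim|PPI|undirected_link"
REGULATION = "sim|Regulation|directed_link"
ANNOTATION = "sim|Annotation|undirected_link"
COFUNCTION = "sim|CoFunction|undirected_link"
FUNCTION_DISEASE = "sim|FunctionDisease|undirected_link"
COMORBIDITY = "sim|Comorbidity|undirected_link"

GENERATOR_VERSION = "funact-sim-1"

#: target-side and indication-side meta-paths along which signal is planted
SIGNAL_TARGET_METAPATH = f"M-[{PPI}]-M-[{ANNOTATION}]-F"
SIGNAL_INDICATION_METAPATH = f"F-[{FUNCTION_DISEASE}]-P"


def synthetic_schema() -> NetworkSchema:
    """A compact six-relation schema: one per node-type pair + a directed M->M."""
    return NetworkSchema(
        [
            SchemaRelation(PPI, MOLECULE, MOLECULE, directed=False),
            SchemaRelation(REGULATION, MOLECULE, MOLECULE, directed=True),
            SchemaRelation(ANNOTATION, MOLECULE, FUNCTION, directed=False),
            SchemaRelation(COFUNCTION, FUNCTION, FUNCTION, directed=False),
            SchemaRelation(FUNCTION_DISEASE, FUNCTION, PHENOTYPE, directed=False),
            SchemaRelation(COMORBIDITY, PHENOTYPE, PHENOTYPE, directed=False),
        ]
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark.

    The case sizes (20 positives, 20 negatives, 100 candidates with 5 planted
    true functions) and wiring probabilities (signal 0.9 vs background 0.05)
    are the benchmark's standard conditions; the network sizes are chosen so
    background paths exist without saturating connectivity (mean PPI degree
    = 4, roughly one annotation per molecule).
    """

    n_molecules: int = 60
    n_functions: int = 140
    n_phenotypes: int = 30
    edge_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            PPI: 120,
            REGULATION: 40,
            ANNOTATION: 120,
            COFUNCTION: 80,
            FUNCTION_DISEASE: 60,
            COMORBIDITY: 40,
        }
    )
    n_targets: int = 2
    n_indications: int = 2
    n_positives: int = 20
    n_negatives: int = 20
    n_candidates: int = 100
    n_planted: int = 5
    signal: float = 0.9
    background: float = 0.05
    dag_terms: Mapping[str, int] = field(
        default_factory=lambda: {"biological_process": 40, "molecular_function": 15}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.signal, self.background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("wiring probabilities must lie in [0, 1]")
        if self.signal < self.background:
            raise ValueError("signal strength must be >= background rate")
        if self.n_planted > self.n_candidates:
            raise ValueError("cannot plant more functions than candidates")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one integer seed, deterministic per-component streams
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _node_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_network(config: SimConfig) -> tuple[HeteroNetwork, NetworkSchema]:
    """A random typed network with exactly the configured node/edge counts."""
    schema = synthetic_schema()
    net = HeteroNetwork(schema)
    pools = {
        MOLECULE: _node_ids("M", config.n_molecules),
        FUNCTION: _node_ids("F", config.n_functions),
        PHENOTYPE: _node_ids("P", config.n_phenotypes),
    }
    for t, ids in pools.items():
        for nid in ids:
            net.add_node(nid, t)
    rng = _rng(config, 0)
    for rel in schema:
        count = int(config.edge_counts.get(rel.name, 0))
        if count == 0:
            continue
        src_pool = pools[rel.src_type]
        dst_pool = pools[rel.dst_type]
        if rel.src_type == rel.dst_type:
            max_pairs = len(src_pool) * (len(src_pool) - 1)
            if not rel.directed:
                max_pairs //= 2
        else:
            max_pairs = len(src_pool) * len(dst_pool)
        if count > max_pairs:
            raise ValueError(
                f"{rel.name}: {count} edges requested but only "
                f"{max_pairs} distinct pairs exist"
            )
        added = 0
        while added < count:
            u = src_pool[int(rng.integers(len(src_pool)))]
            v = dst_pool[int(rng.integers(len(dst_pool)))]
            if u == v:
                continue
            if net.add_edge(u, rel.name, v):
                added += 1
    return net, schema


@dataclass
class SimDrugCase:
    """A generated drug case plus the planted-signal ground truth."""

    case: DrugCase
    planted: frozenset[str]
    candidates: tuple[str, ...]
    signal_target_metapath: str = SIGNAL_TARGET_METAPATH
    signal_indication_metapath: str = SIGNAL_INDICATION_METAPATH
    generator_version: str = GENERATOR_VERSION


def generate_drug_case(
    network: HeteroNetwork, config: SimConfig
) -> tuple[HeteroNetwork, SimDrugCase]:
    """Plant a drug case into (a copy of) the network.

    Positives and planted candidates are wired to every target with
    probability ``signal`` via target--PPI--intermediate--annotation--function
    and to every indication directly; negatives and remaining candidates use
    the ``background`` probability.  Returns the augmented network and the
    case with ground truth.
    """
    rng = _rng(config, 1)
    net = network.copy()
    molecules = net.nodes_of_type(MOLECULE)
    functions = net.nodes_of_type(FUNCTION)
    phenotypes = net.nodes_of_type(PHENOTYPE)
    if len(functions) < config.n_positives + config.n_negatives + config.n_candidates:
        raise ValueError("not enough function nodes for the requested case")
    targets = [molecules[i] for i in rng.choice(len(molecules), config.n_targets, replace=False)]
    indications = [
        phenotypes[i]
        for i in rng.choice(len(phenotypes), config.n_indications, replace=False)
    ]
    perm = rng.permutation(len(functions))
    pos = [functions[i] for i in perm[: config.n_positives]]
    neg = [
        functions[i]
        for i in perm[config.n_positives : config.n_positives + config.n_negatives]
    ]
    cand = [
        functions[i]
        for i in perm[
            config.n_positives
            + config.n_negatives : config.n_positives
            + config.n_negatives
            + config.n_candidates
        ]
    ]
    planted = cand[: config.n_planted]

    def wire(function_id: str, p: float) -> None:
        for t in targets:
            if rng.random() < p:
                m = t
                while m == t:
                    m = molecules[int(rng.integers(len(molecules)))]
                net.add_edge(t, PPI, m)
                net.add_edge(m, ANNOTATION, function_id)
        for ind in indications:
            if rng.random() < p:
                net.add_edge(function_id, FUNCTION_DISEASE, ind)

    for f in pos:
        wire(f, config.signal)
    for f in planted:
        wire(f, config.signal)
    for f in neg:
        wire(f, config.background)
    for f in cand[config.n_planted :]:
        wire(f, config.background)

    case = DrugCase(
        drug_id=f"simdrug-{config.seed}",
        targets=frozenset(targets),
        indications=frozenset(indications),
        positives=frozenset(pos),
        negatives=frozenset(neg),
    )
    return net, SimDrugCase(
        case=case, planted=frozenset(planted), candidates=tuple(cand)
    )


def generate_dag(config: SimConfig) -> OntologyDAG:
    """A random rooted DAG per namespace; every non-root term gets 1-2 parents."""
    rng = _rng(config, 2)
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    for ns_i, (ns, n_terms) in enumerate(sorted(config.dag_terms.items())):
        if n_terms < 1:
            raise ValueError(f"namespace {ns} needs at least a root term")
        ids = [f"GO:{ns_i + 1}{i:06d}" for i in range(n_terms)]
        namespace.update({t: ns for t in ids})
        parents[ids[0]] = set()  # root
        for i in range(1, n_terms):
            k = 1 + int(rng.random() < 0.4 and i > 1)
            picks = rng.choice(i, size=min(k, i), replace=False)
            parents[ids[i]] = {ids[int(j)] for j in picks}
    return OntologyDAG(parents, namespace)
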