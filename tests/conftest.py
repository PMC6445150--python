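import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from funact.hetnet import (
    FUNCTION,
    MOLECULE,
    PHENOTYPE,
    HeteroNetwork,
    NetworkSchema,
    SchemaRelation,
)

PPI = "sim|PPI|undirected_link"
REG = "sim|Regulation|directed_link"
ANNOT = "sim|Annotation|undirected_link"


@pytest.fixture
def tiny_schema():
    return NetworkSchema(
        [
            SchemaRelation(PPI, MOLECULE, MOLECULE, directed=False),
            SchemaRelation(REG, MOLECULE, MOLECULE, directed=True),
            SchemaRelation(ANNOT, MOLECULE, FUNCTION, directed=False),
        ]
    )


@pytest.fixture
def two_path_network(tiny_schema):
    """One target reaching f1 via two intermediate molecules, f2 via none.

    The molecule-molecule-function meta-path (interaction then annotation)
    yields exactly two paths from the target to f1 and zero to f2, although
    both functions sit at the same shortest distance from the target.
    """
    net = HeteroNetwork(tiny_schema)
    for nid, t in {
        "ace": MOLECULE,
        "mA": MOLECULE,
        "mB": MOLECULE,
        "mC": MOLECULE,
        "f1": FUNCTION,
        "f2": FUNCTION,
    }.items():
        net.add_node(nid, t)
    net.add_edge("ace", PPI, "mA")
    net.add_edge("ace", PPI, "mB")
    net.add_edge("ace", PPI, "mC")
    net.add_edge("mA", ANNOT, "f1")
    net.add_edge("mB", ANNOT, "f1")
    net.add_edge("ace", ANNOT, "f2")  # f2 reachable, but not via the M-M-F route
    return net
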