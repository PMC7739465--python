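"""Shared fixtures: a small cellular-component hierarchy, toy OBO text,
and random-DAG helpers used by the property tests."""

import numpy as np
import pytest

from gogcn.ontology import OntologyGraph


@pytest.fixture
def cc_graph():
    """Plasma-membrane fragment of the cellular-component hierarchy.

    GO:0005886 (plasma membrane) sits under cell periphery (GO:0071944)
    and membrane (GO:0016020), which roll up through cell part
    (GO:0044464) and cell (GO:0005623) to the CC root (GO:0005575); its
    ancestor closure is exactly those five terms.
    """
    edges = {
        ("GO:0005623", "GO:0005575", "is_a"),  # cell -> cellular_component
        ("GO:0044464", "GO:0005623", "is_a"),  # cell part -> cell
        ("GO:0044464", "GO:0005575", "is_a"),
        ("GO:0016020", "GO:0044464", "is_a"),  # membrane -> cell part
        ("GO:0071944", "GO:0044464", "is_a"),  # cell periphery -> cell part
        ("GO:0005886", "GO:0071944", "is_a"),  # plasma membrane
        ("GO:0005886", "GO:0016020", "is_a"),
    }
    terms = {t for e in edges for t in e[:2]}
    return OntologyGraph(
        terms=terms, edges=edges, namespace={t: "CC" for t in terms}
    )


FIG1_ANCESTORS = {
    "GO:0071944",
    "GO:0044464",
    "GO:0005623",
    "GO:0016020",
    "GO:0005575",
}


@pytest.fixture
def toy_obo(tmp_path):
    """Three-stanza OBO: root, child, and an obsolete term; one alt_id."""
    text = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process
alt_id: GO:0000002

[Term]
id: GO:0000003
name: child
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_obsolete: true
"""
    path = tmp_path / "toy.obo"
    path.write_text(text)
    return path


def random_dag(rng, n_nodes=None, p=0.3):
    """Random DAG via an ordered node list; edges only point to earlier
    nodes, so acyclicity holds by construction."""
    if n_nodes is None:
        n_nodes = int(rng.integers(2, 31))
    terms = [f"GO:{i + 1:07d}" for i in range(n_nodes)]
    edges = set()
    for i in range(1, n_nodes):
        parents = [j for j in range(i) if rng.random() < p]
        if not parents:
            parents = [int(rng.integers(0, i))]
        for j in parents:
            edges.add((terms[i], terms[j], "is_a"))
    return OntologyGraph(
        terms=set(terms), edges=edges, namespace={t: "BP" for t in terms}
    )
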