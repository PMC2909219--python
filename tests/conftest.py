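"""Shared fixtures: small constructed scenarios used across test modules."""

from __future__ import annotations

import networkx as nx
import pytest

from matescaf.layout import ContigPlacement, ScaffoldLayout


@pytest.fixture
def fused_scaffolds():
    """Two 4-contig scaffolds fused by one chimeric contig.

    The chimera ``X`` carries the third contig of the "green" chain
    (g1-g2-X-g4) and the third of the "magenta" chain (m5-m6-X-m8); an extra
    overarching mate-pair edge links m6 and m8 directly.  Positions are the
    spring-consistent solution, which lays the two true scaffolds on top of
    each other (density about 2) with the chimera covering once in between.
    Returns (layout, graph, chimera_id, insert_size).
    """
    length = 2000
    placements = [
        ContigPlacement("g1", 1, 0, length),
        ContigPlacement("m5", 1, 2000, length),
        ContigPlacement("g2", 1, 2200, length),
        ContigPlacement("m6", 1, 4200, length),
        ContigPlacement("X", 1, 4400, 2 * length),
        ContigPlacement("g4", 1, 8600, length),
        ContigPlacement("m8", 1, 8600, length),
    ]
    graph = nx.Graph()
    graph.add_nodes_from(p.contig_id for p in placements)
    edges = [
        ("g1", "g2"), ("g2", "X"), ("X", "g4"),
        ("m5", "m6"), ("m6", "X"), ("X", "m8"),
        ("m6", "m8"),  # overarching pair
    ]
    for a, b in edges:
        graph.add_edge(a, b, J=10)
    return ScaffoldLayout("fused", placements), graph, "X", 2000.0
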