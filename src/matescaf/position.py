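"""Contig positioning: weighted least squares on a spring network.

After orientation assignment, each retained, orientation-consistent edge
(i, j) behaves as a spring of stiffness |J_ij| attached to the contig start
coordinates, with relaxed length equal to the mean suggested separation
d_ij.  Maximizing the Gaussian likelihood of the pair separations is the
same as minimizing

    sum_edges |J_ij| * ((x_j - x_i) - d_ij)^2

whose minimizer solves the force-balance linear system (a weighted graph
Laplacian).  One vertex per connected component is anchored at x = 0 to fix
the translation freedom.  The per-edge residual Delta_ij = |(x_j - x_i) -
d_ij| measures how stretched or compressed a spring is: a large residual
flags mutually inconsistent constraints (repeats, chimeras), whose endpoint
contigs are removed before the pipeline loops back to orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["PositionSolution", "solve_spring", "prune_stretched"]


@dataclass
class PositionSolution:
    positions: dict[str, float]
    residuals: dict[tuple[str, str], float]  # keyed (a, b) with a < b
    weights: dict[tuple[str, str], float]
    sigma: float


def solve_spring(
    edges: list[tuple[str, str, float, float]],
    sigma: float = 1.0,
) -> PositionSolution:
    """Equilibrium positions for one connected spring component.

    ``edges`` holds (a, b, weight, dbar) with dbar the relaxed length of the
    spring in the direction a -> b (target x_b - x_a).  The lowest-named
    vertex is anchored at 0.  Raises on a disconnected system — the caller
    splits components first.
    """
    if not edges:
        raise ValueError("no edges to solve")
    nodes = sorted({v for a, b, _, _ in edges for v in (a, b)})
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from((a, b) for a, b, _, _ in edges)
    if not nx.is_connected(graph):
        raise ValueError("spring system is disconnected; solve per component")
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    rhs = np.zeros(n)
    for a, b, w, d in edges:
        i, j = index[a], index[b]
        lap[i, i] += w
        lap[j, j] += w
        lap[i, j] -= w
        lap[j, i] -= w
        rhs[i] -= w * d
        rhs[j] += w * d
    # anchor the first vertex at 0: drop its row/column
    x = np.zeros(n)
    if n > 1:
        x[1:] = np.linalg.solve(lap[1:, 1:], rhs[1:])
    positions = {v: float(x[index[v]]) for v in nodes}
    residuals: dict[tuple[str, str], float] = {}
    weights: dict[tuple[str, str], float] = {}
    for a, b, w, d in edges:
        key = (a, b) if a < b else (b, a)
        signed = d if a < b else -d
        residuals[key] = abs((positions[key[1]] - positions[key[0]]) - signed)
        weights[key] = w
    return PositionSolution(positions, residuals, weights, sigma)


def prune_stretched(
    solution: PositionSolution,
    k: float = 5.0,
) -> tuple[list[str], tuple[str, str] | None]:
    """Contigs to remove because of the worst over-threshold spring.

    The threshold for edge (i, j) is k * sigma / sqrt(|J_ij|): the standard
    deviation of a mean of |J| independent pair separations, times a safety
    factor.  Among edges exceeding it, the one with the largest
    residual-to-threshold ratio is the worst; both its endpoint contigs are
    removed (the pipeline then re-runs orientation on the remainder).
    Returns ([], None) when every spring is within threshold.
    """
    worst, worst_ratio = None, 1.0
    for edge, delta in sorted(solution.residuals.items()):
        w = solution.weights[edge]
        threshold = k * solution.sigma / np.sqrt(w)
        if threshold <= 0:
            continue
        ratio = delta / threshold
        if ratio > worst_ratio:
            worst, worst_ratio = edge, ratio
    if worst is None:
        return [], None
    return sorted(worst), worst
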