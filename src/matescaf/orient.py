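"""Contig orientation assignment: ground state of an Ising model.

Each contig carries a spin S_i in {+1, -1}; the mate-pair links between
contigs i and j aggregate into a signed coupling J_ij, and the assignment
minimizes E[S] = -sum_ij J_ij S_i S_j, i.e. satisfies as many orientation
constraints as possible (a maximum-weight-cut instance, NP-complete in
general).

The scaffolding graph is nearly linear, which two structural tricks exploit:

* articulation vertices with more than two neighbors split the graph into
  components that can be solved independently (each child keeps a copy of
  the vertex; the E[S] = E[-S] degeneracy lets the copies be aligned when
  merging), and
* breadth-first layering of a component puts every edge within a layer or
  between adjacent layers, so when all layers are small an exact
  Viterbi-style sweep over the 2^|Z_k| layer states finds the true minimum.

Components with large layers fall back to Metropolis simulated annealing
with an exponential cooling schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np

__all__ = [
    "OrientationAssignment",
    "AnnealSchedule",
    "split_nonreducible",
    "layer_sets",
    "solve_dp",
    "solve_sa",
    "solve_component",
    "assign_orientations",
    "ising_energy",
]


@dataclass(frozen=True)
class AnnealSchedule:
    """Exponential cooling schedule for Metropolis annealing.

    ``t0_factor`` scales the initial temperature off the largest coupling;
    ``alpha`` is the per-sweep cooling factor; annealing stops when the best
    energy has not improved for ``plateau`` sweeps or T drops below
    ``t_floor``.
    """

    t0_factor: float = 2.0
    alpha: float = 0.999
    plateau: int = 50
    t_floor: float = 1e-3
    max_sweeps: int = 20000


@dataclass
class OrientationAssignment:
    orientations: dict[str, int]
    energy: float
    energy_min: float  # -sum |J|, reached iff every link is satisfiable
    violated_edges: list[tuple[str, str]] = field(default_factory=list)


def ising_energy(graph: nx.Graph, spins: dict[str, int]) -> float:
    return -sum(d["J"] * spins[a] * spins[b] for a, b, d in graph.edges(data=True))


def _canonicalize(graph: nx.Graph, spins: dict[str, int]) -> dict[str, int]:
    """Fix the global-flip degeneracy: lowest-indexed vertex gets S = +1."""
    anchor = min(spins)
    if spins[anchor] == -1:
        return {v: -s for v, s in spins.items()}
    return dict(spins)


def split_nonreducible(graph: nx.Graph):
    """Split at articulation vertices of degree > 2 into non-reducible parts.

    Yields (component_subgraph, articulation_vertex) pairs depth-first; the
    articulation vertex is the copy shared with the parent (None for the
    root component).  Degree-2 articulation vertices are part of linear
    chains the exact solvers already handle, so they are not split.
    """
    out = []

    def recurse(g: nx.Graph, shared):
        arts = sorted(
            v for v in nx.articulation_points(g) if g.degree[v] > 2
        )
        if not arts:
            out.append((g, shared))
            return
        v = arts[0]
        rest = g.copy()
        rest.remove_node(v)
        for comp in sorted(nx.connected_components(rest), key=min):
            child = g.subgraph(comp | {v}).copy()
            recurse(child, v)

    recurse(graph, None)
    return out


def layer_sets(graph: nx.Graph, start: str | None = None) -> list[list[str]]:
    """BFS layering Z_1..Z_K: edges stay within or between adjacent layers.

    The default start vertex is the minimum-degree vertex (ties by name),
    which keeps layers small on near-linear graphs.
    """
    if start is None:
        start = min(graph.nodes, key=lambda v: (graph.degree[v], v))
    layers = [[start]]
    seen = {start}
    while True:
        frontier = sorted(
            {
                u
                for v in layers[-1]
                for u in graph.neighbors(v)
                if u not in seen
            }
        )
        if not frontier:
            break
        seen.update(frontier)
        layers.append(frontier)
    if len(seen) != graph.number_of_nodes():
        raise ValueError("layer_sets requires a connected component")
    return layers


class LayerTooLarge(Exception):
    """Signals the caller to fall back to simulated annealing."""


def solve_dp(graph: nx.Graph, layer_cap: int = 6) -> OrientationAssignment:
    """Exact minimum by a Viterbi sweep over BFS-layer states.

    Each layer Z_k contributes 2^|Z_k| states; the DP keeps, per state, the
    best energy of the prefix and a backpointer.  Raises LayerTooLarge when
    a layer exceeds ``layer_cap``.
    """
    layers = layer_sets(graph)
    if max(len(z) for z in layers) > layer_cap:
        raise LayerTooLarge(max(len(z) for z in layers))

    def intra(vertices, state) -> float:
        spin = dict(zip(vertices, state))
        e = 0.0
        for a, b, d in graph.subgraph(vertices).edges(data=True):
            e -= d["J"] * spin[a] * spin[b]
        return e

    def inter(prev_v, prev_s, cur_v, cur_s) -> float:
        spin = dict(zip(prev_v, prev_s))
        spin.update(zip(cur_v, cur_s))
        e = 0.0
        for v in cur_v:
            for u in graph.neighbors(v):
                if u in spin and u not in cur_v:
                    e -= graph.edges[u, v]["J"] * spin[u] * spin[v]
        return e

    states = [list(product((1, -1), repeat=len(z))) for z in layers]
    best = {s: intra(layers[0], s) for s in states[0]}
    back: list[dict] = []
    for k in range(1, len(layers)):
        cur_best, cur_back = {}, {}
        for s in states[k]:
            node_e = intra(layers[k], s)
            choice, choice_e = None, np.inf
            for p in states[k - 1]:
                e = best[p] + inter(layers[k - 1], p, layers[k], s)
                if e < choice_e:
                    choice, choice_e = p, e
            cur_best[s] = choice_e + node_e
            cur_back[s] = choice
        best, back = cur_best, back + [cur_back]

    end = min(best, key=lambda s: (best[s], s))
    energy = best[end]
    assignment: dict[str, int] = {}
    state = end
    for k in range(len(layers) - 1, -1, -1):
        assignment.update(zip(layers[k], state))
        if k > 0:
            state = back[k - 1][state]
    spins = _canonicalize(graph, assignment)
    emin = -sum(abs(d["J"]) for _, _, d in graph.edges(data=True))
    return OrientationAssignment(spins, energy, emin, _violations(graph, spins))


def solve_sa(
    graph: nx.Graph,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> OrientationAssignment:
    """Metropolis single-flip annealing from the all-+1 start.

    Heuristic: tracks and returns the best configuration seen.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    neighbors = [
        [(index[u], graph.edges[v, u]["J"]) for u in graph.neighbors(v)]
        for v in nodes
    ]
    spins = np.ones(n, dtype=np.int64)
    energy = ising_energy(graph, dict(zip(nodes, spins)))
    best_spins, best_energy = spins.copy(), energy
    max_j = max((abs(d["J"]) for _, _, d in graph.edges(data=True)), default=1.0)
    t0 = schedule.t0_factor * max_j
    temperature = t0
    since_improvement = 0
    for _ in range(schedule.max_sweeps):
        picks = rng.integers(0, n, size=n)
        accepts = rng.random(n)
        for v, u_rand in zip(picks, accepts):
            # flipping v changes E by 2 * sum_j J_vj S_v S_j
            local = sum(j * spins[u] for u, j in neighbors[v])
            delta = 2.0 * spins[v] * local
            if delta <= 0 or u_rand < np.exp(-delta / temperature):
                spins[v] = -spins[v]
                energy += delta
        if energy < best_energy - 1e-12:
            best_energy, best_spins = energy, spins.copy()
            since_improvement = 0
        else:
            since_improvement += 1
        temperature *= schedule.alpha
        # the plateau criterion is meaningful only once the walk has cooled;
        # at high T the best-seen energy rarely moves even far from optimum
        cooled = temperature < 0.05 * t0
        if (cooled and since_improvement >= schedule.plateau) or (
            temperature < schedule.t_floor
        ):
            break
    assignment = _canonicalize(graph, dict(zip(nodes, (int(s) for s in best_spins))))
    emin = -sum(abs(d["J"]) for _, _, d in graph.edges(data=True))
    return OrientationAssignment(
        assignment, best_energy, emin, _violations(graph, assignment)
    )


def _violations(graph: nx.Graph, spins: dict[str, int]) -> list[tuple[str, str]]:
    return sorted(
        (a, b) if a < b else (b, a)
        for a, b, d in graph.edges(data=True)
        if np.sign(d["J"]) != spins[a] * spins[b]
    )


def solve_component(
    graph: nx.Graph,
    layer_cap: int = 6,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> OrientationAssignment:
    """Solve one connected component: decompose, DP where layers fit, else SA.

    Children of each articulation split are solved independently and merged
    in reverse split order: each child keeps a copy of the articulation
    vertex, and the E[S] = E[-S] degeneracy of a whole child lets its copy
    be aligned with the others.  The merge must follow the split tree
    bottom-up — a flat merge can leave a part constrained by two earlier
    copies at once.
    """

    def solve(g: nx.Graph) -> dict[str, int]:
        arts = sorted(v for v in nx.articulation_points(g) if g.degree[v] > 2)
        if not arts:
            try:
                return dict(solve_dp(g, layer_cap).orientations)
            except LayerTooLarge:
                return dict(solve_sa(g, schedule, seed).orientations)
        v = arts[0]
        rest = g.copy()
        rest.remove_node(v)
        merged: dict[str, int] = {}
        for comp in sorted(nx.connected_components(rest), key=min):
            child = solve(g.subgraph(comp | {v}).copy())
            if merged and child[v] != merged[v]:
                child = {u: -s for u, s in child.items()}
            merged.update(child)
        return merged

    spins = _canonicalize(graph, solve(graph))
    energy = ising_energy(graph, spins)
    emin = -sum(abs(d["J"]) for _, _, d in graph.edges(data=True))
    return OrientationAssignment(spins, energy, emin, _violations(graph, spins))


def assign_orientations(
    graph: nx.Graph,
    layer_cap: int = 6,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> OrientationAssignment:
    """Orient every contig of (possibly disconnected) ``graph``.

    Components are solved independently; energies add.  Edges violated by
    the final assignment are reported so positioning can drop them.
    """
    spins: dict[str, int] = {}
    energy = 0.0
    for k, comp in enumerate(sorted(nx.connected_components(graph), key=min)):
        sub = graph.subgraph(comp).copy()
        res = solve_component(sub, layer_cap, schedule, seed + k)
        spins.update(res.orientations)
        energy += res.energy
    emin = -sum(abs(d["J"]) for _, _, d in graph.edges(data=True))
    return OrientationAssignment(spins, energy, emin, _violations(graph, spins))
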