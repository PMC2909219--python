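"""Tangled-scaffold detection and segmentation.

A valid scaffold covers each of its positions with exactly one contig (zero
in gaps).  When a chimeric contig or a collapsed repeat fuses several true
scaffolds, the positioning step lays them on top of each other and the
*density profile* — the windowed mean number of contigs covering each
scaffold position — shows plateaus near 2, 3, ...  The number of fused
scaffolds q follows from the plateau heights; contigs are then labeled by a
q-state Potts model whose energy

    E[sigma] = sum_{i<j} (w_O * O_ij - w_D * D_ij) * delta(sigma_i, sigma_j)

rewards mate-pair-connected contigs sharing a label (ferromagnetic, D_ij = 1
iff directly linked) and penalizes positionally overlapping contigs sharing
one (antiferromagnetic, O_ij grows with the overlap length).  Junctures sit
at label boundaries; removal subsets drawn from the boundary contigs are
scored and the best subset removed, recursing on components whose profile is
still overloaded.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .layout import ScaffoldLayout
from .orient import AnnealSchedule

__all__ = [
    "density_profile",
    "estimate_q",
    "potts_couplings",
    "potts_energy",
    "anneal_potts",
    "resolve_tangles",
]

HIGH_DENSITY = 1.5  # separates plateau 1 from plateau 2 robustly
MIN_RUN = 2  # windows a high-density run must sustain


def density_profile(layout: ScaffoldLayout, window: int = 1000) -> np.ndarray:
    """Windowed mean contig-coverage count along the scaffold."""
    if not layout.contigs:
        return np.zeros(0)
    lo = min(c.start for c in layout.contigs)
    hi = max(c.end for c in layout.contigs)
    span = int(np.ceil(hi - lo))
    if span <= 0:
        return np.zeros(0)
    cover = np.zeros(span + 1)
    for c in layout.contigs:
        a = int(round(c.start - lo))
        b = int(round(c.end - lo))
        cover[a] += 1
        cover[b] -= 1
    per_base = np.cumsum(cover[:-1])
    n_win = int(np.ceil(span / window))
    profile = np.zeros(n_win)
    for w in range(n_win):
        profile[w] = per_base[w * window : (w + 1) * window].mean()
    return profile


def _high_runs(profile: np.ndarray, threshold: float, min_run: int):
    runs = []
    start = None
    for i, v in enumerate(profile):
        if v >= threshold and start is None:
            start = i
        elif v < threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(profile)))
    return [(a, b) for a, b in runs if b - a >= min_run]


def estimate_q(
    profile: np.ndarray,
    threshold: float = HIGH_DENSITY,
    min_run: int = MIN_RUN,
) -> int:
    """Number of distinct scaffold labels implied by the density profile.

    Each sustained high-density run contributes (rounded peak - 1) extra
    labels on top of the background single scaffold; e.g. runs peaking at 3
    and 2 imply q = 1 + 2 + 1 = 4.  A clean profile gives q = 1.
    """
    q = 1
    for a, b in _high_runs(profile, threshold, min_run):
        q += max(0, int(round(profile[a:b].max())) - 1)
    return q


def potts_couplings(
    layout: ScaffoldLayout,
    graph: nx.Graph,
    w_d: float = 1.0,
    w_o: float = 1.0,
) -> dict[tuple[str, str], float]:
    """Pairwise label couplings w_O*O_ij - w_D*D_ij for the layout's contigs.

    O_ij is the positional overlap length normalized by the mean contig
    length (monotone in the overlap); D_ij is 1 iff the contigs are directly
    linked by mate pairs.  Only nonzero couplings are returned, keyed with
    i < j.
    """
    contigs = layout.contigs
    mean_len = float(np.mean([c.length for c in contigs])) or 1.0
    couplings: dict[tuple[str, str], float] = {}
    for ca, cb in combinations(contigs, 2):
        key = tuple(sorted((ca.contig_id, cb.contig_id)))
        overlap = min(ca.end, cb.end) - max(ca.start, cb.start)
        o_ij = max(0.0, overlap) / mean_len
        d_ij = 1.0 if graph.has_edge(ca.contig_id, cb.contig_id) else 0.0
        value = w_o * o_ij - w_d * d_ij
        if value != 0.0:
            couplings[key] = value
    return couplings


def potts_energy(
    couplings: dict[tuple[str, str], float], labels: dict[str, int]
) -> float:
    return sum(
        w for (a, b), w in couplings.items() if labels[a] == labels[b]
    )


def anneal_potts(
    couplings: dict[tuple[str, str], float],
    nodes: list[str],
    q: int,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> dict[str, int]:
    """Metropolis annealing of the q-state Potts labels; best seen returned.

    Starts from a uniform random label assignment; each move re-labels a
    randomly chosen contig with a randomly chosen new label.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = sorted(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    neighbors: list[list[tuple[int, float]]] = [[] for _ in nodes]
    for (a, b), w in couplings.items():
        neighbors[index[a]].append((index[b], w))
        neighbors[index[b]].append((index[a], w))
    labels = rng.integers(0, q, size=n)
    energy = sum(
        w for (a, b), w in couplings.items()
        if labels[index[a]] == labels[index[b]]
    )
    best_labels, best_energy = labels.copy(), energy
    max_w = max((abs(w) for w in couplings.values()), default=1.0)
    t0 = schedule.t0_factor * max_w
    temperature = t0
    since = 0
    for _ in range(schedule.max_sweeps):
        picks = rng.integers(0, n, size=n)
        news = rng.integers(0, q, size=n)
        us = rng.random(n)
        for v, new, u in zip(picks, news, us):
            old = labels[v]
            if new == old:
                continue
            delta = 0.0
            for j, w in neighbors[v]:
                if labels[j] == new:
                    delta += w
                elif labels[j] == old:
                    delta -= w
            if delta <= 0 or u < np.exp(-delta / temperature):
                labels[v] = new
                energy += delta
        if energy < best_energy - 1e-12:
            best_energy, best_labels = energy, labels.copy()
            since = 0
        else:
            since += 1
        temperature *= schedule.alpha
        # plateau stopping only once cooled (best-seen barely moves at high T)
        cooled = temperature < 0.05 * t0
        if (cooled and since >= schedule.plateau) or temperature < schedule.t_floor:
            break
    return {v: int(best_labels[index[v]]) for v in nodes}


def _component_score(
    components: list[ScaffoldLayout],
    n_removed: int,
    small_span: float,
    window: int,
    threshold: float,
) -> float:
    # removed contigs end up as singletons, i.e. the smallest components
    small = n_removed + sum(1 for comp in components if comp.span < small_span)
    hot = sum(
        int((density_profile(comp, window) >= threshold).sum())
        for comp in components
    )
    return small + 5 * hot


def _components_of(
    layout: ScaffoldLayout, graph: nx.Graph, removed: set[str]
) -> list[ScaffoldLayout]:
    keep = [c for c in layout.contigs if c.contig_id not in removed]
    sub = graph.subgraph({c.contig_id for c in keep})
    comps = []
    by_id = {c.contig_id: c for c in keep}
    for k, comp in enumerate(sorted(nx.connected_components(sub), key=min)):
        comps.append(
            ScaffoldLayout(
                f"{layout.name}.{k}", [by_id[cid] for cid in sorted(comp)]
            ).shifted()
        )
    return comps


def resolve_tangles(
    layout: ScaffoldLayout,
    graph: nx.Graph,
    insert_size: float,
    window: int = 1000,
    threshold: float = HIGH_DENSITY,
    subset_cap: int = 12,
    sample_size: int = 2000,
    schedule: AnnealSchedule = AnnealSchedule(),
    seed: int = 0,
) -> tuple[list[ScaffoldLayout], list[str]]:
    """Split a tangled scaffold into clean scaffolds by juncture removal.

    Returns (clean layouts, removed contig ids).  A layout whose profile
    shows no sustained high-density run is returned unchanged.  Otherwise
    the Potts labeling marks boundary contigs as juncture candidates;
    removal subsets are scored by (number of components spanning less than
    2x the insert size) + 5 * (number of remaining high-density windows),
    ties preferring smaller subsets then lexicographic order.  The search is
    exhaustive up to ``subset_cap`` candidates, then restricted to the
    densest run, then a seeded random sample.
    """
    profile = density_profile(layout, window)
    q = estimate_q(profile, threshold)
    if q < 2 or len(layout) < 3:
        return [layout.shifted()], []
    couplings = potts_couplings(layout, graph)
    labels = anneal_potts(couplings, layout.contig_ids(), q, schedule, seed)
    in_layout = set(layout.contig_ids())
    candidates = sorted(
        cid
        for cid in in_layout
        if any(
            labels.get(nb) is not None and labels[nb] != labels[cid]
            for nb in graph.neighbors(cid)
            if nb in in_layout
        )
    )
    if not candidates:
        return [layout.shifted()], []

    rng = np.random.default_rng(seed)
    if len(candidates) > subset_cap:
        # restrict to candidates overlapping the densest high-density run
        runs = _high_runs(profile, threshold, MIN_RUN)
        if runs:
            dense = max(runs, key=lambda r: profile[r[0] : r[1]].max())
            lo = min(c.start for c in layout.contigs) + dense[0] * window
            hi = min(c.start for c in layout.contigs) + dense[1] * window
            by_id = {c.contig_id: c for c in layout.contigs}
            narrowed = [
                cid
                for cid in candidates
                if by_id[cid].end > lo and by_id[cid].start < hi
            ]
            if narrowed:
                candidates = narrowed
    if len(candidates) <= subset_cap:
        subsets = [
            tuple(sorted(s))
            for r in range(len(candidates) + 1)
            for s in combinations(candidates, r)
        ]
    else:
        subsets = [()]
        for _ in range(sample_size):
            mask = rng.random(len(candidates)) < 0.5
            subsets.append(
                tuple(c for c, m in zip(candidates, mask) if m)
            )
        subsets = sorted(set(subsets))

    small_span = 2.0 * insert_size
    best_subset, best_key = None, None
    for subset in subsets:
        comps = _components_of(layout, graph, set(subset))
        score = _component_score(comps, len(subset), small_span, window, threshold)
        key = (score, len(subset), subset)
        if best_key is None or key < best_key:
            best_subset, best_key = subset, key
    removed = list(best_subset)
    clean: list[ScaffoldLayout] = []
    for comp in _components_of(layout, graph, set(removed)):
        if estimate_q(density_profile(comp, window), threshold) >= 2 and len(comp) > 2:
            sub_clean, sub_removed = resolve_tangles(
                comp, graph, insert_size, window, threshold,
                subset_cap, sample_size, schedule, seed + 1,
            )
            clean.extend(sub_clean)
            removed.extend(sub_removed)
        else:
            clean.append(comp)
    return clean, removed
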