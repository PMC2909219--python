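"""Mate pairs -> contig connectivity graph.

Every mate pair whose two reads landed on different contigs votes on the
relative orientation of those contigs (the parity of S_i * S_j) and suggests
a separation between their start coordinates.  Votes are aggregated per
contig pair into a signed link count J_ij (sign = dominant parity, magnitude
= number of retained links) after majority filtering: if the dominant parity
group holds less than the majority fraction of the links, the whole edge is
ignored; likewise edges carried by fewer than W links.  The retained pairs'
suggested separations average into the relaxed spring length d_ij used by the
positioning step.

Coordinate convention: x_i is the scaffold coordinate of the *start* of
contig i, S_i = +1 means the stored sequence reads left-to-right.  A read at
offset p on a contig of length M sits at scaffold-forward position
x_i + p (S_i = +1) or x_i + M - p - read_len (S_i = -1), and its scaffold
strand is tau * S_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model import ILLUMINA_PE, SOLID_MATE, Library, ReadPlacement

__all__ = ["PairConstraint", "pair_constraint", "build_graph", "edge_dbar", "to_dot"]


@dataclass(frozen=True)
class PairConstraint:
    """One mate pair's constraint between two contigs.

    ``parity`` is the expected sign of S_a * S_b.  ``offset_plus`` is the
    implied x_b - x_a when S_a = +1 (and hence S_b = parity); for the flipped
    choice the implied offset follows from reflecting the layout, which needs
    both contig lengths and the read length (kept here for that purpose).
    """

    contig_a: str
    contig_b: str
    parity: int
    offset_plus: float
    len_a: int
    len_b: int
    pair_id: str = ""

    def implied_offset(self, s_a: int) -> float:
        """x_b - x_a for the given orientation of contig a."""
        if s_a == +1:
            return self.offset_plus
        # global flip: x' = -(x + M)  =>  x'_b - x'_a = -(x_b - x_a) - M_b + M_a
        return -self.offset_plus + self.len_a - self.len_b


def pair_constraint(
    placement_r: ReadPlacement,
    placement_f: ReadPlacement,
    library: Library,
    len_a: int,
    len_b: int,
) -> PairConstraint:
    """Orientation parity and implied separation for a cross-contig pair.

    SOLiD mate pairs put both reads on the same strand (parity tau_R*tau_F);
    Illumina paired-ends put them on opposite strands (parity -tau_R*tau_F).
    The separation follows by placing both reads at their scaffold-forward
    coordinates and imposing start-of-right-read minus start-of-left-read =
    insert size, with the strand of R deciding which read is left.
    """
    if placement_r.contig_id == placement_f.contig_id:
        raise ValueError("same-contig pair: handled by preprocessing")
    tau_r, tau_f = placement_r.same_strand, placement_f.same_strand
    if library.kind == SOLID_MATE:
        parity = tau_r * tau_f
    elif library.kind == ILLUMINA_PE:
        parity = -tau_r * tau_f
    else:  # pragma: no cover
        raise ValueError(f"unknown library kind {library.kind!r}")

    rl = library.read_length
    s_a, s_b = +1, parity
    # read positions relative to x_a = x_b = 0 with the chosen orientations
    rel_r = placement_r.offset if s_a == +1 else len_a - placement_r.offset - rl
    rel_f = placement_f.offset if s_b == +1 else len_b - placement_f.offset - rl
    g = tau_r * s_a  # scaffold strand of the R read
    # g * ((x_b + rel_f) - (x_a + rel_r)) = insert
    offset_plus = g * library.insert + rel_r - rel_f
    return PairConstraint(
        placement_r.contig_id,
        placement_f.contig_id,
        parity,
        float(offset_plus),
        len_a,
        len_b,
        pair_id=placement_r.read_id,
    )


@dataclass
class IgnoredEdge:
    contig_a: str
    contig_b: str
    n_links: int
    reason: str


def build_graph(
    constraints: list[PairConstraint],
    contig_lengths: dict[str, int],
    min_links: int = 5,
    min_length: int = 150,
    majority_fraction: float = 0.7,
    max_sep_deviation: float | None = None,
) -> tuple[nx.Graph, list[IgnoredEdge]]:
    """Aggregate pair constraints into the contig connectivity graph.

    Contigs shorter than ``min_length`` are excluded.  Per edge, links are
    split by parity; if the dominant group's fraction reaches
    ``majority_fraction`` the minority links are dropped and J = +/- the
    dominant count, otherwise the whole edge is ignored.  When
    ``max_sep_deviation`` is set, links whose suggested separation deviates
    from the edge median by more than it are dropped as broad-background
    pairs (their separations are uniform over the genome rather than peaked
    at the insert size).  Edges left with |J| < ``min_links`` are ignored.
    Edge attributes: ``J`` (signed link count) and ``pairs`` (the retained
    constraints, oriented a < b).
    """
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    if not (0.5 < majority_fraction <= 1.0):
        raise ValueError("majority_fraction must lie in (0.5, 1]")
    by_edge: dict[tuple[str, str], list[PairConstraint]] = {}
    for c in constraints:
        if (
            contig_lengths.get(c.contig_a, 0) < min_length
            or contig_lengths.get(c.contig_b, 0) < min_length
        ):
            continue
        a, b = sorted((c.contig_a, c.contig_b))
        if c.contig_a != a:
            # re-express as a -> b: with S_a = +1 the old S_b is the parity,
            # and x_old_b - x_old_a seen from the other end changes sign
            c = PairConstraint(
                a, b, c.parity, -c.implied_offset(c.parity),
                c.len_b, c.len_a, c.pair_id,
            )
        by_edge.setdefault((a, b), []).append(c)

    graph = nx.Graph()
    for cid, length in contig_lengths.items():
        if length >= min_length:
            graph.add_node(cid, length=length)
    ignored: list[IgnoredEdge] = []
    for (a, b), group in sorted(by_edge.items()):
        plus = [c for c in group if c.parity == +1]
        minus = [c for c in group if c.parity == -1]
        dominant, parity = (plus, +1) if len(plus) >= len(minus) else (minus, -1)
        frac = len(dominant) / len(group)
        if frac < majority_fraction:
            ignored.append(IgnoredEdge(a, b, len(group), "no significant majority"))
            continue
        if max_sep_deviation is not None and len(dominant) >= 3:
            med = float(np.median([c.offset_plus for c in dominant]))
            tight = [
                c for c in dominant
                if abs(c.offset_plus - med) <= max_sep_deviation
            ]
            # a genuine edge's separations cluster at the insert size; when
            # the window drops a large fraction the links are background
            if len(tight) < majority_fraction * len(dominant):
                ignored.append(
                    IgnoredEdge(a, b, len(group), "separations not clustered")
                )
                continue
            dominant = tight
        if len(dominant) < min_links:
            ignored.append(IgnoredEdge(a, b, len(group), "fewer links than W"))
            continue
        graph.add_edge(a, b, J=parity * len(dominant), pairs=dominant)
    return graph, ignored


def edge_dbar(graph: nx.Graph, a: str, b: str, orientations: dict[str, int]) -> float:
    """Mean suggested x_b - x_a (a, b in either order) under an assignment."""
    lo, hi = sorted((a, b))
    pairs: list[PairConstraint] = graph.edges[lo, hi]["pairs"]
    mean = sum(c.implied_offset(orientations[lo]) for c in pairs) / len(pairs)
    return mean if a == lo else -mean


def _linked_sep_mean(
    delta: float, la: float, lb: float, insert: float, sigma: float
) -> float:
    """E[separation | the pair links the two contigs] for offset ``delta``.

    A pair is observed on an edge only when both reads fit inside the
    contigs, which weights the Gaussian separation density by the trapezoid
    of feasible read-position combinations and truncates its tails; the
    conditional mean therefore differs from the nominal insert.
    """
    lo = max(delta - la, insert - 6.0 * sigma)
    hi = min(delta + lb, insert + 6.0 * sigma)
    if hi <= lo:
        return insert
    s = np.linspace(lo, hi, 257)
    w = s - delta
    # feasible read-start combinations at separation s
    tent = np.clip(np.minimum(la, lb - w) - np.maximum(0.0, -w), 0.0, None)
    dens = tent * np.exp(-0.5 * ((s - insert) / sigma) ** 2)
    z = np.trapezoid(dens, s)
    if z <= 0:
        return insert
    return float(np.trapezoid(s * dens, s) / z)


def corrected_edge_dbar(
    graph: nx.Graph,
    a: str,
    b: str,
    orientations: dict[str, int],
    insert: float,
    sigma: float,
    read_length: int,
    max_iter: int = 20,
) -> float:
    """Conditioning-corrected mean separation for one edge.

    The naive per-pair suggested separation systematically misestimates the
    true offset by insert - E[separation | linked] (a bias growing with
    sigma^2 and steepening as the contigs shorten).  The corrected offset
    solves delta = naive - insert + E[sep | linked, delta] by fixed-point
    iteration; with sigma = 0 it equals the naive mean.
    """
    naive = edge_dbar(graph, a, b, orientations)
    if sigma <= 0:
        return naive
    lo, hi = sorted((a, b))
    pairs: list[PairConstraint] = graph.edges[lo, hi]["pairs"]
    la = max(1.0, pairs[0].len_a - read_length)
    lb = max(1.0, pairs[0].len_b - read_length)
    # work in the canonical direction, on the magnitude of the offset
    canon = naive if a == lo else -naive
    sign = 1.0 if canon >= 0 else -1.0
    delta = abs(canon)
    if sign < 0:
        la, lb = lb, la
    for _ in range(max_iter):
        new = abs(canon) - insert + _linked_sep_mean(delta, la, lb, insert, sigma)
        if abs(new - delta) < 1e-3:
            delta = new
            break
        delta = new
    corrected = sign * delta
    return corrected if a == lo else -corrected


def to_dot(graph: nx.Graph, path=None) -> str:
    """Emit the connectivity graph in DOT format (J as edge label)."""
    lines = ["graph connectivity {"]
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";')
    for a, b, data in sorted(graph.edges(data=True)):
        lines.append(f'  "{a}" -- "{b}" [label="J={data["J"]}"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
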