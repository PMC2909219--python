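"""Pair-constraint geometry and connectivity-graph construction tests."""

import numpy as np
import pytest

from matescaf.model import ILLUMINA_PE, SOLID_MATE, Library, ReadPlacement
from matescaf.pairgraph import (
    PairConstraint,
    build_graph,
    corrected_edge_dbar,
    edge_dbar,
    pair_constraint,
    to_dot,
)
from matescaf.simdata import fragment_to_contigs, simulate_genome, simulate_mate_pairs

SOLID = Library("solid", SOLID_MATE, insert=1000.0, read_length=30)


def test_worked_solid_example():
    """R at offset 50 on i, F at offset 120 on j, both forward, Ins = 1000
    implies x_j - x_i = Ins - p_F + p_R = 930 and same-orientation parity."""
    pr = ReadPlacement("r", "i", 50, +1, 30)
    pf = ReadPlacement("f", "j", 120, +1, 30)
    c = pair_constraint(pr, pf, SOLID, len_a=2000, len_b=2000)
    assert c.parity == +1
    assert c.implied_offset(+1) == 930.0


def test_opposite_strand_solid_pair_has_negative_parity():
    pr = ReadPlacement("r", "i", 50, +1, 30)
    pf = ReadPlacement("f", "j", 120, -1, 30)
    assert pair_constraint(pr, pf, SOLID, 2000, 2000).parity == -1


def test_illumina_parity_is_negated():
    pe = Library("pe", ILLUMINA_PE, insert=350.0, read_length=30)
    pr = ReadPlacement("r", "i", 50, +1, 30)
    pf = ReadPlacement("f", "j", 120, -1, 30)
    assert pair_constraint(pr, pf, pe, 2000, 2000).parity == +1


def test_same_contig_pair_rejected():
    pr = ReadPlacement("r", "i", 50, +1, 30)
    pf = ReadPlacement("f", "i", 120, +1, 30)
    with pytest.raises(ValueError):
        pair_constraint(pr, pf, SOLID, 2000, 2000)


def test_flip_transform_is_consistent():
    """Flipping contig a reflects the implied offset through the layout."""
    pr = ReadPlacement("r", "i", 50, +1, 30)
    pf = ReadPlacement("f", "j", 120, +1, 30)
    c = pair_constraint(pr, pf, SOLID, 1500, 800)
    assert c.implied_offset(-1) == -c.implied_offset(+1) + 1500 - 800


@pytest.mark.parametrize("kind", [SOLID_MATE, ILLUMINA_PE])
def test_zero_noise_round_trip(kind):
    """Every zero-noise cross-contig pair reproduces the exact true offset
    when evaluated at the true orientations."""
    g = simulate_genome(40_000, seed=31)
    contigs, truth = fragment_to_contigs(g, 12, seed=32)
    lib = Library("lib", kind, insert=1350.0, sigma=0.0, read_length=35)
    placements, pairs = simulate_mate_pairs(truth, lib, 6000, seed=33)
    by_read = {p.read_id: p for p in placements}
    lengths = {cid: len(s) for cid, s in contigs.items()}
    tstart = {c.contig_id: c.intervals[0].genome_start for c in truth.contigs.values()}
    tstrand = {c.contig_id: c.intervals[0].strand for c in truth.contigs.values()}
    n_cross = 0
    for pair in pairs:
        pr, pf = by_read[pair.r_read], by_read[pair.f_read]
        if pr.contig_id == pf.contig_id:
            continue
        c = pair_constraint(pr, pf, lib, lengths[pr.contig_id], lengths[pf.contig_id])
        assert c.parity == tstrand[c.contig_a] * tstrand[c.contig_b]
        true_offset = tstart[c.contig_b] - tstart[c.contig_a]
        assert c.implied_offset(tstrand[c.contig_a]) == pytest.approx(true_offset)
        n_cross += 1
    assert n_cross > 300


def _constraints(n, parity, offset=500.0, a="a", b="b"):
    return [
        PairConstraint(a, b, parity, offset, 2000, 2000, f"p{k}")
        for k in range(n)
    ]


class TestBuildGraph:
    lengths = {"a": 2000, "b": 2000}

    def test_clear_majority_drops_minority(self):
        cons = _constraints(9, +1) + _constraints(1, -1)
        graph, ignored = build_graph(cons, self.lengths, min_links=5)
        assert graph.edges["a", "b"]["J"] == +9
        assert not ignored

    def test_no_majority_ignores_edge(self):
        cons = _constraints(6, +1) + _constraints(5, -1)
        graph, ignored = build_graph(cons, self.lengths, min_links=5)
        assert graph.number_of_edges() == 0
        assert len(ignored) == 1

    def test_too_few_links_ignored(self):
        graph, ignored = build_graph(
            _constraints(4, +1), self.lengths, min_links=5
        )
        assert graph.number_of_edges() == 0

    def test_short_contigs_excluded(self):
        graph, _ = build_graph(
            _constraints(9, +1), {"a": 2000, "b": 100}, min_length=150
        )
        assert "b" not in graph

    def test_scattered_separations_flag_background_edge(self):
        cons = [
            PairConstraint("a", "b", +1, off, 2000, 2000, f"p{k}")
            for k, off in enumerate([-1500, -800, 0, 700, 1400, 2100])
        ]
        graph, ignored = build_graph(
            cons, self.lengths, min_links=5, max_sep_deviation=300.0
        )
        assert graph.number_of_edges() == 0
        assert ignored[0].reason == "separations not clustered"

    def test_dbar_is_antisymmetric(self):
        graph, _ = build_graph(
            _constraints(6, +1, offset=420.0), self.lengths, min_links=5
        )
        ors = {"a": 1, "b": 1}
        assert edge_dbar(graph, "a", "b", ors) == 420.0
        assert edge_dbar(graph, "b", "a", ors) == -420.0

    def test_corrected_dbar_reduces_to_naive_at_zero_sigma(self):
        graph, _ = build_graph(
            _constraints(6, +1, offset=420.0), self.lengths, min_links=5
        )
        ors = {"a": 1, "b": 1}
        got = corrected_edge_dbar(graph, "a", "b", ors, 1000.0, 0.0, 30)
        assert got == 420.0


def test_zero_noise_graph_is_exact():
    g = simulate_genome(60_000, seed=34)
    contigs, truth = fragment_to_contigs(g, 15, seed=35)
    lib = Library("lib", SOLID_MATE, insert=1350.0, sigma=0.0, read_length=35)
    placements, pairs = simulate_mate_pairs(truth, lib, 15_000, seed=36)
    by_read = {p.read_id: p for p in placements}
    lengths = {cid: len(s) for cid, s in contigs.items()}
    cons = [
        pair_constraint(
            by_read[p.r_read], by_read[p.f_read], lib,
            lengths[by_read[p.r_read].contig_id],
            lengths[by_read[p.f_read].contig_id],
        )
        for p in pairs
        if by_read[p.r_read].contig_id != by_read[p.f_read].contig_id
    ]
    graph, ignored = build_graph(cons, lengths, min_links=5)
    assert not ignored
    tstart = {c.contig_id: c.intervals[0].genome_start for c in truth.contigs.values()}
    tstrand = {c.contig_id: c.intervals[0].strand for c in truth.contigs.values()}
    for a, b, data in graph.edges(data=True):
        assert np.sign(data["J"]) == tstrand[a] * tstrand[b]
        assert edge_dbar(graph, a, b, tstrand) == pytest.approx(
            tstart[b] - tstart[a]
        )


def test_dot_export_counts():
    graph, _ = build_graph(
        _constraints(6, +1) + _constraints(7, -1, a="b", b="c"),
        {"a": 2000, "b": 2000, "c": 2000},
        min_links=5,
    )
    dot = to_dot(graph)
    assert dot.count(" -- ") == 2
    assert sum(line.strip().endswith('";') for line in dot.splitlines()) == 3
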