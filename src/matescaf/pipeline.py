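"""End-to-end scaffolding driver.

Stages: preprocessing (insert estimation, optional self-consistency and
chimera splitting, coverage filtering) -> connectivity graph -> an
orientation / positioning / spring-pruning loop that returns to orientation
whenever positioning removes contigs -> density-profile segmentation (which
also loops back when junctures are removed) -> contig joining and gap
rendering -> optional truth-based evaluation.  Every input contig ends up
exactly once in the output: in a scaffold, or as a singleton with a recorded
removal reason.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx

from .config import PipelineConfig
from .evaluate import ErrorReport, adjacency_recovery, error_report
from .finish import render_scaffold
from .layout import ContigPlacement, ScaffoldLayout
from .model import Library, MatePair, ReadPlacement
from .orient import assign_orientations
from .pairgraph import build_graph, corrected_edge_dbar, pair_constraint
from .position import prune_stretched, solve_spring
from .preprocess import (
    InsertStats,
    coverage_filter,
    estimate_insert_size,
    measured_separation,
    pair_parity_ok,
    split_low_span,
)
from .segment import resolve_tangles
from .simdata import TruthLayout

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    scaffolds: dict[str, tuple[ScaffoldLayout, str]]
    singletons: dict[str, str]
    removed_reasons: dict[str, str]
    graph: nx.Graph
    insert_stats: dict[str, InsertStats]
    report: ErrorReport | None
    adjacency: tuple[int, int] | None
    log: list[str] = field(default_factory=list)
    converged: bool = True


def _estimate_libraries(
    config: PipelineConfig,
    same_contig: list[tuple[ReadPlacement, ReadPlacement, Library]],
    log: list[str],
) -> tuple[dict[str, InsertStats], dict[str, Library]]:
    seps: dict[str, list[float]] = defaultdict(list)
    for pr, pf, lib in same_contig:
        if pair_parity_ok(pr, pf, lib):
            seps[lib.name].append(measured_separation(pr, pf))
    stats: dict[str, InsertStats] = {}
    effective: dict[str, Library] = {}
    for lib in config.libraries:
        if seps.get(lib.name):
            st = estimate_insert_size(seps[lib.name], lib.insert)
        else:
            st = InsertStats(lib.insert, lib.sigma_or_default, 0, 0, None, True)
            log.append(f"{lib.name}: no same-contig pairs; using nominal insert")
        stats[lib.name] = st
        sigma = st.sd if st.n_retained > 1 and st.sd > 0 else lib.sigma_or_default
        effective[lib.name] = replace(lib, insert=st.mean, sigma=sigma)
        log.append(
            f"{lib.name}: insert {st.mean:.1f} +/- {sigma:.1f} "
            f"({st.n_retained} pairs, {st.n_outliers} outliers)"
        )
    return stats, effective


def _orient_position_loop(
    working: nx.Graph,
    config: PipelineConfig,
    sigma: float,
    insert: float,
    read_length: int,
    removed_reasons: dict[str, str],
    log: list[str],
) -> tuple[list[ScaffoldLayout], bool]:
    """The orient -> position -> prune cycle; returns (layouts, converged)."""
    for _ in range(config.max_iterations):
        with_edges = working.edge_subgraph(working.edges).copy() if working.edges else nx.Graph()
        assignment = (
            assign_orientations(
                with_edges, config.layer_cap, config.anneal, config.seed
            )
            if with_edges.number_of_nodes()
            else None
        )
        consistent = nx.Graph()
        consistent.add_nodes_from(working.nodes)
        if assignment is not None:
            violated = set(assignment.violated_edges)
            for a, b in with_edges.edges:
                key = (a, b) if a < b else (b, a)
                if key not in violated:
                    consistent.add_edge(a, b)
            if violated:
                log.append(f"orientation: {len(violated)} links dropped as violated")
        layouts: list[ScaffoldLayout] = []
        pruned: list[str] = []
        for comp in sorted(nx.connected_components(consistent), key=min):
            comp = sorted(comp)
            if len(comp) == 1:
                layouts.append(
                    ScaffoldLayout(
                        comp[0],
                        [ContigPlacement(comp[0], 1, 0.0, working.nodes[comp[0]]["length"])],
                    )
                )
                continue
            sub = consistent.subgraph(comp)
            edges = []
            for a, b in sub.edges:
                data = working.edges[a, b]
                edges.append(
                    (a, b, float(abs(data["J"])),
                     corrected_edge_dbar(
                         working, a, b, assignment.orientations,
                         insert, sigma, read_length,
                     ))
                )
            solution = solve_spring(edges, sigma)
            to_remove, worst = prune_stretched(solution, config.delta_threshold_k)
            if to_remove:
                pruned.extend(to_remove)
                log.append(
                    f"positioning: spring {worst} over threshold; removing {to_remove}"
                )
                continue
            placements = [
                ContigPlacement(
                    cid,
                    assignment.orientations[cid],
                    solution.positions[cid],
                    working.nodes[cid]["length"],
                )
                for cid in comp
            ]
            layout = ScaffoldLayout(min(comp), placements).shifted()
            # canonical direction: lowest-named contig forward
            anchor = min(comp)
            if next(
                c.orientation for c in layout.contigs if c.contig_id == anchor
            ) == -1:
                layout = layout.flipped()
            layouts.append(layout)
        if not pruned:
            return layouts, True
        for cid in pruned:
            if working.has_node(cid):
                working.remove_node(cid)
                removed_reasons[cid] = "stretched spring"
    return layouts, False


def run_pipeline(
    contigs: dict[str, str],
    placements: list[ReadPlacement],
    pairs: list[MatePair],
    config: PipelineConfig,
    truth: TruthLayout | None = None,
    genome: str | None = None,
) -> PipelineResult:
    log: list[str] = []
    removed_reasons: dict[str, str] = {}
    contigs = dict(contigs)
    by_read = {p.read_id: p for p in placements}

    same_contig: list[tuple[ReadPlacement, ReadPlacement, Library]] = []
    cross: list[tuple[ReadPlacement, ReadPlacement, Library]] = []
    for pair in pairs:
        pr, pf = by_read.get(pair.r_read), by_read.get(pair.f_read)
        if pr is None or pf is None:
            continue
        lib = config.library(pair.library)
        (same_contig if pr.contig_id == pf.contig_id else cross).append((pr, pf, lib))
    log.append(
        f"inputs: {len(contigs)} contigs, {len(placements)} placements, "
        f"{len(pairs)} pairs ({len(same_contig)} same-contig)"
    )

    stats, effective = _estimate_libraries(config, same_contig, log)

    if config.self_consistency:
        by_contig: dict[str, list] = defaultdict(list)
        for pr, pf, lib in same_contig:
            by_contig[pr.contig_id].append((pr, pf, lib))
        for cid, items in sorted(by_contig.items()):
            violations = 0
            for pr, pf, lib in items:
                st = stats[lib.name]
                if not pair_parity_ok(pr, pf, lib):
                    violations += 1
                elif abs(measured_separation(pr, pf) - st.mean) > st.sd:
                    violations += 1
            if violations > config.self_consistency_max_violations:
                removed_reasons[cid] = "self-consistency"
        if removed_reasons:
            log.append(f"self-consistency: discarded {len(removed_reasons)} contigs")

    if config.split_chimeric:
        max_ins = max((l.insert for l in effective.values()), default=0.0)
        pair_index: dict[str, list] = defaultdict(list)
        for pr, pf, lib in same_contig:
            pair_index[pr.contig_id].append((pr, pf))
        renames: dict[str, list[tuple[str, int, int]]] = {}
        for cid in sorted(contigs):
            if cid in removed_reasons:
                continue
            segments = split_low_span(
                len(contigs[cid]), pair_index.get(cid, []), max_ins,
                config.split_min_span,
            )
            if len(segments) > 1:
                renames[cid] = [
                    (f"{cid}:{k}", a, b) for k, (a, b) in enumerate(segments)
                ]
        if renames:
            log.append(f"chimera split: cut {len(renames)} contigs")
            new_placements = []
            for p in placements:
                parts = renames.get(p.contig_id)
                if parts is None:
                    new_placements.append(p)
                    continue
                for name, a, b in parts:
                    if p.offset >= a and p.offset + p.read_length <= b:
                        new_placements.append(
                            replace(p, contig_id=name, offset=p.offset - a)
                        )
                        break
            placements = new_placements
            by_read = {p.read_id: p for p in placements}
            for cid, parts in renames.items():
                seq = contigs.pop(cid)
                for name, a, b in parts:
                    contigs[name] = seq[a:b]
            cross = []
            for pair in pairs:
                pr, pf = by_read.get(pair.r_read), by_read.get(pair.f_read)
                if pr is None or pf is None or pr.contig_id == pf.contig_id:
                    continue
                cross.append((pr, pf, config.library(pair.library)))

    lengths = {cid: len(seq) for cid, seq in contigs.items()}
    cov_removed, excluded_reads = coverage_filter(
        {cid: n for cid, n in lengths.items() if cid not in removed_reasons},
        [p for p in placements if p.contig_id not in removed_reasons],
        config.mean_cov_factor,
        config.local_cov_factor,
        config.coverage_window,
    )
    for cid in cov_removed:
        removed_reasons[cid] = "high mean coverage"
    if cov_removed or excluded_reads:
        log.append(
            f"coverage filter: removed {len(cov_removed)} contigs, "
            f"excluded {len(excluded_reads)} reads"
        )

    constraints = []
    for pr, pf, lib in cross:
        if pr.contig_id in removed_reasons or pf.contig_id in removed_reasons:
            continue
        if pr.read_id in excluded_reads or pf.read_id in excluded_reads:
            continue
        constraints.append(
            pair_constraint(
                pr, pf, effective[lib.name],
                lengths[pr.contig_id], lengths[pf.contig_id],
            )
        )
    eligible = {
        cid: n for cid, n in lengths.items() if cid not in removed_reasons
    }
    sep_cutoff = 2.5 * max(
        (lib.sigma_or_default for lib in effective.values()), default=0.0
    )
    graph, ignored = build_graph(
        constraints, eligible, config.min_links, config.min_length,
        config.majority_fraction, max_sep_deviation=sep_cutoff or None,
    )
    log.append(
        f"graph: {graph.number_of_nodes()} contigs, {graph.number_of_edges()} edges, "
        f"{len(ignored)} edges ignored"
    )
    sigma = max(
        (lib.sigma_or_default for lib in effective.values()), default=1.0
    )
    mean_insert = max((lib.insert for lib in effective.values()), default=1000.0)
    read_length = max((lib.read_length for lib in effective.values()), default=35)

    working = graph.copy()
    layouts: list[ScaffoldLayout] = []
    converged = True
    for round_no in range(config.max_segmentation_rounds):
        layouts, ok = _orient_position_loop(
            working, config, sigma, mean_insert, read_length,
            removed_reasons, log,
        )
        converged = converged and ok
        removed_any = False
        for layout in layouts:
            if len(layout) < 3:
                continue
            _, removed = resolve_tangles(
                layout, working, mean_insert,
                window=config.density_window,
                schedule=config.anneal,
                seed=config.seed + round_no,
            )
            for cid in removed:
                if working.has_node(cid):
                    working.remove_node(cid)
                    removed_reasons[cid] = "tangle juncture"
                    removed_any = True
        if not removed_any:
            break
        log.append(f"segmentation round {round_no}: junctures removed, re-solving")
    else:
        converged = False

    scaffolds: dict[str, tuple[ScaffoldLayout, str]] = {}
    in_scaffold: set[str] = set()
    counter = 0
    for layout in layouts:
        if len(layout) < 2:
            continue
        name = f"scaffold_{counter:04d}"
        counter += 1
        seq, _ = render_scaffold(
            ScaffoldLayout(name, layout.contigs), contigs,
            config.small_gap, config.min_join_identity,
        )
        scaffolds[name] = (ScaffoldLayout(name, layout.contigs), seq)
        in_scaffold.update(layout.contig_ids())

    singletons: dict[str, str] = {}
    for cid in sorted(contigs):
        if cid in in_scaffold:
            continue
        singletons[cid] = contigs[cid]
        if cid not in removed_reasons:
            if len(contigs[cid]) < config.min_length:
                removed_reasons[cid] = "shorter than L"
            else:
                removed_reasons[cid] = "unconnected"
    log.append(
        f"output: {len(scaffolds)} scaffolds, {len(singletons)} singletons"
    )

    report = None
    adjacency = None
    if truth is not None:
        scaffold_layouts = [lay for lay, _ in scaffolds.values()]
        report = error_report(scaffold_layouts, truth, genome, contigs)
        adjacency = adjacency_recovery(scaffold_layouts, truth)
    return PipelineResult(
        scaffolds, singletons, removed_reasons, graph, stats, report,
        adjacency, log, converged,
    )
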