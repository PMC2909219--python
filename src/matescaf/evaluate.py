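"""Assembly-quality metrics against simulator ground truth.

N50 plus a four-part error taxonomy, evaluated exactly from the recorded
truth layout instead of aligning against a reference:

* ``eps_no_m`` — percentage of assembled bases in contigs with no truth
  match;
* ``eps_mis_m`` — percentage of assembled bases that mismatch the genome at
  their truth coordinates;
* ``eps_ch_small`` / ``eps_ch_large`` — chimeric joins inside one contig,
  split by whether the true gap between the joined loci is at most / more
  than 500 bases (events per Mbp of assembly);
* ``eps_orient`` — adjacent contig pairs in a scaffold whose relative
  orientation disagrees with the truth (events per Mbp);
* ``eps_sep`` — adjacent pairs with verified orientation whose estimated
  separation is more than 500 bases off the true separation (events per
  Mbp);

together with the genome coverage percentage of the assembled contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .layout import ScaffoldLayout
from .simdata import TruthLayout, reverse_complement

__all__ = ["ErrorReport", "n50", "error_report", "adjacency_recovery"]

GAP_CLASS = 500  # bases: small vs large chimeric gap, separation tolerance


@dataclass
class ErrorReport:
    n50: int
    eps_no_m: float
    eps_mis_m: float
    eps_ch_small: float
    eps_ch_large: float
    eps_orient: float
    eps_sep: float
    genome_coverage: float
    assembled_bases: int


def n50(lengths) -> int:
    """Smallest length such that pieces at least that long cover half the
    assembled bases."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def _primary_interval(truth: TruthLayout, contig_id: str):
    ct = truth.contigs.get(contig_id)
    if ct is None or not ct.intervals:
        return None
    return ct.intervals[0]


def error_report(
    scaffolds: list[ScaffoldLayout],
    truth: TruthLayout,
    genome: str | None = None,
    contig_sequences: dict[str, str] | None = None,
) -> ErrorReport:
    """Truth-based error taxonomy for a set of scaffold layouts."""
    assembled = sum(c.length for s in scaffolds for c in s.contigs)
    mbp = max(assembled, 1) / 1e6

    no_match_bases = 0
    mismatch_bases = 0
    ch_small = ch_large = 0
    orient_events = sep_events = 0

    seen: set[str] = set()
    for scaffold in scaffolds:
        for c in scaffold.contigs:
            if c.contig_id in seen:
                continue
            seen.add(c.contig_id)
            ct = truth.contigs.get(c.contig_id)
            if ct is None:
                no_match_bases += c.length
                continue
            # chimeric joins recorded inside one contig
            for iv1, iv2 in zip(ct.intervals, ct.intervals[1:]):
                gap = abs(iv2.genome_start - (iv1.genome_start + iv1.length))
                if gap <= GAP_CLASS:
                    ch_small += 1
                else:
                    ch_large += 1
            if genome is not None and contig_sequences is not None:
                seq = contig_sequences.get(c.contig_id)
                if seq is not None:
                    for iv in ct.intervals:
                        ref = genome[iv.genome_start : iv.genome_start + iv.length]
                        part = seq[iv.contig_offset : iv.contig_offset + iv.length]
                        if iv.strand == -1:
                            part = reverse_complement(part)
                        mismatch_bases += sum(
                            1 for a, b in zip(ref, part) if a != b
                        ) + abs(len(ref) - len(part))

        # adjacency-level rearrangement errors
        for left, right in zip(scaffold.contigs, scaffold.contigs[1:]):
            iv_l = _primary_interval(truth, left.contig_id)
            iv_r = _primary_interval(truth, right.contig_id)
            if iv_l is None or iv_r is None:
                continue
            rel_assembled = left.orientation * right.orientation
            rel_true = iv_l.strand * iv_r.strand
            if rel_assembled != rel_true:
                orient_events += 1
                continue
            # facing-end gap is invariant under reversing the whole scaffold
            est_gap = right.start - left.end
            g_lo, g_hi = sorted((iv_l.genome_start, iv_r.genome_start))
            left_len = iv_l.length if g_lo == iv_l.genome_start else iv_r.length
            true_gap = g_hi - (g_lo + left_len)
            if abs(est_gap - true_gap) > GAP_CLASS:
                sep_events += 1

    covered = sorted(
        (iv.genome_start, iv.genome_start + iv.length)
        for cid in seen
        if truth.contigs.get(cid)
        for iv in truth.contigs[cid].intervals
    )
    merged_total = 0
    cur_start = cur_end = None
    for a, b in covered:
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                merged_total += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        merged_total += cur_end - cur_start

    lengths = [sum(c.length for c in s.contigs) for s in scaffolds if s.contigs]
    return ErrorReport(
        n50=n50(lengths) if lengths else 0,
        eps_no_m=100.0 * no_match_bases / max(assembled, 1),
        eps_mis_m=100.0 * mismatch_bases / max(assembled, 1),
        eps_ch_small=ch_small / mbp,
        eps_ch_large=ch_large / mbp,
        eps_orient=orient_events / mbp,
        eps_sep=sep_events / mbp,
        genome_coverage=100.0 * merged_total / truth.genome_length,
        assembled_bases=assembled,
    )


def adjacency_recovery(
    scaffolds: list[ScaffoldLayout], truth: TruthLayout
) -> tuple[int, int]:
    """(recovered, total) count of true adjacent contig pairs.

    A true adjacency (consecutive source intervals on the genome) counts as
    recovered when the two contigs are adjacent in some scaffold, in the
    true relative order and relative orientation — both invariant under a
    global scaffold flip, so either scaffold direction matches.
    """
    assembled_adjacent: set[tuple[str, int, str, int]] = set()
    for scaffold in scaffolds:
        for left, right in zip(scaffold.contigs, scaffold.contigs[1:]):
            assembled_adjacent.add(
                (left.contig_id, left.orientation, right.contig_id, right.orientation)
            )
            # the flipped scaffold represents the same assembly
            assembled_adjacent.add(
                (right.contig_id, -right.orientation, left.contig_id, -left.orientation)
            )
    total = recovered = 0
    for iv_l, iv_r in truth.true_adjacencies():
        if iv_l.contig_id == iv_r.contig_id:
            continue
        total += 1
        key = (iv_l.contig_id, iv_l.strand, iv_r.contig_id, iv_r.strand)
        if key in assembled_adjacent:
            recovered += 1
    return recovered, total
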