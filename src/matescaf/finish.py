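"""Scaffold finishing: join overlapping contig ends or insert 'N' spacers.

For each adjacency in a positioned scaffold the estimated gap g between the
left contig's end and the right contig's start decides the action: when the
positions indicate an overlap (g < 0) or a tiny gap (g below a small-gap
cutoff, default 10 bases) and the facing ends are sequence-similar, the two
contigs are merged; otherwise an 'N' spacer is inserted whose length is g
rounded to the nearest multiple of 50 (minimum 50).  When the positions
indicate an overlap but the ends are *not* similar, a fixed 50-base 'N'
spacer separates the contigs.  A contig with negative orientation
contributes its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .layout import ScaffoldLayout
from .simdata import reverse_complement

__all__ = ["JoinDecision", "join_or_gap", "render_scaffold", "round_gap"]

SMALL_GAP = 10  # bases: below this, try joining instead of an N spacer
SPACER_UNIT = 50
MIN_IDENTITY = 0.90


@dataclass(frozen=True)
class JoinDecision:
    action: str  # "merge" | "gap"
    overlap: int = 0  # bases shared when merging
    n_run: int = 0  # spacer length when gapping


def round_gap(g: float) -> int:
    """Round a gap to the nearest positive multiple of 50 (ties up)."""
    g = max(0.0, g)
    return max(SPACER_UNIT, int(g / SPACER_UNIT + 0.5) * SPACER_UNIT)


def _end_identity(left_end: str, right_start: str, overlap: int) -> float:
    """Identity of the best alignment of the facing ends at this overlap."""
    if overlap < 1 or overlap > len(left_end) or overlap > len(right_start):
        return 0.0
    a = left_end[-overlap:]
    b = right_start[:overlap]
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / overlap


def join_or_gap(
    left_end: str,
    right_start: str,
    gap: float,
    small_gap: int = SMALL_GAP,
    min_identity: float = MIN_IDENTITY,
) -> JoinDecision:
    """Decide merge vs spacer for one adjacency.

    ``left_end`` / ``right_start`` are the facing sequence windows (already
    oriented); ``gap`` is the positional gap (negative = overlap).
    """
    if gap < small_gap:
        # candidate overlap lengths around the positional estimate
        center = max(1, int(round(-gap)))
        window = max(2 * center, 30)
        lo = max(1, center - window // 2)
        hi = min(window, len(left_end), len(right_start))
        best_o, best_id = 0, 0.0
        for o in range(lo, hi + 1):
            ident = _end_identity(left_end, right_start, o)
            if ident > best_id or (ident == best_id and abs(o - center) < abs(best_o - center)):
                best_o, best_id = o, ident
        # require a few bases of overlap so a chance single-base match
        # cannot trigger a merge
        if best_id >= min_identity and best_o >= 5:
            return JoinDecision("merge", overlap=best_o)
        if gap < 0:
            # positions claim an overlap the sequences do not support
            return JoinDecision("gap", n_run=SPACER_UNIT)
        return JoinDecision("gap", n_run=round_gap(gap))
    return JoinDecision("gap", n_run=round_gap(gap))


def render_scaffold(
    layout: ScaffoldLayout,
    sequences: dict[str, str],
    small_gap: int = SMALL_GAP,
    min_identity: float = MIN_IDENTITY,
) -> tuple[str, list[JoinDecision]]:
    """Concatenate oriented contigs and spacers in position order."""
    pieces: list[str] = []
    decisions: list[JoinDecision] = []
    prev_end: float | None = None
    for placement in layout.contigs:
        seq = sequences[placement.contig_id]
        if placement.orientation == -1:
            seq = reverse_complement(seq)
        if prev_end is None:
            pieces.append(seq)
        else:
            gap = placement.start - prev_end
            decision = join_or_gap(
                pieces[-1][-200:], seq[:200], gap, small_gap, min_identity
            )
            decisions.append(decision)
            if decision.action == "merge":
                o = decision.overlap
                left_tail = pieces[-1][-o:]
                right_head = seq[:o]
                # consensus at disagreeing columns: keep the left contig's base
                merged = "".join(
                    l if l == r else l for l, r in zip(left_tail, right_head)
                )
                pieces[-1] = pieces[-1][:-o] + merged
                pieces.append(seq[o:])
            else:
                pieces.append("N" * decision.n_run)
                pieces.append(seq)
        prev_end = placement.end
    return "".join(pieces), decisions
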