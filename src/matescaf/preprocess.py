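"""Preprocessing: insert-size estimation and contig/read quality filters.

Mate pairs whose two reads landed on the *same* contig calibrate the library
(empirical insert size and spread) and audit the contigs themselves:

* insert estimation drops outlier pairs whose separation differs from the
  nominal insert by more than the nominal insert itself (five standard
  deviations under the ~20%-of-mean rule) and averages the rest;
* the self-consistency check discards contigs accumulating too many pairs
  whose on-contig orientation contradicts the library geometry or whose
  separation is more than one empirical sd off the empirical insert;
* the spanning-link splitter cuts a contig where suspiciously few pairs
  bridge a point — the signature of a chimeric join;
* the coverage filter removes whole contigs with outlying mean coverage
  (collapsed repeats) from scaffolding and excludes reads in locally
  high-coverage windows from pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SOLID_MATE, Library, ReadPlacement

__all__ = [
    "InsertStats",
    "measured_separation",
    "pair_parity_ok",
    "estimate_insert_size",
    "self_consistency_filter",
    "split_low_span",
    "coverage_filter",
]


@dataclass
class InsertStats:
    mean: float
    sd: float
    n_retained: int
    n_outliers: int
    histogram: tuple[np.ndarray, np.ndarray] | None = None
    fallback: bool = False


def measured_separation(
    placement_r: ReadPlacement, placement_f: ReadPlacement
) -> float:
    """Observed insert for a same-contig pair (start-to-start separation).

    With both reads on one contig the scaffold geometry collapses to
    tau_R * (p_F - p_R); a correctly oriented, correctly separated pair
    yields a value near the library insert, wrong geometry yields a negative
    or wildly off value.
    """
    if placement_r.contig_id != placement_f.contig_id:
        raise ValueError("pair spans two contigs")
    return placement_r.same_strand * (placement_f.offset - placement_r.offset)


def pair_parity_ok(
    placement_r: ReadPlacement, placement_f: ReadPlacement, library: Library
) -> bool:
    """Same-contig orientation check: SOLiD pairs expect the two reads on
    the same strand, Illumina paired-ends on opposite strands."""
    parity = placement_r.same_strand * placement_f.same_strand
    return parity == (+1 if library.kind == SOLID_MATE else -1)


def estimate_insert_size(
    separations: list[float], nominal_insert: float
) -> InsertStats:
    """Empirical insert size from same-contig pair separations.

    Pairs with |separation - nominal| > nominal are outliers (the broad
    background of the separation histogram); the empirical insert is the
    mean of the remainder, the empirical sigma its standard deviation.
    Falls back to the nominal insert with sigma = 0.2 * nominal when every
    pair is an outlier.
    """
    if nominal_insert <= 0:
        raise ValueError("nominal insert must be positive")
    if not separations:
        raise ValueError("need at least one same-contig pair")
    seps = np.asarray(separations, dtype=float)
    keep = np.abs(seps - nominal_insert) <= nominal_insert
    retained = seps[keep]
    hist = np.histogram(seps, bins=50)
    if retained.size == 0:
        return InsertStats(
            nominal_insert, 0.2 * nominal_insert, 0, int(seps.size), hist, True
        )
    return InsertStats(
        float(retained.mean()),
        float(retained.std()),
        int(retained.size),
        int(seps.size - retained.size),
        hist,
    )


def self_consistency_filter(
    pairs: list[tuple[ReadPlacement, ReadPlacement]],
    library: Library,
    stats: InsertStats,
    max_violations: int = 5,
) -> bool:
    """True = keep the contig, False = discard it.

    A pair violates when its on-contig orientation contradicts the library
    geometry or its separation is more than one empirical sd away from the
    empirical insert (strictly more).  The contig is discarded when the
    violation count exceeds ``max_violations``.
    """
    violations = 0
    for pr, pf in pairs:
        if not pair_parity_ok(pr, pf, library):
            violations += 1
            continue
        sep = measured_separation(pr, pf)
        if abs(sep - stats.mean) > stats.sd:
            violations += 1
    return violations <= max_violations


def split_low_span(
    contig_length: int,
    pairs: list[tuple[ReadPlacement, ReadPlacement]],
    insert_size: float,
    min_span: int = 3,
) -> list[tuple[int, int]]:
    """Cut a contig where too few mate pairs bridge a point.

    For each interior position t the spanning count is the number of pairs
    with one read entirely left of t and the other entirely right.  Within
    the interior region [insert, length - insert] (ends cannot be spanned),
    each maximal run of positions with count < ``min_span`` produces one cut
    at its minimum (leftmost on ties).  Contigs shorter than twice the
    insert size pass through uncut.  Returns the (start, end) segments.
    """
    whole = [(0, contig_length)]
    if contig_length <= 2 * insert_size:
        return whole
    lo, hi = int(insert_size), int(contig_length - insert_size)
    if hi <= lo:
        return whole
    count = np.zeros(hi - lo + 1, dtype=np.int64)
    for pr, pf in pairs:
        left = min(pr.offset + pr.read_length, pf.offset + pf.read_length)
        right = max(pr.offset, pf.offset)
        if right < left:
            continue  # overlapping reads span nothing
        a, b = max(left, lo), min(right, hi)
        if a <= b:
            count[a - lo] += 1
            if b - lo + 1 < count.size:
                count[b - lo + 1] -= 1
    spanning = np.cumsum(count)
    low = spanning < min_span
    cuts: list[int] = []
    i = 0
    while i < low.size:
        if low[i]:
            j = i
            while j < low.size and low[j]:
                j += 1
            region = spanning[i:j]
            cuts.append(lo + i + int(np.argmin(region)))
            i = j
        else:
            i += 1
    if not cuts:
        return whole
    bounds = [0] + cuts + [contig_length]
    return list(zip(bounds, bounds[1:]))


def coverage_filter(
    contig_lengths: dict[str, int],
    placements: list[ReadPlacement],
    mean_cov_factor: float = 2.5,
    local_cov_factor: float = 3.0,
    window: int = 100,
) -> tuple[list[str], set[str]]:
    """Remove repeat-like contigs and reads in local coverage spikes.

    A contig whose mean coverage exceeds ``mean_cov_factor`` times the
    median of contig mean coverages is removed from scaffolding (it is still
    reported as a singleton).  Reads whose placement midpoint falls in a
    window with local coverage above ``local_cov_factor`` times the median
    are excluded from pairing.  Returns (removed contig ids, excluded read
    ids).
    """
    arrays = {
        cid: np.zeros(length + 1) for cid, length in contig_lengths.items()
    }
    for p in placements:
        arr = arrays.get(p.contig_id)
        if arr is None:
            continue
        a = min(p.offset, len(arr) - 1)
        b = min(p.offset + p.read_length, len(arr) - 1)
        arr[a] += 1
        arr[b] -= 1
    coverage = {cid: np.cumsum(arr[:-1]) for cid, arr in arrays.items()}
    means = {cid: cov.mean() if cov.size else 0.0 for cid, cov in coverage.items()}
    median = float(np.median(list(means.values()))) if means else 0.0
    removed = sorted(
        cid for cid, m in means.items() if median > 0 and m > mean_cov_factor * median
    )
    excluded: set[str] = set()
    if median > 0:
        hot: dict[str, np.ndarray] = {}
        for cid, cov in coverage.items():
            n_win = int(np.ceil(cov.size / window)) if cov.size else 0
            win_means = np.array(
                [cov[w * window : (w + 1) * window].mean() for w in range(n_win)]
            )
            hot[cid] = win_means > local_cov_factor * median
        for p in placements:
            flags = hot.get(p.contig_id)
            if flags is None or not flags.size:
                continue
            mid = min(p.offset + p.read_length // 2, len(coverage[p.contig_id]) - 1)
            if flags[mid // window]:
                excluded.add(p.read_id)
    return removed, excluded
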