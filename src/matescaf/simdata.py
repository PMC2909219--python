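"""Synthetic genomes, contig fragmentations and mate-pair libraries.

This module generates all test inputs for the scaffolder, together with the
ground-truth layout needed for truth-based evaluation: random genomes with
optional planted repeats, tilings of a genome into contigs separated by gaps
(optionally with injected chimeric contigs or a collapsed repeat contig), and
mate-pair / paired-end libraries whose separation distribution is a Gaussian
peak around the insert size on top of an optional uniform background, as seen
in real separation histograms.

Strand geometry follows the platforms: a SOLiD mate pair has both reads on
the same genome strand with F3 to the right of R3; an Illumina paired-end has
the reads on opposite strands facing each other.  Reads falling in gaps or
straddling a contig end are discarded.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .colorspace import BASES, ColorContig, default_error_rates
from .model import SOLID_MATE, Library, MatePair, ReadPlacement

__all__ = [
    "Genome",
    "TruthInterval",
    "ContigTruth",
    "TruthLayout",
    "simulate_genome",
    "fragment_to_contigs",
    "simulate_mate_pairs",
    "simulate_collapsed_repeat",
    "corrupt_colorspace",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    sequence: str
    repeat_loci: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TruthInterval:
    """One genomic source interval of a contig.

    ``strand`` is +1 when the contig stores the genome-forward sequence of
    the interval, -1 when it stores the reverse complement.  The interval
    occupies contig coordinates [contig_offset, contig_offset+length).
    """

    genome_start: int
    length: int
    strand: int
    contig_id: str
    contig_offset: int


@dataclass
class ContigTruth:
    contig_id: str
    length: int
    intervals: list[TruthInterval]
    chimeric: bool = False
    repeat_copy: bool = False


class TruthLayout:
    """Ground truth of a simulated assembly: where every contig came from."""

    def __init__(self, genome_length: int, contigs: dict[str, ContigTruth]):
        self.genome_length = genome_length
        self.contigs = contigs
        entries = [iv for c in contigs.values() for iv in c.intervals]
        entries.sort(key=lambda iv: iv.genome_start)
        self._entries = entries
        self._starts = [iv.genome_start for iv in entries]

    def map_read(
        self, genome_pos: int, read_len: int, genome_strand: int
    ):
        """Map a genome-placed read to (contig_id, offset, same_strand).

        Returns None when the read falls in a gap or straddles a contig end.
        """
        k = bisect.bisect_right(self._starts, genome_pos) - 1
        if k < 0:
            return None
        iv = self._entries[k]
        if genome_pos + read_len > iv.genome_start + iv.length:
            return None
        if iv.strand == +1:
            offset = iv.contig_offset + (genome_pos - iv.genome_start)
        else:
            offset = iv.contig_offset + (
                iv.genome_start + iv.length - genome_pos - read_len
            )
        return iv.contig_id, offset, genome_strand * iv.strand

    def genome_order(self) -> list[TruthInterval]:
        """All source intervals in genome order."""
        return list(self._entries)

    def true_adjacencies(self) -> list[tuple[TruthInterval, TruthInterval]]:
        """Consecutive source intervals along the genome."""
        order = self.genome_order()
        return list(zip(order, order[1:]))


def simulate_genome(
    length: int,
    gc_fraction: float = 0.5,
    repeat_spec: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> Genome:
    """i.i.d. random genome at a given GC content with planted exact repeats.

    ``repeat_spec`` is a list of (unit_length, copy_number); each unit is a
    random sequence pasted at non-overlapping random loci, recorded in
    ``Genome.repeat_loci``.
    """
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    seq = rng.choice(list(BASES), size=length, p=probs)
    loci: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []
    for unit_len, copies in repeat_spec or []:
        if unit_len > length:
            raise ValueError("repeat unit longer than genome")
        unit = rng.choice(list(BASES), size=unit_len, p=probs)
        placed = 0
        attempts = 0
        while placed < copies:
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not place repeat copies")
            start = int(rng.integers(0, length - unit_len + 1))
            if any(start < e and start + unit_len > s for s, e in occupied):
                continue
            seq[start : start + unit_len] = unit
            occupied.append((start, start + unit_len))
            loci.append((start, unit_len))
            placed += 1
    return Genome("".join(seq), loci)


def _default_gap_model(rng: np.random.Generator) -> int:
    # gap lengths as multiples of 50, matching the scaffolder's N-run grid
    return int(rng.integers(1, 7)) * 50


def fragment_to_contigs(
    genome: Genome | str,
    n_contigs: int,
    gap_model=None,
    chimera_count: int = 0,
    seed: int = 0,
    min_contig: int = 300,
    random_strands: bool = True,
) -> tuple[dict[str, str], TruthLayout]:
    """Tile a genome into contigs separated by gaps; optionally inject chimeras.

    The genome is cut into ``n_contigs`` non-overlapping contigs with gaps
    drawn from ``gap_model`` (a callable taking the RNG; default: uniform
    multiples of 50 in [50, 300]).  Each contig is stored on a random strand
    when ``random_strands``.  ``chimera_count`` randomly chosen non-adjacent
    contig pairs are concatenated into chimeric contigs whose truth records
    both source intervals.
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome
    glen = len(seq)
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    rng = np.random.default_rng(seed)
    gap_model = gap_model or _default_gap_model
    gaps = [gap_model(rng) for _ in range(n_contigs - 1)]
    covered = glen - sum(gaps)
    extra = covered - n_contigs * min_contig
    if extra < 0:
        raise ValueError("too many contigs for this genome length")
    cuts = np.sort(rng.integers(0, extra + 1, size=n_contigs - 1))
    parts = np.diff(np.concatenate(([0], cuts, [extra])))
    lengths = [min_contig + int(p) for p in parts]

    contigs: dict[str, str] = {}
    truths: dict[str, ContigTruth] = {}
    pos = 0
    for k, clen in enumerate(lengths):
        cid = f"contig_{k:04d}"
        sub = seq[pos : pos + clen]
        strand = int(rng.choice([1, -1])) if random_strands else 1
        stored = sub if strand == 1 else reverse_complement(sub)
        contigs[cid] = stored
        truths[cid] = ContigTruth(
            cid, clen, [TruthInterval(pos, clen, strand, cid, 0)]
        )
        pos += clen
        if k < n_contigs - 1:
            pos += gaps[k]

    ids = list(contigs)
    used: set[str] = set()
    for c in range(chimera_count):
        candidates = [
            (a, b)
            for i, a in enumerate(ids)
            for j, b in enumerate(ids)
            if a not in used and b not in used and abs(i - j) >= 2 and i < j
        ]
        if not candidates:
            raise ValueError("not enough non-adjacent contigs for chimeras")
        a, b = candidates[int(rng.integers(len(candidates)))]
        used.update((a, b))
        cid = f"chimera_{c:02d}"
        seq_a, seq_b = contigs.pop(a), contigs.pop(b)
        ta, tb = truths.pop(a), truths.pop(b)
        ivs = [
            TruthInterval(iv.genome_start, iv.length, iv.strand, cid, iv.contig_offset)
            for iv in ta.intervals
        ] + [
            TruthInterval(
                iv.genome_start, iv.length, iv.strand, cid,
                iv.contig_offset + ta.length,
            )
            for iv in tb.intervals
        ]
        contigs[cid] = seq_a + seq_b
        truths[cid] = ContigTruth(cid, ta.length + tb.length, ivs, chimeric=True)

    return contigs, TruthLayout(glen, truths)


def simulate_collapsed_repeat(
    n_copies: int = 3,
    unit_length: int = 2000,
    spacer_length: int = 6000,
    gap: int = 100,
    seed: int = 0,
) -> tuple[dict[str, str], TruthLayout, Genome]:
    """A genome with ``n_copies`` exact repeat copies collapsed into one contig.

    The repeat contig's truth records one interval per copy, so simulated
    reads from every copy land on the same contig: its coverage is
    ``n_copies`` times the background, and its mate pairs pull in neighbors
    of all copies — the classic collapsed-repeat tangle.
    """
    rng_seed = seed
    spacers = [
        simulate_genome(spacer_length, seed=rng_seed * 101 + i).sequence
        for i in range(n_copies + 1)
    ]
    unit = simulate_genome(unit_length, seed=rng_seed * 101 + 99).sequence
    pieces: list[str] = []
    contigs: dict[str, str] = {}
    truths: dict[str, ContigTruth] = {}
    repeat_ivs: list[TruthInterval] = []
    pos = 0
    rep_id = "repeat_contig"
    for i, sp in enumerate(spacers):
        # spacer contig (trim a gap on each side)
        c_start, c_len = pos + gap, len(sp) - 2 * gap
        cid = f"spacer_{i}"
        contigs[cid] = sp[gap : gap + c_len]
        truths[cid] = ContigTruth(
            cid, c_len, [TruthInterval(c_start, c_len, 1, cid, 0)]
        )
        pieces.append(sp)
        pos += len(sp)
        if i < n_copies:
            repeat_ivs.append(TruthInterval(pos, unit_length, 1, rep_id, 0))
            pieces.append(unit)
            pos += unit_length
    contigs[rep_id] = unit
    truths[rep_id] = ContigTruth(
        rep_id, unit_length, repeat_ivs, repeat_copy=True
    )
    genome = Genome("".join(pieces), [(iv.genome_start, unit_length) for iv in repeat_ivs])
    return contigs, TruthLayout(len(genome), truths), genome


def simulate_mate_pairs(
    truth: TruthLayout,
    library: Library,
    n_pairs: int,
    seed: int = 0,
) -> tuple[list[ReadPlacement], list[MatePair]]:
    """Draw mate pairs on the genome and convert them to contig placements.

    For a non-background pair the separation between the two reads' start
    coordinates is Normal(insert, sigma) (negative draws redrawn); background
    pairs get a uniform-random second coordinate and strand.  Reads that fall
    in gaps or straddle contig ends are discarded; the pair record is emitted
    only when both reads land.
    """
    rng = np.random.default_rng(seed)
    rl = library.read_length
    ins = library.insert
    sigma = library.sigma if library.sigma is not None else 0.0
    if rl >= ins:
        raise ValueError("read length must be smaller than the insert size")
    glen = truth.genome_length
    hi = glen - rl  # last valid read start

    placements: list[ReadPlacement] = []
    pairs: list[MatePair] = []
    for k in range(n_pairs):
        g_r = 1 if rng.random() < 0.5 else -1
        background = rng.random() < library.background_fraction
        if background:
            pos_r = int(rng.integers(0, hi + 1))
            pos_f = int(rng.integers(0, hi + 1))
            g_f = 1 if rng.random() < 0.5 else -1
        else:
            sep = float(rng.normal(ins, sigma)) if sigma > 0 else float(ins)
            while sep < 0:
                sep = float(rng.normal(ins, sigma))
            sep = int(round(sep))
            if sep > hi:
                continue
            # R start uniform among positions where both reads fit
            if g_r == 1:
                pos_r = int(rng.integers(0, hi - sep + 1))
                pos_f = pos_r + sep
            else:
                pos_r = int(rng.integers(sep, hi + 1))
                pos_f = pos_r - sep
            g_f = g_r if library.kind == SOLID_MATE else -g_r
        hit_r = truth.map_read(pos_r, rl, g_r)
        hit_f = truth.map_read(pos_f, rl, g_f)
        rid, fid = f"p{k}_r", f"p{k}_f"
        if hit_r is not None:
            placements.append(ReadPlacement(rid, hit_r[0], hit_r[1], hit_r[2], rl))
        if hit_f is not None:
            placements.append(ReadPlacement(fid, hit_f[0], hit_f[1], hit_f[2], rl))
        if hit_r is not None and hit_f is not None:
            pairs.append(MatePair(rid, fid, library.name))
    return placements, pairs


def corrupt_colorspace(
    sequence: str,
    coverage: float,
    read_length: int,
    color_error_rate: float,
    seed: int = 0,
) -> ColorContig:
    """Simulate a color-space consensus contig with first-base suggestions.

    The true sequence is encoded to colors; reads tile the contig at the
    given coverage.  Each read contributes color votes over the positions it
    covers and one translated-first-call base suggestion at its start; every
    call is flipped to a uniformly random wrong symbol with probability
    ``color_error_rate``.  The consensus color at each position is the
    majority vote (ties broken toward the smallest color value).
    """
    if not (0.0 <= color_error_rate < 1.0):
        raise ValueError("color_error_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    if n < 2:
        raise ValueError("sequence too short")
    from .colorspace import encode_colors

    true_colors = np.array(encode_colors(sequence), dtype=np.int64)
    base_idx = np.array([BASES.index(b) for b in sequence.upper()])
    n_reads = max(1, int(round(coverage * n / read_length)))
    # deterministic tiling guarantees every color position is covered,
    # the rest of the reads start uniformly at random
    starts = list(range(0, n - read_length + 1, max(1, read_length // 2)))
    if starts[-1] != n - read_length:
        starts.append(n - read_length)
    while len(starts) < n_reads:
        starts.append(int(rng.integers(0, n - read_length + 1)))

    votes = np.zeros((n - 1, 4), dtype=np.int64)
    f = np.zeros((n, 4), dtype=np.float64)
    for s in starts:
        span = true_colors[s : s + read_length - 1].copy()
        if color_error_rate > 0:
            flips = rng.random(len(span)) < color_error_rate
            span[flips] = (span[flips] + rng.integers(1, 4, size=int(flips.sum()))) % 4
        np.add.at(votes, np.arange(s, s + len(span)), np.eye(4, dtype=np.int64)[span])
        # first-base suggestion at the read start
        b = int(base_idx[s])
        if color_error_rate > 0 and rng.random() < color_error_rate:
            b = int((b + rng.integers(1, 4)) % 4)
        f[s, b] += 1
    consensus = votes.argmax(axis=1)  # argmax keeps smallest color on ties
    r_c, r_s = default_error_rates(max(color_error_rate, 1e-4), max(coverage, 1.0))
    return ColorContig(consensus, f, r_c=r_c, r_s=r_s)
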