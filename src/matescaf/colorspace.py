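"""SOLiD di-base color algebra and robust color-space -> base-space translation.

The SOLiD platform reads dinucleotides: each pair of adjacent bases produces
one of four color calls (0-3).  The sixteen dinucleotides fall into four
classes of four (e.g. color 2 covers AG, GA, TC and CT), designed so that the
first base and the color uniquely determine the second base.  Under the
standard code the classes are

    0 = {AA, CC, GG, TT}    1 = {AC, CA, GT, TG}
    2 = {AG, GA, CT, TC}    3 = {AT, TA, CG, GC}

which is exactly XOR arithmetic on the base encoding A=0, C=1, G=2, T=3.

Naive translation walks the color chain from a known reference base; a single
wrong color call corrupts every base downstream.  The robust translator
instead treats the true base sequence as hidden states of a chain model whose
observations are (a) the assembled consensus color sequence and (b) per-position
first-base "suggestions" (one vote per read that starts at that position,
obtained by translating only the read's first color call).  Maximizing the
posterior over base sequences by dynamic programming corrects isolated color
errors instead of propagating them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "BASES",
    "ColorContig",
    "Translation",
    "encode_colors",
    "next_base",
    "color_of",
    "naive_translate",
    "robust_translate",
    "default_error_rates",
    "sequence_log_prob",
]


def color_of(b1: str, b2: str) -> int:
    """Color call for the dinucleotide ``b1 b2``."""
    return _BASE_INDEX[b1] ^ _BASE_INDEX[b2]


def next_base(base: str, color: int) -> str:
    """The base following ``base`` given the color call between them."""
    if color not in (0, 1, 2, 3):
        raise ValueError(f"invalid color call {color!r}")
    return BASES[_BASE_INDEX[base] ^ color]


def encode_colors(sequence: str) -> list[int]:
    """Encode a base sequence (length >= 2) into its N-1 color calls."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("need at least two bases to encode colors")
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid base {exc.args[0]!r}") from None
    return [a ^ b for a, b in zip(idx, idx[1:])]


def naive_translate(reference_base: str, colors) -> str:
    """Iterated single-step decoding from a reference base.

    Returns one base per color call; the reference base itself is not part of
    the output.  A single wrong color corrupts all downstream bases.
    """
    out = []
    b = _BASE_INDEX[reference_base.upper()]
    for c in colors:
        if c not in (0, 1, 2, 3):
            raise ValueError(f"invalid color call {c!r}")
        b ^= c
        out.append(BASES[b])
    return "".join(out)


@dataclass
class ColorContig:
    """A color-space contig with per-position base suggestions.

    ``colors[i]`` is the consensus color call between base positions i and
    i+1 (0-based).  ``suggestions`` has shape (N, 4): ``suggestions[i, b]``
    counts reads whose translated first base votes for base ``BASES[b]`` at
    position i.  ``r_c`` / ``r_s`` are the probabilities that a color call /
    a suggestion is wrong (a wrong symbol is uniform over the 3 alternatives).
    """

    colors: np.ndarray
    suggestions: np.ndarray
    r_c: float = 0.01
    r_s: float = 0.03

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.int64)
        self.suggestions = np.asarray(self.suggestions, dtype=np.float64)
        n = len(self.colors) + 1
        if self.suggestions.shape != (n, 4):
            raise ValueError(
                f"suggestions shape {self.suggestions.shape} != ({n}, 4)"
            )
        if not (0.0 < self.r_c < 1.0 and 0.0 < self.r_s < 1.0):
            raise ValueError("error rates must lie strictly in (0, 1)")
        if np.any((self.colors < 0) | (self.colors > 3)):
            raise ValueError("color calls must be in 0..3")
        if np.any(self.suggestions < 0):
            raise ValueError("suggestion counts must be non-negative")

    @property
    def n_bases(self) -> int:
        return len(self.colors) + 1


@dataclass
class Translation:
    """Result of the robust translation."""

    sequence: str
    color_flags: list[int] = field(default_factory=list)
    suggestion_flags: list[int] = field(default_factory=list)
    log_prob: float = 0.0


def default_error_rates(e_s: float, d: float) -> tuple[float, float]:
    """Map a platform error rate and mean coverage to (r_c, r_s).

    A base suggestion comes from a single read's first color call, so its
    error probability is the platform rate ``e_s`` directly.  A consensus
    color call is averaged over ~d covering reads, so its error probability
    falls with coverage; we use ``e_s / d`` capped to (1e-9, 0.5).
    """
    if not (0.0 < e_s < 1.0):
        raise ValueError("e_s must lie in (0, 1)")
    if d < 1:
        raise ValueError("coverage must be >= 1")
    r_s = e_s
    r_c = min(0.5, e_s / d)
    return max(r_c, 1e-9), r_s


def _log_factors(r_c: float, r_s: float) -> tuple[float, float, float, float]:
    return (
        math.log1p(-r_c),
        math.log(r_c / 3.0),
        math.log1p(-r_s),
        math.log(r_s / 3.0),
    )


def sequence_log_prob(contig: ColorContig, sequence: str) -> float:
    """Log-probability of a candidate base sequence under the chain model.

    Per color position: (1-r_c) if the candidate dinucleotide matches the
    call, else r_c/3.  Per suggestion: (1-r_s) if it votes for the candidate
    base, else r_s/3, each raised to its multiplicity.
    """
    if len(sequence) != contig.n_bases:
        raise ValueError("sequence length does not match contig")
    lc_ok, lc_bad, ls_ok, ls_bad = _log_factors(contig.r_c, contig.r_s)
    idx = [_BASE_INDEX[b] for b in sequence.upper()]
    total = 0.0
    for i, c in enumerate(contig.colors):
        total += lc_ok if (idx[i] ^ idx[i + 1]) == c else lc_bad
    f = contig.suggestions
    for i, bi in enumerate(idx):
        row = f[i]
        total += ls_ok * row[bi] + ls_bad * (row.sum() - row[bi])
    return total


def robust_translate(
    contig: ColorContig, reference_base: str | None = None
) -> Translation:
    """Most probable base sequence given colors and suggestions (Viterbi).

    Forward pass keeps, for each of the four states of base k, the best
    log-probability of a prefix ending in that base plus a backpointer; the
    backtrace starts from the best final base.  Ties prefer the base earlier
    in A < C < G < T, so the result is deterministic even for the degenerate
    no-suggestion input (which is determined only up to the 4-fold color
    symmetry unless ``reference_base`` pins position 1).
    """
    n = contig.n_bases
    lc_ok, lc_bad, ls_ok, ls_bad = _log_factors(contig.r_c, contig.r_s)
    f = contig.suggestions
    totals = f.sum(axis=1)
    # node[i, b]: suggestion score of base b at position i
    node = ls_ok * f + ls_bad * (totals[:, None] - f)
    if reference_base is not None:
        ref = _BASE_INDEX[reference_base.upper()]
        clamp = np.full(4, -math.inf)
        clamp[ref] = 0.0
        node[0] += clamp

    score = node[0].copy()
    back = np.zeros((n, 4), dtype=np.int64)
    for i in range(1, n):
        c = contig.colors[i - 1]
        new = np.full(4, -math.inf)
        for b in range(4):
            best_prev, best_score = 0, -math.inf
            for p in range(4):
                s = score[p] + (lc_ok if (p ^ b) == c else lc_bad)
                if s > best_score:  # strict: ties keep the earlier base
                    best_prev, best_score = p, s
            new[b] = best_score + node[i, b]
            back[i, b] = best_prev
        score = new
    # np.argmax returns the first maximum: alphabetical tie-break
    last = int(np.argmax(score))
    log_prob = float(score[last])
    idx = [0] * n
    idx[-1] = last
    for i in range(n - 1, 0, -1):
        idx[i - 1] = int(back[i, idx[i]])
    sequence = "".join(BASES[b] for b in idx)

    color_flags = [
        i for i, c in enumerate(contig.colors) if (idx[i] ^ idx[i + 1]) != c
    ]
    suggestion_flags = [
        i
        for i in range(n)
        if f[i].sum() > f[i, idx[i]]  # some vote disagrees with the call
    ]
    return Translation(sequence, color_flags, suggestion_flags, log_prob)
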