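"""Independent exhaustive-enumeration oracles.

These deliberately do not share code with the package's solvers: energies
and probabilities are recomputed from their definitions over every candidate
configuration (vectorized so that 2^N / q^N / 4^N enumeration stays fast).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


def ising_minimum(edges: list[tuple[int, int, float]], n: int) -> float:
    """Exact minimum of -sum J_ij s_i s_j over all 2^n spin configurations."""
    assert n <= 20
    states = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
    energy = np.zeros(2**n)
    for i, j, w in edges:
        energy -= w * states[:, i] * states[:, j]
    return float(energy.min())


def potts_minimum(
    couplings: dict[tuple[int, int], float], n: int, q: int
) -> float:
    """Exact minimum of sum w_ij delta(s_i, s_j) over all q^n labelings."""
    total = q**n
    assert total <= 2_000_000
    idx = np.arange(total)
    digits = np.empty((total, n), dtype=np.int8)
    for k in range(n):
        digits[:, k] = idx % q
        idx = idx // q
    energy = np.zeros(total)
    for (i, j), w in couplings.items():
        energy += w * (digits[:, i] == digits[:, j])
    return float(energy.min())


def translation_argmax(
    colors: np.ndarray, suggestions: np.ndarray, r_c: float, r_s: float
) -> tuple[str, float]:
    """Most probable base sequence by scoring all 4^N candidates.

    The probability is the product, over color positions, of (1 - r_c) when
    the candidate dinucleotide encodes the observed color and r_c/3 when
    not, times the product over suggestions of (1 - r_s) or r_s/3 raised to
    the vote multiplicity.  Colors are compared through the standard code in
    which the color equals the XOR of the two base indices.
    """
    n = len(colors) + 1
    total = 4**n
    assert total <= 5_000_000
    idx = np.arange(total)
    digits = np.empty((total, n), dtype=np.int8)
    for k in range(n):
        digits[:, k] = idx % 4
        idx = idx // 4
    log_p = np.zeros(total)
    for i, c in enumerate(colors):
        match = (digits[:, i] ^ digits[:, i + 1]) == c
        log_p += np.where(match, np.log1p(-r_c), np.log(r_c / 3.0))
    for i in range(n):
        votes = suggestions[i]
        total_votes = votes.sum()
        if total_votes == 0:
            continue
        for b in range(4):
            match = digits[:, i] == b
            log_p += np.where(
                match,
                np.log1p(-r_s) * votes[b] + np.log(r_s / 3.0) * (total_votes - votes[b]),
                0.0,
            )
    # ties: the enumeration order is little-endian in the base index, so the
    # first maximum is the lexicographically smallest sequence
    best = int(np.argmax(log_p))
    seq = "".join(BASES[digits[best, k]] for k in range(n))
    return seq, float(log_p[best])
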