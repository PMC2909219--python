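"""Color algebra and robust translation tests."""

import numpy as np
import pytest

from matescaf.colorspace import (
    BASES,
    ColorContig,
    default_error_rates,
    encode_colors,
    naive_translate,
    next_base,
    robust_translate,
    sequence_log_prob,
)

from .oracles import translation_argmax


def random_sequence(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


@pytest.mark.parametrize(
    "seq,colors",
    [("AG", [2]), ("GA", [2]), ("TC", [2]), ("CT", [2]), ("AA", [0]),
     ("CC", [0]), ("ATGC", [3, 1, 3])],
)
def test_encode_known_dinucleotides(seq, colors):
    assert encode_colors(seq) == colors


def test_color_code_structure():
    """Each color class has 4 dinucleotides; (first base, color) determines
    the second base; the code is symmetric and reflexive on color 0."""
    classes = {c: set() for c in range(4)}
    for b1 in BASES:
        for b2 in BASES:
            classes[encode_colors(b1 + b2)[0]].add(b1 + b2)
    assert all(len(v) == 4 for v in classes.values())
    for b in BASES:
        assert encode_colors(b + b) == [0]
        for c in range(4):
            nxt = next_base(b, c)
            assert encode_colors(b + nxt) == [c]
        # bijection for fixed color
    for c in range(4):
        assert len({next_base(b, c) for b in BASES}) == 4


def test_encode_rejects_ambiguous_bases():
    with pytest.raises(ValueError):
        encode_colors("ANGT")
    with pytest.raises(ValueError):
        encode_colors("A")


def test_naive_translate_inverts_encoding():
    rng = np.random.default_rng(7)
    for _ in range(20):
        seq = random_sequence(rng, int(rng.integers(2, 60)))
        assert naive_translate(seq[0], encode_colors(seq)) == seq[1:]
    assert naive_translate("G", []) == ""


def test_naive_translate_propagates_single_error():
    """One flipped color corrupts every downstream base (XOR code)."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        seq = random_sequence(rng, 50)
        colors = encode_colors(seq)
        k = int(rng.integers(0, len(colors)))
        colors[k] ^= int(rng.integers(1, 4))
        out = naive_translate(seq[0], colors)
        downstream_true = seq[1:][k:]
        downstream_out = out[k:]
        mismatches = sum(1 for a, b in zip(downstream_true, downstream_out) if a != b)
        assert mismatches == len(downstream_true)  # every base shifted
        assert out[:k] == seq[1 : k + 1]


def _contig_for(seq, votes_per_pos=2, r_c=0.01, r_s=0.01):
    colors = encode_colors(seq)
    f = np.zeros((len(seq), 4))
    for i, b in enumerate(seq):
        f[i, BASES.index(b)] = votes_per_pos
    return ColorContig(np.array(colors), f, r_c, r_s)


def test_worked_four_base_example():
    """Exact recovery of ATGC from its colors plus two true suggestions per
    position, with and without a corrupted middle color."""
    contig = _contig_for("ATGC")
    t = robust_translate(contig)
    assert t.sequence == "ATGC"
    assert t.color_flags == []

    corrupted = ColorContig(np.array([3, 0, 3]), contig.suggestions, 0.01, 0.01)
    t = robust_translate(corrupted)
    assert t.sequence == "ATGC"
    assert t.color_flags == [1]  # the corrupted middle color is declared wrong


def test_scaling_error_rates_preserves_translation():
    contig = _contig_for("ATGC", r_c=0.01, r_s=0.01)
    doubled = ColorContig(contig.colors, contig.suggestions, 0.02, 0.02)
    assert robust_translate(contig).sequence == robust_translate(doubled).sequence


def test_robust_equals_exhaustive_argmax():
    """DP result matches brute-force enumeration over 4^N candidates for all
    lengths up to 8 across an error-rate grid."""
    rng = np.random.default_rng(9)
    grid = [1e-4, 1e-2, 1e-1]
    for n in range(2, 9):
        for trial in range(6):
            seq = random_sequence(rng, n)
            colors = np.array(encode_colors(seq))
            if rng.random() < 0.5:  # corrupt one color
                k = int(rng.integers(0, n - 1))
                colors[k] ^= int(rng.integers(1, 4))
            f = np.zeros((n, 4))
            for i in range(n):
                if rng.random() < 0.8:
                    b = BASES.index(seq[i]) if rng.random() < 0.9 else int(rng.integers(4))
                    f[i, b] += int(rng.integers(1, 4))
            r_c, r_s = grid[trial % 3], grid[(trial // 2) % 3]
            contig = ColorContig(colors, f, r_c, r_s)
            got = robust_translate(contig)
            want_seq, want_lp = translation_argmax(colors, f, r_c, r_s)
            assert got.log_prob == pytest.approx(want_lp, abs=1e-9)
            if got.sequence != want_seq:  # tie between optima
                assert sequence_log_prob(contig, got.sequence) == pytest.approx(want_lp)


def test_single_error_corrected_across_rate_grid():
    """A lone color error with correct suggestions downstream (at coverage
    density, hence >= 2 within the following 5 positions) is corrected for
    every (r_c, r_s) in the [1e-4, 1e-1]^2 grid."""
    rng = np.random.default_rng(10)
    seq = random_sequence(rng, 30)
    colors = np.array(encode_colors(seq))
    k = 12
    corrupted = colors.copy()
    corrupted[k] ^= 2
    f = np.zeros((30, 4))
    for i in range(30):  # one first-base vote per position, as coverage gives
        f[i, BASES.index(seq[i])] = 1
    for r_c in [1e-4, 1e-3, 1e-2, 1e-1]:
        for r_s in [1e-4, 1e-3, 1e-2, 1e-1]:
            t = robust_translate(ColorContig(corrupted, f, r_c, r_s))
            assert t.sequence == seq, (r_c, r_s)
            assert t.color_flags == [k]


def test_robust_likelihood_never_below_naive():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(5, 40))
        seq = random_sequence(rng, n)
        colors = np.array(encode_colors(seq))
        for _ in range(2):
            colors[int(rng.integers(0, n - 1))] ^= int(rng.integers(1, 4))
        f = np.zeros((n, 4))
        for i in range(0, n, 3):
            f[i, BASES.index(seq[i])] = 1
        contig = ColorContig(colors, f, 0.01, 0.03)
        t = robust_translate(contig)
        naive = seq[0] + naive_translate(seq[0], colors)
        assert t.log_prob >= sequence_log_prob(contig, naive) - 1e-12


def test_no_suggestions_reduces_to_naive_chain():
    rng = np.random.default_rng(12)
    seq = random_sequence(rng, 20)
    colors = np.array(encode_colors(seq))
    contig = ColorContig(colors, np.zeros((20, 4)), 0.01, 0.03)
    t = robust_translate(contig, reference_base=seq[0])
    assert t.sequence == seq[0] + naive_translate(seq[0], colors)[: len(seq) - 1]
    # degenerate no-reference case is still deterministic
    t1 = robust_translate(contig)
    t2 = robust_translate(contig)
    assert t1.sequence == t2.sequence


def test_default_error_rates():
    r_c, r_s = default_error_rates(0.03, 1)
    assert r_s == 0.03
    rates = [default_error_rates(0.03, d)[0] for d in (1, 5, 50, 5000)]
    assert all(a >= b for a, b in zip(rates, rates[1:]))  # decreasing in d
    assert rates[-1] > 0  # floor keeps it a valid probability
    with pytest.raises(ValueError):
        default_error_rates(1.5, 10)
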