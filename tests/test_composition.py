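"""Positional composition, relative dinucleotide bias, and variance descriptors."""

import numpy as np
import pytest

from codonshuffle.composition import (
    DINUCLEOTIDES,
    EmptyInputError,
    FrequencyVector,
    composition_variance,
    gc_vector,
    positional_dinucleotide_counts,
    positional_dinucleotide_freqs,
    positional_nucleotide_counts,
    positional_nucleotide_freqs,
    relative_dinucleotide_bias,
)
from codonshuffle.sequence import translate_cds


def brute_dinucleotide_counts(nt: str, pair: int) -> dict:
    """Oracle: scan the raw string at the pair's codon offsets."""
    out = {}
    n_codons = len(nt) // 3
    for k in range(n_codons):
        if pair == 12:
            d = nt[3 * k] + nt[3 * k + 1]
        elif pair == 23:
            d = nt[3 * k + 1] + nt[3 * k + 2]
        else:  # 31
            if k == n_codons - 1:
                continue
            d = nt[3 * k + 2] + nt[3 * k + 3]
        out[d] = out.get(d, 0) + 1
    return out


def test_positional_nucleotide_freqs_hand_example():
    cds = translate_cds("ATGAAA")  # M, K
    fv = positional_nucleotide_freqs(cds, 3)
    assert fv.as_dict() == {"A": 0.5, "C": 0.0, "G": 0.5, "T": 0.0}


def test_positional_counts_conserve_total_nucleotides(make_random_cds):
    rng = np.random.default_rng(2)
    for _ in range(20):
        cds = make_random_cds(rng, int(rng.integers(5, 80)))
        total = sum(positional_nucleotide_counts(cds, p) for p in (1, 2, 3))
        from collections import Counter

        brute = Counter(cds.nt)
        assert [brute.get(n, 0) for n in "ACGT"] == list(total)


def test_dinucleotide_freqs_hand_examples():
    cds = translate_cds("ACGACGAGAAGA")  # ACG,ACG,AGA,AGA = T,T,R,R
    f23 = positional_dinucleotide_freqs(cds, 23)
    assert f23["CG"] == 0.5
    assert f23["GA"] == 0.5
    f31 = positional_dinucleotide_freqs(cds, 31)  # GA, GA, AA over 3 junctions
    assert f31["GA"] == pytest.approx(2 / 3)
    assert f31["AA"] == pytest.approx(1 / 3)


def test_dinucleotide_counts_match_string_scan_oracle(make_random_cds):
    rng = np.random.default_rng(3)
    for _ in range(50):
        cds = make_random_cds(rng, int(rng.integers(2, 51)), alpha=0.6)
        for pair in (12, 23, 31):
            counts = positional_dinucleotide_counts(cds, pair)
            brute = brute_dinucleotide_counts(cds.nt, pair)
            for i, d in enumerate(DINUCLEOTIDES):
                assert counts[i] == brute.get(d, 0)


def test_pair31_needs_two_codons():
    cds = translate_cds("ATGAAA")
    positional_dinucleotide_counts(cds, 31)  # two codons: fine
    single = translate_cds("AAA")
    with pytest.raises(EmptyInputError):
        positional_dinucleotide_counts(single, 31)


def test_rdb_hand_examples():
    # ACG,TCG,ACA,TCA: f(C2)=1, f(G3)=0.5, observed CG23=0.5 -> RDB 1.0
    cds = translate_cds("ACGTCGACATCA")
    assert relative_dinucleotide_bias(cds, 23)["CG"] == pytest.approx(1.0)
    # ACG,ACG,AGA,AGA: observed 0.5 / (0.5 * 0.5) = 2.0
    cds2 = translate_cds("ACGACGAGAAGA")
    assert relative_dinucleotide_bias(cds2, 23)["CG"] == pytest.approx(2.0)


def test_rdb_identity_reconstructs_observed(make_random_cds):
    rng = np.random.default_rng(4)
    for _ in range(20):
        cds = make_random_cds(rng, int(rng.integers(5, 60)), alpha=0.5)
        for pair in (23, 31):
            t = relative_dinucleotide_bias(cds, pair)
            rec = t.rdb[t.defined] * t.expected[t.defined]
            assert np.allclose(rec, t.observed[t.defined], atol=1e-12)
            # undefined entries are flagged, not zeroed
            assert np.all(np.isnan(t.rdb[~t.defined]))


def analytic_rdb23(third_freqs: np.ndarray) -> np.ndarray:
    """Oracle: expected pair-23 RDB under i.i.d. uniform-amino-acid codon
    choice, from the exact codon distribution.

    The genetic code couples positions 2 and 3 (each family fixes position
    2 and restricts position 3), so pair-23 RDB does not converge to 1 even
    for i.i.d. sequences; it converges to this code-induced value.
    """
    from codonshuffle.genetic_code import standard_code

    code = standard_code()
    joint = np.zeros((4, 4))
    for aa in code.amino_acids:
        codons = code.aa_to_codons[aa]
        w = np.array([third_freqs["ACGT".index(c[2])] for c in codons])
        if w.sum() == 0:
            w = np.ones(len(codons))
        w = w / w.sum() / len(code.amino_acids)
        for codon, wc in zip(codons, w):
            joint["ACGT".index(codon[1]), "ACGT".index(codon[2])] += wc
    expected = np.outer(joint.sum(axis=1), joint.sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (joint / expected).ravel()


def test_iid_sequences_rdb31_is_one_but_rdb23_is_code_induced():
    rng = np.random.default_rng(5)
    from codonshuffle.simulate import generate_random_cds

    cds = generate_random_cds(30000, np.full(4, 0.25), rng)
    # across-junction pairs are independent draws: RDB31 -> 1
    t31 = relative_dinucleotide_bias(cds, 31)
    assert np.nanmax(np.abs(t31.rdb - 1.0)) < 0.12
    # within-codon pairs carry the code's own 2-3 coupling
    t23 = relative_dinucleotide_bias(cds, 23)
    predicted = analytic_rdb23(np.full(4, 0.25))
    mask = t23.defined & np.isfinite(predicted)
    assert np.abs(t23.rdb[mask] - predicted[mask]).max() < 0.12


def test_variance_examples_and_invariance():
    uniform = FrequencyVector(("A", "C", "G", "T"), np.full(4, 0.25))
    assert composition_variance(uniform) == 0.0
    gc = FrequencyVector(("GC", "AT"), np.array([0.6, 0.4]))
    assert composition_variance(gc) == pytest.approx(0.01)
    onehot = FrequencyVector(("A", "C", "G", "T"), np.array([1.0, 0, 0, 0]))
    assert composition_variance(onehot) == pytest.approx(0.1875)
    # permutation invariance and zero-iff-uniform
    rng = np.random.default_rng(6)
    x = rng.dirichlet(np.ones(4))
    v = composition_variance(FrequencyVector(tuple("ACGT"), x))
    for _ in range(5):
        perm = rng.permutation(4)
        assert composition_variance(
            FrequencyVector(tuple("ACGT"), x[perm])
        ) == pytest.approx(v)
    if not np.allclose(x, 0.25):
        assert v > 0


def test_onehot_maximises_variance_on_simplex_grid():
    # brute-force over a coarse simplex grid: nothing beats one-hot
    best = 0.0
    step = 0.1
    n = int(1 / step)
    for i in range(n + 1):
        for j in range(n + 1 - i):
            for k in range(n + 1 - i - j):
                x = np.array([i, j, k, n - i - j - k]) * step
                fv = FrequencyVector(tuple("ACGT"), x)
                best = max(best, composition_variance(fv))
    assert best == pytest.approx(0.1875)


try:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=16)
    )
    def test_variance_properties_on_arbitrary_simplex_vectors(weights):
        x = np.array(weights) / np.sum(weights)
        fv = FrequencyVector(tuple(str(i) for i in range(len(x))), x)
        v = composition_variance(fv)
        assert v >= 0
        # bounded by the one-hot maximum for this state count
        n = len(x)
        onehot = np.zeros(n)
        onehot[0] = 1.0
        vmax = composition_variance(
            FrequencyVector(tuple(str(i) for i in range(n)), onehot)
        )
        assert v <= vmax + 1e-12
        # invariant under reversal (a permutation)
        rev = FrequencyVector(tuple(str(i) for i in range(n)), x[::-1].copy())
        assert composition_variance(rev) == pytest.approx(v)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_gc_vector_collapse():
    cds = translate_cds("ATGAAA")
    fv = gc_vector(positional_nucleotide_freqs(cds, 3))
    assert fv.as_dict() == {"GC": 0.5, "AT": 0.5}


def test_frequency_vector_must_sum_to_one():
    with pytest.raises(ValueError):
        FrequencyVector(("A", "B"), np.array([0.5, 0.4]))
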