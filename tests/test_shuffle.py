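"""Shuffling null models: conservation contracts, uniformity, replicates."""

import itertools
from collections import Counter

import numpy as np
import pytest

from codonshuffle.enc import EncUndefinedError
from codonshuffle.sequence import translate_cds
from codonshuffle.shuffle import (
    MODES,
    ShuffleSpec,
    extract_sites,
    run_shuffle_replicates,
    shuffle_synonymous,
)


def third_counts(cds):
    return Counter(c[2] for c in cds.codons())


def dn23_counts(cds):
    return Counter(c[1] + c[2] for c in cds.codons())


def dn31_counts(cds):
    cod = cds.codons()
    return Counter(cod[k][2] + cod[k + 1][0] for k in range(len(cod) - 1))


def gc3_count(cds):
    return sum(v for k, v in third_counts(cds).items() if k in "GC")


def assert_mode_conservation(original, shuffled, mode):
    """The mode-specific count tables that must survive a shuffle exactly."""
    assert shuffled.aa == original.aa
    for c_orig, c_new in zip(original.codons(), shuffled.codons()):
        assert c_orig[:2] == c_new[:2]
    if mode == "gc3":
        assert abs(gc3_count(shuffled) - gc3_count(original)) <= 1
    if mode == "n3":
        assert third_counts(shuffled) == third_counts(original)
    if mode in ("dn23", "dn231"):
        assert dn23_counts(shuffled) == dn23_counts(original)
    if mode in ("dn31", "dn231"):
        assert dn31_counts(shuffled) == dn31_counts(original)


def test_extract_sites_examples(code):
    sites = extract_sites(translate_cds("ATGTGG"))  # M, W
    assert all(not s.degenerate for s in sites)

    sites = extract_sites(translate_cds("TTTAAA"))  # F, K
    assert sites[0].allowed_third == frozenset("TC")
    assert sites[1].allowed_third == frozenset("AG")
    assert sites[0].n1_next == "A"
    assert sites[1].n1_next is None

    sites = extract_sites(translate_cds("CTGAGT"))  # Leu CUN, Ser AGY
    assert sites[0].family_id == "L4"
    assert sites[0].allowed_third == frozenset("ACGT")
    assert sites[1].family_id == "S2"
    assert sites[1].allowed_third == frozenset("TC")


def test_fully_constrained_sequence_is_identity():
    cds = translate_cds("TTTAAA")  # pool {T, A}: only one feasible arrangement
    rng = np.random.default_rng(0)
    for _ in range(20):
        assert shuffle_synonymous(cds, "n3", rng).nt == cds.nt


@pytest.mark.parametrize("mode", MODES)
def test_conservation_on_random_sequences(mode, make_random_cds):
    rng = np.random.default_rng(20)
    shuffle_rng = np.random.default_rng(21)
    for _ in range(25):
        cds = make_random_cds(rng, int(rng.integers(20, 120)), alpha=0.7)
        out = shuffle_synonymous(cds, mode, shuffle_rng)
        assert_mode_conservation(cds, out, mode)


def test_conservation_ladder(make_random_cds):
    """dn231 satisfies the dn23 and dn31 contracts; dn23/dn31 satisfy n3;
    n3 satisfies gc3 — stronger constraints nest inside weaker ones."""
    rng = np.random.default_rng(22)
    shuffle_rng = np.random.default_rng(23)
    for _ in range(10):
        cds = make_random_cds(rng, 80, alpha=0.7)
        out = shuffle_synonymous(cds, "dn231", shuffle_rng)
        assert dn23_counts(out) == dn23_counts(cds)
        assert dn31_counts(out) == dn31_counts(cds)
        for mode in ("dn23", "dn31"):
            out = shuffle_synonymous(cds, mode, shuffle_rng)
            assert third_counts(out) == third_counts(cds)
        out = shuffle_synonymous(cds, "n3", shuffle_rng)
        assert abs(gc3_count(out) - gc3_count(cds)) <= 1


def test_pool_engine_matches_swap_conservation(make_random_cds):
    rng = np.random.default_rng(24)
    shuffle_rng = np.random.default_rng(25)
    for _ in range(10):
        cds = make_random_cds(rng, 60, alpha=0.7)
        out = shuffle_synonymous(cds, "n3", shuffle_rng, engine="pool")
        assert_mode_conservation(cds, out, "n3")
        out = shuffle_synonymous(cds, "gc3", shuffle_rng, engine="pool")
        assert_mode_conservation(cds, out, "gc3")


def test_dn23_two_thr_toy_visits_both_arrangements():
    cds = translate_cds("ACAACG")  # Thr, Thr: arrangements ACA,ACG / ACG,ACA
    rng = np.random.default_rng(26)
    seen = Counter()
    for _ in range(2000):
        seen[shuffle_synonymous(cds, "dn23", rng).nt] += 1
    assert set(seen) == {"ACAACG", "ACGACA"}
    assert abs(seen["ACAACG"] / 2000 - 0.5) < 0.05


def enumerate_arrangements(cds):
    """Oracle: all distinct feasible third-position arrangements of a toy."""
    sites = extract_sites(cds)
    deg = [s for s in sites if s.degenerate]
    pool = [s.n3 for s in deg]
    feasible = set()
    for perm in set(itertools.permutations(pool)):
        if all(p in s.allowed_third for p, s in zip(perm, deg)):
            feasible.add(perm)
    return deg, feasible


def test_swap_chain_is_uniform_over_arrangements_chi_square():
    # four Ala codons: pool {A, A, C, G} over four 4-fold sites -> 12 arrangements
    cds = translate_cds("GCAGCAGCCGCG")
    deg, feasible = enumerate_arrangements(cds)
    assert len(feasible) == 12
    rng = np.random.default_rng(27)
    seen = Counter()
    reps = 10000
    for _ in range(reps):
        out = shuffle_synonymous(cds, "n3", rng)
        seen[tuple(c[2] for c in out.codons())] += 1
    assert set(seen) <= feasible
    from scipy import stats

    observed = [seen.get(arr, 0) for arr in feasible]
    chi = stats.chisquare(observed)
    assert chi.pvalue > 0.01


def test_replicates_single_arrangement_has_zero_sd():
    # Phe sites must keep T (no C in the pool); everything else is all-A:
    # exactly one feasible arrangement, so the null is degenerate.
    cds = translate_cds("TTT" * 5 + "AAA" * 5 + "GGA" * 5 + "CTA" * 5)
    s = run_shuffle_replicates(cds, ShuffleSpec(mode="n3", replicates=30, seed=1))
    assert s.enc_sd == 0.0
    assert s.enc_mean == pytest.approx(s.enc_original)
    assert not s.call.significant


def test_replicates_summary_statistics(make_random_cds):
    rng = np.random.default_rng(28)
    cds = make_random_cds(rng, 300, alpha=0.5)
    spec = ShuffleSpec(mode="n3", replicates=50, seed=5, keep_replicates=True)
    s = run_shuffle_replicates(cds, spec)
    assert s.replicate_encs.shape == (50,)
    assert s.enc_sd >= 0
    assert s.replicate_encs.min() <= s.enc_mean <= s.replicate_encs.max()
    assert s.enc_mean == pytest.approx(s.replicate_encs.mean())
    assert s.enc_sd == pytest.approx(s.replicate_encs.std(ddof=1))
    # reproducible from the seed
    s2 = run_shuffle_replicates(cds, spec)
    assert np.array_equal(s.replicate_encs, s2.replicate_encs)


def test_met_trp_only_sequence_surfaces_undefined_enc():
    cds = translate_cds("ATGTGGATGTGG")
    with pytest.raises(EncUndefinedError):
        run_shuffle_replicates(cds, ShuffleSpec(mode="n3", replicates=5, seed=0))


def test_protein_conservation_property(make_random_cds):
    rng = np.random.default_rng(29)
    shuffle_rng = np.random.default_rng(30)
    for _ in range(100):
        cds = make_random_cds(rng, int(rng.integers(20, 200)), alpha=0.8)
        mode = MODES[int(rng.integers(len(MODES)))]
        out = shuffle_synonymous(cds, mode, shuffle_rng)
        assert out.aa == cds.aa
        assert translate_cds(out.nt).aa == cds.aa
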