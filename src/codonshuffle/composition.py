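"""Positional nucleotide/dinucleotide composition and bias descriptors.

A codon offers three dinucleotide reading positions: 1-2 (within-codon,
fixed almost entirely by the amino acid), 2-3 (within-codon, third position
variable) and 3-1 (spanning the junction to the next codon).  The relative
dinucleotide bias (RDB) at a position pair is the observed dinucleotide
frequency divided by the product of the positional mononucleotide
frequencies, so that mononucleotide composition alone gives RDB = 1.

The composition-variance descriptor summarises how far a frequency vector
sits from uniform:

    V(x) = (1/n) * sum_i (x_i - 1/n)^2

with n the number of states (2 for GC/AT, 4 for mononucleotides, 16 for
dinucleotides).  V = 0 iff the vector is uniform, and V is invariant under
permutation of the states, which makes it comparable across n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import NUCLEOTIDES, NT_INDEX
from .sequence import CodingSequence, SequenceError

DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)

#: Valid codon-position pairs for dinucleotide statistics.
POSITION_PAIRS = (12, 23, 31)


class EmptyInputError(SequenceError):
    """Statistic requested on an input with no observations."""


@dataclass(frozen=True)
class FrequencyVector:
    """Frequencies over an ordered set of states, with the raw counts."""

    states: tuple[str, ...]
    x: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if np.any(x < -1e-12) or abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    @property
    def n(self) -> int:
        return len(self.states)

    def __getitem__(self, state: str) -> float:
        return float(self.x[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.states, map(float, self.x)))

    def to_frame(self) -> pd.DataFrame:
        data = {"state": self.states}
        if self.counts is not None:
            data["count"] = self.counts
        data["frequency"] = self.x
        return pd.DataFrame(data)


@dataclass(frozen=True)
class RdbTable:
    """Observed/expected ratios for the 16 dinucleotides at one position pair.

    Entries whose expected frequency is zero are *undefined* (NaN in ``rdb``
    with ``defined`` False), never zero: an absent mononucleotide makes the
    ratio meaningless rather than unbiased.
    """

    position_pair: int
    observed: np.ndarray
    expected: np.ndarray
    rdb: np.ndarray
    defined: np.ndarray

    def __getitem__(self, dinucleotide: str) -> float:
        return float(self.rdb[DINUCLEOTIDES.index(dinucleotide)])

    def is_defined(self, dinucleotide: str) -> bool:
        return bool(self.defined[DINUCLEOTIDES.index(dinucleotide)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": DINUCLEOTIDES,
                "observed": self.observed,
                "expected": self.expected,
                "rdb": self.rdb,
            }
        )


def _nt_codes(cds: CodingSequence) -> np.ndarray:
    arr = np.frombuffer(cds.nt.encode("ascii"), dtype=np.uint8)
    lookup = np.full(128, -1, dtype=np.int64)
    for nt, i in NT_INDEX.items():
        lookup[ord(nt)] = i
    return lookup[arr]


def positional_nucleotide_counts(cds: CodingSequence, position: int) -> np.ndarray:
    """Counts of A,C,G,T at one codon position (1, 2 or 3)."""
    if position not in (1, 2, 3):
        raise ValueError(f"codon position must be 1, 2 or 3, got {position}")
    if cds.codon_count == 0:
        raise EmptyInputError(f"{cds.id}: empty sequence")
    codes = _nt_codes(cds)[position - 1 :: 3]
    return np.bincount(codes, minlength=4)


def positional_nucleotide_freqs(cds: CodingSequence, position: int) -> FrequencyVector:
    """Mononucleotide frequencies at one codon position."""
    counts = positional_nucleotide_counts(cds, position)
    return FrequencyVector(tuple(NUCLEOTIDES), counts / counts.sum(), counts)


def positional_dinucleotide_counts(cds: CodingSequence, pair: int) -> np.ndarray:
    """Counts of the 16 dinucleotides read at a codon-position pair.

    Pair 31 spans codon junctions, so the final codon contributes nothing
    and a single-codon sequence has no observations.
    """
    if pair not in POSITION_PAIRS:
        raise ValueError(f"position pair must be one of {POSITION_PAIRS}, got {pair}")
    codes = _nt_codes(cds)
    if pair == 12:
        first, second = codes[0::3], codes[1::3]
    elif pair == 23:
        first, second = codes[1::3], codes[2::3]
    else:  # 31: codon k position 3 with codon k+1 position 1
        if cds.codon_count < 2:
            raise EmptyInputError(
                f"{cds.id}: pair 31 needs at least 2 codons, got {cds.codon_count}"
            )
        first, second = codes[2::3][:-1], codes[3::3]
    return np.bincount(first * 4 + second, minlength=16)


def positional_dinucleotide_freqs(cds: CodingSequence, pair: int) -> FrequencyVector:
    counts = positional_dinucleotide_counts(cds, pair)
    return FrequencyVector(DINUCLEOTIDES, counts / counts.sum(), counts)


def relative_dinucleotide_bias(cds: CodingSequence, pair: int) -> RdbTable:
    """Observed/expected dinucleotide ratios at codon-position pair 23 or 31.

    The expectation for dinucleotide (p, q) is the product of the *genomic*
    positional mononucleotide frequencies, e.g. f(C at 2) x f(G at 3) for
    CG at pair 23, and f(p at 3) x f(q at 1) for pair 31.
    """
    if pair not in (23, 31):
        raise ValueError(f"RDB is defined for pairs 23 and 31, got {pair}")
    observed = positional_dinucleotide_freqs(cds, pair).x
    if pair == 23:
        f_first = positional_nucleotide_freqs(cds, 2).x
        f_second = positional_nucleotide_freqs(cds, 3).x
    else:
        f_first = positional_nucleotide_freqs(cds, 3).x
        f_second = positional_nucleotide_freqs(cds, 1).x
    expected = np.outer(f_first, f_second).ravel()
    defined = expected > 0
    rdb = np.full(16, np.nan)
    np.divide(observed, expected, out=rdb, where=defined)
    return RdbTable(pair, observed, expected, rdb, defined)


def gc_vector(freqs: FrequencyVector) -> FrequencyVector:
    """Collapse a mononucleotide vector to the 2-state (GC, AT) vector."""
    d = freqs.as_dict()
    gc = d["G"] + d["C"]
    return FrequencyVector(("GC", "AT"), np.array([gc, 1.0 - gc]))


def composition_variance(freqs: FrequencyVector) -> float:
    """Mean squared deviation of frequencies from uniform, (1/n) sum (x - 1/n)^2.

    Zero iff uniform; maximal (at fixed n) for a one-hot vector.  The 1/n
    normalisation keeps the descriptor comparable across state-space sizes
    (n = 2 for GC content, 4 for mononucleotides, 16 for dinucleotides).
    """
    x = freqs.x
    n = freqs.n
    return float(np.mean((x - 1.0 / n) ** 2))
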