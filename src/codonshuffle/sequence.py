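"""In-frame coding sequences and their validation.

A :class:`CodingSequence` is the unit every statistic and shuffle operates
on: an in-frame nucleotide string over {A,C,G,T} plus its derived amino-acid
sequence.  RNA input (U) is normalised to T, a single terminal stop codon is
stripped and recorded, and internal stops are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import GeneticCode, NT_INDEX, STOP_SYMBOL, standard_code

logger = logging.getLogger(__name__)

_AMBIGUITY = set("RYSWKMBDHVN")


class SequenceError(ValueError):
    """Base class for coding-sequence validation failures."""


class FrameError(SequenceError):
    """Sequence length is not a positive multiple of three."""


class InternalStopError(SequenceError):
    """A stop codon occurs before the final codon."""

    def __init__(self, codon_idx: int, codon: str):
        self.codon_idx = codon_idx
        self.codon = codon
        super().__init__(f"internal stop codon {codon!r} at codon index {codon_idx}")


class AlphabetError(SequenceError):
    """Sequence contains characters outside the accepted alphabet."""


@dataclass(frozen=True, eq=False)
class CodingSequence:
    """A validated in-frame CDS with its translation.

    Construct via :func:`translate_cds`; direct construction bypasses
    validation and is reserved for code that guarantees the invariants
    (e.g. the shufflers, which never alter the protein).
    """

    id: str
    nt: str
    aa: str
    code: GeneticCode = field(repr=False)
    had_terminal_stop: bool = False
    n_dropped_codons: int = 0

    @property
    def codon_count(self) -> int:
        return len(self.nt) // 3

    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, len(self.nt), 3)]

    def codon_indices(self) -> np.ndarray:
        """Lexicographic codon indices (0..63) as an int array."""
        arr = np.frombuffer(self.nt.encode("ascii"), dtype=np.uint8)
        nt_idx = _NT_LOOKUP[arr].reshape(-1, 3)
        return nt_idx[:, 0] * 16 + nt_idx[:, 1] * 4 + nt_idx[:, 2]

    def codon_counts(self) -> np.ndarray:
        """Counts of the 64 codons in lexicographic order."""
        return np.bincount(self.codon_indices(), minlength=64)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CodingSequence):
            return NotImplemented
        return self.id == other.id and self.nt == other.nt

    def __len__(self) -> int:
        return len(self.nt)


_NT_LOOKUP = np.full(128, -1, dtype=np.int64)
for _nt, _i in NT_INDEX.items():
    _NT_LOOKUP[ord(_nt)] = _i


def translate_cds(
    nt: str,
    code: GeneticCode | None = None,
    id: str = "seq",
    ambiguous: str = "reject",
) -> CodingSequence:
    """Validate and translate an in-frame CDS.

    Parameters
    ----------
    nt:
        Nucleotide sequence; case-insensitive, U accepted and mapped to T.
    code:
        Genetic code; defaults to the standard table.
    id:
        Label carried through to reports.
    ambiguous:
        ``"reject"`` (default) raises on IUPAC ambiguity codes; ``"drop"``
        splices out whole codons containing any ambiguity code (the count is
        logged and recorded on the result).  Dropping joins the flanking
        codons, so junction-spanning dinucleotide statistics around a dropped
        codon refer to the spliced sequence.

    Raises
    ------
    FrameError, AlphabetError, InternalStopError
    """
    if code is None:
        code = standard_code()
    seq = nt.upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise FrameError(f"{id}: length {len(seq)} is not a positive multiple of 3")

    letters = set(seq)
    bad = letters - set("ACGT")
    if bad:
        if ambiguous == "reject" or not bad <= _AMBIGUITY:
            raise AlphabetError(f"{id}: invalid characters {sorted(bad)!r}")
        kept = []
        dropped = 0
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGT"):
                kept.append(codon)
            else:
                dropped += 1
        logger.info("%s: dropped %d codon(s) containing ambiguity codes", id, dropped)
        seq = "".join(kept)
        if not seq:
            raise AlphabetError(f"{id}: no unambiguous codons remain")
        n_dropped = dropped
    else:
        n_dropped = 0

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    had_terminal_stop = False
    if codons and code.codon_to_aa[codons[-1]] == STOP_SYMBOL:
        codons = codons[:-1]
        seq = seq[:-3]
        had_terminal_stop = True
    if not codons:
        raise FrameError(f"{id}: sequence is a bare stop codon")

    aa_chars = []
    for i, codon in enumerate(codons):
        aa = code.codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            raise InternalStopError(i, codon)
        aa_chars.append(aa)

    return CodingSequence(
        id=id,
        nt=seq,
        aa="".join(aa_chars),
        code=code,
        had_terminal_stop=had_terminal_stop,
        n_dropped_codons=n_dropped,
    )


def from_codons(codons: list[str], code: GeneticCode | None = None, id: str = "seq") -> CodingSequence:
    """Build a CDS from an explicit codon list (convenience for tests/toys)."""
    return translate_cds("".join(codons), code=code, id=id)
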