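"""Genetic-code bookkeeping: synonymous families and the six-fold split.

Synonymous codons encoding one amino acid form a *degeneracy family*.  For
the shuffling algorithms every family must share codon positions 1 and 2, so
that exchanging third-position nucleotides between member codons never
touches the rest of the reading frame.  The three six-fold degenerate amino
acids (Leu, Ser, Arg) violate this, so they are split into a two-fold and a
four-fold sub-family:

    Leu -> UUR (2-fold) + CUN (4-fold)
    Ser -> AGY (2-fold) + UCN (4-fold)
    Arg -> AGR (2-fold) + CGN (4-fold)

The effective-number-of-codons statistic, by contrast, scores Leu/Ser/Arg as
whole six-fold families; both views live on :class:`GeneticCode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

#: All 64 codons in lexicographic (A<C<G<T) order; index = 16*p1 + 4*p2 + p3.
CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_SYMBOL = "*"

# Explicit 2-fold/4-fold sub-family membership for the six-fold amino acids.
_SIXFOLD_SPLIT = {
    "L": {"2": ("TTA", "TTG"), "4": ("CTA", "CTC", "CTG", "CTT")},
    "S": {"2": ("AGC", "AGT"), "4": ("TCA", "TCC", "TCG", "TCT")},
    "R": {"2": ("AGA", "AGG"), "4": ("CGA", "CGC", "CGG", "CGT")},
}


@dataclass(frozen=True)
class Family:
    """A synonymous-codon family whose members share codon positions 1-2."""

    id: str
    aa: str
    codons: tuple[str, ...]
    allowed_third: frozenset[str]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)

    @property
    def prefix(self) -> str:
        """The shared first two nucleotides of every member codon."""
        return self.codons[0][:2]


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon table together with its synonymous-family structure.

    ``families`` holds the six-fold-split view used by the shufflers (every
    family shares positions 1-2); ``aa_to_codons`` holds the whole-amino-acid
    view used by the effective-number-of-codons statistic.
    """

    name: str
    codon_to_aa: dict[str, str]  # 64 entries; stops map to "*"
    stop_codons: frozenset[str]
    families: dict[str, Family] = field(repr=False)
    family_of_codon: dict[str, str] = field(repr=False)
    aa_to_codons: dict[str, tuple[str, ...]] = field(repr=False)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if c not in self.stop_codons)

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def degeneracy_class(self, aa: str) -> int:
        """Whole-family degeneracy of an amino acid (1, 2, 3, 4 or 6)."""
        return len(self.aa_to_codons[aa])

    @property
    def aa_index(self) -> np.ndarray:
        """Per-codon amino-acid index (0..n_aa-1; stops = -1), codon order."""
        return _aa_index_array(self)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.aa_to_codons))


def _build_families(codon_to_aa: dict[str, str]) -> dict[str, Family]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        if aa != STOP_SYMBOL:
            by_aa.setdefault(aa, []).append(codon)

    families: dict[str, Family] = {}
    for aa, codons in sorted(by_aa.items()):
        if aa in _SIXFOLD_SPLIT:
            for tag, members in _SIXFOLD_SPLIT[aa].items():
                fid = f"{aa}{tag}"
                families[fid] = Family(
                    id=fid,
                    aa=aa,
                    codons=tuple(sorted(members)),
                    allowed_third=frozenset(c[2] for c in members),
                )
            continue
        # Ordinary families already share positions 1-2 in the standard code,
        # except Ile/Met/Trp-style singletons which do so trivially.
        prefixes = {c[:2] for c in codons}
        for prefix in sorted(prefixes):
            members = tuple(sorted(c for c in codons if c[:2] == prefix))
            fid = aa if len(prefixes) == 1 else f"{aa}_{prefix}"
            families[fid] = Family(
                id=fid,
                aa=aa,
                codons=members,
                allowed_third=frozenset(c[2] for c in members),
            )
    return families


@lru_cache(maxsize=None)
def _standard_code() -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa = {c: table.forward_table.get(c, STOP_SYMBOL) for c in CODONS}
    families = _build_families(codon_to_aa)
    family_of_codon = {
        codon: fam.id for fam in families.values() for codon in fam.codons
    }
    by_aa: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        if aa != STOP_SYMBOL:
            by_aa.setdefault(aa, []).append(codon)
    return GeneticCode(
        name="standard",
        codon_to_aa=codon_to_aa,
        stop_codons=frozenset(table.stop_codons),
        families=families,
        family_of_codon=family_of_codon,
        aa_to_codons={aa: tuple(sorted(cs)) for aa, cs in by_aa.items()},
    )


def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI translation table 1)."""
    return _standard_code()


@lru_cache(maxsize=None)
def _aa_index_array(code: GeneticCode) -> np.ndarray:
    aas = code.amino_acids
    aa_pos = {aa: i for i, aa in enumerate(aas)}
    idx = np.full(64, -1, dtype=np.int64)
    for i, codon in enumerate(CODONS):
        aa = code.codon_to_aa[codon]
        if aa != STOP_SYMBOL:
            idx[i] = aa_pos[aa]
    return idx


def codon_index(codon: str) -> int:
    """Lexicographic index of a codon (A<C<G<T), 0..63."""
    return CODON_INDEX[codon]
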