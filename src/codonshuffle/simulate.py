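"""Random coding sequences with controlled third-position composition.

The generator emulates a mutational-pressure-only world: amino acids are
drawn i.i.d. (uniform over the 20 by default) and, within each synonymous
family, the codon is chosen with probability proportional to a target
third-position nucleotide frequency vector restricted and renormalised to
the family's allowed third-position set.  Sweeping the target vector over
the simplex therefore produces sequences whose codon usage bias is driven
purely by third-position composition, the reference panel against which
ENC-vs-composition structure is judged.

The ``extreme`` frequency sampler draws from a sparse symmetric Dirichlet
(alpha = 0.3) so that a 1000-draw panel covers both near-vertex (one
nucleotide dominating) and near-uniform compositions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .composition import FrequencyVector
from .genetic_code import CODONS, GeneticCode, NUCLEOTIDES, standard_code
from .sequence import CodingSequence

logger = logging.getLogger(__name__)

#: Symmetric Dirichlet concentration of the "extreme" composition sampler.
EXTREME_ALPHA = 0.3

_CODON_ARR = np.array(CODONS)


@dataclass(frozen=True)
class SimulationSpec:
    """Panel-generation settings.

    Defaults produce 1000 sequences of 3334 codons (10002 nt) with
    independently sampled extreme third-position compositions.
    """

    n_sequences: int = 1000
    n_codons: int = 3334
    seed: int = 0
    strategy: str = "extreme"
    alpha: float = EXTREME_ALPHA
    fixed_freqs: FrequencyVector | None = None
    aa_distribution: np.ndarray | None = None
    cpg23_suppression: float = 1.0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


def sample_third_position_frequencies(
    rng: np.random.Generator,
    strategy: str = "extreme",
    alpha: float | None = None,
    fixed: FrequencyVector | np.ndarray | None = None,
) -> FrequencyVector:
    """Draw a target third-position frequency vector over {A,C,G,T}.

    ``extreme`` uses a symmetric Dirichlet with alpha = 0.3; ``dirichlet``
    uses the supplied alpha; ``fixed`` returns the given vector unchanged.
    """
    if strategy == "fixed":
        if fixed is None:
            raise ValueError("fixed strategy requires a frequency vector")
        if isinstance(fixed, FrequencyVector):
            return fixed
        return FrequencyVector(tuple(NUCLEOTIDES), np.asarray(fixed, dtype=float))
    if strategy == "extreme":
        alpha = EXTREME_ALPHA
    elif strategy == "dirichlet":
        if alpha is None or alpha <= 0:
            raise ValueError("dirichlet strategy requires alpha > 0")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    x = rng.dirichlet(np.full(4, alpha))
    return FrequencyVector(tuple(NUCLEOTIDES), x)


def _codon_weight_tables(
    code: GeneticCode, third_freqs: np.ndarray, cpg23_suppression: float
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-amino-acid cumulative codon-choice distributions."""
    cum_tables: list[np.ndarray] = []
    codon_ids: list[np.ndarray] = []
    fallback = []
    for aa in code.amino_acids:
        codons = code.aa_to_codons[aa]
        ids = np.array([CODONS.index(c) for c in codons])
        w = np.array([third_freqs[NUCLEOTIDES.index(c[2])] for c in codons])
        if cpg23_suppression != 1.0:
            cg = np.array([c[1] == "C" and c[2] == "G" for c in codons])
            w = np.where(cg, w * cpg23_suppression, w)
        if w.sum() == 0:
            w = np.ones(len(codons))  # zero-mass family: uniform fallback
            fallback.append(aa)
        cum_tables.append(np.cumsum(w / w.sum()))
        codon_ids.append(ids)
    if fallback:
        logger.info(
            "zero third-position mass for families %s; using uniform codon choice",
            ",".join(fallback),
        )
    return cum_tables, codon_ids


def generate_random_cds(
    n_codons: int,
    third_freqs: FrequencyVector | np.ndarray,
    rng: np.random.Generator,
    aa_distribution: np.ndarray | None = None,
    cpg23_suppression: float = 1.0,
    code: GeneticCode | None = None,
    id: str = "sim",
) -> CodingSequence:
    """An i.i.d. random CDS whose synonymous codon choice follows ``third_freqs``.

    ``cpg23_suppression`` multiplies the weight of codons that would create
    a CG dinucleotide at positions 2-3 (NCG codons); values below 1 plant a
    within-codon CpG depletion on top of the mononucleotide target.
    """
    if code is None:
        code = standard_code()
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    freqs = third_freqs.x if isinstance(third_freqs, FrequencyVector) else np.asarray(third_freqs, dtype=float)
    n_aa = len(code.amino_acids)
    p = (
        np.full(n_aa, 1.0 / n_aa)
        if aa_distribution is None
        else np.asarray(aa_distribution, dtype=float) / np.sum(aa_distribution)
    )
    cum_tables, codon_ids = _codon_weight_tables(code, freqs, cpg23_suppression)

    aa_idx = rng.choice(n_aa, size=n_codons, p=p)
    codon_idx = np.empty(n_codons, dtype=np.int64)
    for a in range(n_aa):
        pos = np.nonzero(aa_idx == a)[0]
        if len(pos) == 0:
            continue
        pick = np.searchsorted(cum_tables[a], rng.random(len(pos)), side="right")
        pick = np.minimum(pick, len(codon_ids[a]) - 1)  # guard fp edge at 1.0
        codon_idx[pos] = codon_ids[a][pick]

    nt = "".join(_CODON_ARR[codon_idx])
    aa = "".join(code.amino_acids[a] for a in aa_idx)
    return CodingSequence(id=id, nt=nt, aa=aa, code=code)


def generate_panel(
    spec: SimulationSpec, return_targets: bool = False
) -> list[CodingSequence] | tuple[list[CodingSequence], np.ndarray]:
    """Generate the simulated panel; reproducible byte-for-byte from ``seed``."""
    rng = np.random.default_rng(spec.seed)
    code = standard_code()
    seqs: list[CodingSequence] = []
    targets = np.empty((spec.n_sequences, 4))
    width = len(str(spec.n_sequences))
    for i in range(spec.n_sequences):
        fv = sample_third_position_frequencies(
            rng, strategy=spec.strategy, alpha=spec.alpha, fixed=spec.fixed_freqs
        )
        targets[i] = fv.x
        seqs.append(
            generate_random_cds(
                spec.n_codons,
                fv,
                rng,
                aa_distribution=spec.aa_distribution,
                cpg23_suppression=spec.cpg23_suppression,
                code=code,
                id=f"sim_{i + 1:0{width}d}",
            )
        )
    if return_targets:
        return seqs, targets
    return seqs
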