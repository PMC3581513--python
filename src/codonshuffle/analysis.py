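"""Dataset-level comparative analyses.

Two analyses dissect where composition pressure acts:

* positional CpG comparison — is the CG dinucleotide more suppressed
  within codons (positions 2-3) than across codon junctions (3-1)?
* amino-acid preference — does third-position nucleotide content predict
  the choice between chemically compatible amino acids (Ile vs Leu,
  Val vs Leu) while leaving incompatible pairs (Arg vs Gly) untouched?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    positional_nucleotide_counts,
    positional_nucleotide_freqs,
    relative_dinucleotide_bias,
)
from .sequence import CodingSequence

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    """Two groups of per-sequence statistics and their t-test."""

    group_a: np.ndarray
    group_b: np.ndarray
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    p_value: float
    rho: float | None = None
    n_dropped: int = 0


def cpg_positional_comparison(
    dataset: list[CodingSequence], equal_var: bool = True
) -> ComparisonResult:
    """Compare relative CpG bias at codon positions 2-3 vs 3-1 across a dataset.

    Group A holds each sequence's RDB(CG) at pair 2-3, group B at pair 3-1;
    the p-value is a two-sided two-sample Student's t-test (equal-variance
    by default, Welch via ``equal_var=False``).  Sequences with an undefined
    RDB at either pair are dropped pairwise with a logged count.
    """
    if len(dataset) < 2:
        raise AnalysisError("need at least 2 sequences")
    a, b = [], []
    dropped = 0
    for cds in dataset:
        r23 = relative_dinucleotide_bias(cds, 23)
        r31 = relative_dinucleotide_bias(cds, 31)
        if r23.is_defined("CG") and r31.is_defined("CG"):
            a.append(r23["CG"])
            b.append(r31["CG"])
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d sequence(s) with undefined CpG RDB", dropped)
    if len(a) < 2:
        raise AnalysisError("fewer than 2 sequences with defined CpG RDB")
    a = np.array(a)
    b = np.array(b)
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        group_a=a,
        group_b=b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        p_value=float(t.pvalue),
        n_dropped=dropped,
    )


@dataclass(frozen=True)
class PreferenceAnalysis:
    """Per-sequence compatible-amino-acid ratios and their rank correlations.

    ``table`` has one row per sequence (ile_leu, val_leu, arg_gly ratios;
    a3/g3 third-position frequencies; c12 and c3 cytosine frequencies);
    ``correlations`` maps each pairing to its Spearman (rho, p-value),
    computed with average ranks for ties and NaN rows omitted.
    """

    table: pd.DataFrame
    correlations: dict[str, tuple[float, float]]
    n_excluded: int = 0


#: The rank-correlation pairings reported by the preference analysis.
PREFERENCE_PAIRINGS = {
    "ile_leu_vs_a3": ("ile_leu", "a3"),
    "val_leu_vs_g3": ("val_leu", "g3"),
    "arg_gly_vs_g3": ("arg_gly", "g3"),
    "c12_vs_c3": ("c12", "c3"),
}


def amino_acid_preference_analysis(dataset: list[CodingSequence]) -> PreferenceAnalysis:
    """Relate protein-level amino-acid choice to synonymous-site composition.

    Sequences without any leucine are excluded (their Ile/Leu and Val/Leu
    ratios are undefined); an Arg/Gly ratio with zero glycine is NaN and is
    omitted pairwise from its correlation.
    """
    rows = []
    excluded = 0
    for cds in dataset:
        n_leu = cds.aa.count("L")
        if n_leu == 0:
            excluded += 1
            continue
        n_gly = cds.aa.count("G")
        f1 = positional_nucleotide_counts(cds, 1)
        f2 = positional_nucleotide_counts(cds, 2)
        f3 = positional_nucleotide_freqs(cds, 3)
        c12 = (f1[1] + f2[1]) / (f1.sum() + f2.sum())  # index 1 = C
        rows.append(
            {
                "id": cds.id,
                "ile_leu": cds.aa.count("I") / n_leu,
                "val_leu": cds.aa.count("V") / n_leu,
                "arg_gly": cds.aa.count("R") / n_gly if n_gly else np.nan,
                "a3": f3["A"],
                "g3": f3["G"],
                "c12": float(c12),
                "c3": f3["C"],
            }
        )
    if excluded:
        logger.info("excluded %d sequence(s) without leucine", excluded)
    if len(rows) < 3:
        raise AnalysisError("need at least 3 usable sequences for correlations")
    table = pd.DataFrame(rows)
    correlations = {}
    for name, (xcol, ycol) in PREFERENCE_PAIRINGS.items():
        res = stats.spearmanr(table[xcol], table[ycol], nan_policy="omit")
        correlations[name] = (float(res.statistic), float(res.pvalue))
    return PreferenceAnalysis(table=table, correlations=correlations, n_excluded=excluded)
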