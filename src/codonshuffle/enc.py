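"""Wright's effective number of codons (ENC) and the ENC-GC3 curve.

ENC summarises codon usage bias in a single number between 20 (extreme
bias, one codon per amino acid) and 61 (all synonymous codons used evenly).
Per amino-acid family the codon *homozygosity* F is estimated and averaged
within degeneracy classes; ENC combines the class means as

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where the constants count the amino acids per class (9 two-fold, Ile the
lone three-fold, 5 four-fold, Leu/Ser/Arg six-fold) and the leading 2
counts the non-degenerate Met and Trp.

Two homozygosity estimators are provided.  The *corrected* (default,
small-sample-unbiased) form is

    F_hat = (n * sum_i p_i^2 - 1) / (n - 1)

for a family observed n times with within-family codon frequencies p_i;
the *frequency* form is simply F = sum_i p_i^2 and attains the exact
61-codon limit on perfectly even usage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import CODONS, GeneticCode, standard_code
from .sequence import CodingSequence, SequenceError

ENC_MIN = 20.0
ENC_MAX = 61.0

#: Amino acids per degeneracy class under the standard code (whole families).
CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


class EncUndefinedError(SequenceError):
    """ENC cannot be computed: a required degeneracy class has no usable family."""


@dataclass(frozen=True)
class EncResult:
    """ENC together with the per-family homozygosity estimates behind it."""

    enc: float
    family_homozygosity: dict[str, tuple[float, int]]  # aa -> (F, n codons)
    class_means: dict[int, float]
    estimator: str
    capped: bool
    raw_enc: float
    used_class3_fallback: bool = False

    def __float__(self) -> float:
        return self.enc


@dataclass(frozen=True)
class SignificanceCall:
    """Shuffled-vs-original ENC difference and its significance.

    ``delta`` is mean shuffled ENC minus original ENC; a magnitude strictly
    above ``threshold`` (default 1.0, chosen well above the replicate SDs
    seen in practice) is called significant.
    """

    delta: float
    threshold: float
    significant: bool


def family_homozygosities(
    counts: np.ndarray | dict[str, int],
    code: GeneticCode | None = None,
    estimator: str = "corrected",
) -> dict[str, tuple[float, int]]:
    """Per-amino-acid homozygosity estimates from codon counts.

    Families observed at most once are omitted (their estimate is undefined
    or degenerate).  Six-fold amino acids are scored as whole families.
    """
    if code is None:
        code = standard_code()
    if estimator not in ("corrected", "frequency"):
        raise ValueError(f"unknown estimator {estimator!r}")
    counts64 = _as_counts64(counts)
    out: dict[str, tuple[float, int]] = {}
    for aa, codons in code.aa_to_codons.items():
        if len(codons) == 1:
            continue
        c = counts64[[CODONS.index(x) for x in codons]]
        n = int(c.sum())
        if n <= 1:
            continue
        p = c / n
        s = float(np.sum(p * p))
        f = (n * s - 1.0) / (n - 1.0) if estimator == "corrected" else s
        out[aa] = (f, n)
    return out


def _as_counts64(counts) -> np.ndarray:
    if isinstance(counts, dict):
        arr = np.zeros(64, dtype=np.int64)
        for codon, k in counts.items():
            arr[CODONS.index(codon.upper().replace("U", "T"))] = k
        return arr
    arr = np.asarray(counts)
    if arr.shape != (64,):
        raise ValueError("expected a length-64 codon count vector")
    return arr


def enc_from_codon_counts(
    counts: np.ndarray | dict[str, int],
    code: GeneticCode | None = None,
    estimator: str = "corrected",
) -> EncResult:
    """ENC from a codon count table (stops, if present, are ignored)."""
    if code is None:
        code = standard_code()
    fams = family_homozygosities(counts, code, estimator)

    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, (f, _n) in fams.items():
        if f <= 0.0:
            # A non-positive corrected estimate carries no usable signal
            # (possible only for tiny n); excluded from its class mean.
            continue
        per_class[code.degeneracy_class(aa)].append(f)

    class_means: dict[int, float] = {}
    for k, vals in per_class.items():
        if vals:
            class_means[k] = float(np.mean(vals))

    used_fallback = False
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        # Wright's treatment of a missing Ile class: average the flanking
        # two-fold and four-fold class means.
        class_means[3] = 0.5 * (class_means[2] + class_means[4])
        used_fallback = True
    missing = [k for k in CLASS_WEIGHTS if k not in class_means]
    if missing:
        raise EncUndefinedError(
            f"no usable family in degeneracy class(es) {missing}; ENC undefined"
        )

    raw = 2.0 + sum(CLASS_WEIGHTS[k] / class_means[k] for k in CLASS_WEIGHTS)
    capped = raw > ENC_MAX
    enc = min(max(raw, ENC_MIN), ENC_MAX)
    return EncResult(
        enc=enc,
        family_homozygosity=fams,
        class_means=class_means,
        estimator=estimator,
        capped=capped,
        raw_enc=raw,
        used_class3_fallback=used_fallback,
    )


def effective_number_of_codons(
    cds: CodingSequence, estimator: str = "corrected"
) -> EncResult:
    """Wright's effective number of codons for a coding sequence."""
    return enc_from_codon_counts(cds.codon_counts(), cds.code, estimator)


def wright_expected_enc(s: float) -> float:
    """Wright's theoretical ENC at third-position GC content ``s``.

    ENC(s) = 2 + s + 29 / (s^2 + (1-s)^2), the expected ENC when codon
    choice is driven purely by a GC-vs-AT bias at the third position; the
    curve is symmetric about s = 0.5 where it peaks at 60.5.
    """
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def classify_enc_difference(
    original: float, shuffled_mean: float, threshold: float = 1.0
) -> SignificanceCall:
    """Call whether shuffled-null ENC differs meaningfully from the original.

    ``delta = shuffled_mean - original``; significant iff |delta| is
    strictly greater than ``threshold``.
    """
    delta = float(shuffled_mean) - float(original)
    return SignificanceCall(
        delta=delta, threshold=float(threshold), significant=abs(delta) > threshold
    )
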