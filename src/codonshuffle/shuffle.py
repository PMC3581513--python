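"""Constraint-preserving synonymous shuffling and the replicate engine.

Five null models permute third-position nucleotides among synonymous codons
while always preserving the encoded protein.  They differ in which
composition statistic of the original sequence is conserved exactly:

========  =============================================================
mode      conserved quantity (besides the protein and positions 1-2)
========  =============================================================
n3        multiset of third-position nucleotides over degenerate sites
gc3       combined G+C count at degenerate third positions (the pool is
          first rebalanced so #G = #C and #A = #T, then redistributed)
dn23      joint (position-2, position-3) dinucleotide counts
dn31      joint (position-3, next position-1) dinucleotide counts
dn231     both dinucleotide tables simultaneously
========  =============================================================

The default mechanism is a lazy random-transposition Markov chain: pairs of
compatible degenerate sites exchange their third-position nucleotides, so
every conservation contract holds exactly by construction and the chain's
stationary distribution is uniform over the reachable arrangements.  Sites
are compatible when each nucleotide is allowed in the other's degeneracy
family and, for the dinucleotide modes, when the flanking context (position
2 and/or the next codon's position 1) matches.  The six-fold amino acids
Leu/Ser/Arg are handled as split 2-fold/4-fold sub-families so positions
1-2 are never touched.

``n3`` and ``gc3`` are also available as pool-and-redistribute methods
(``engine="pool"``): third-position nucleotides are extracted to a pool and
randomly distributed back under the family constraints, restarting on
deadlock.  A generate-to-target-frequencies ``n3_random`` mode draws each
site independently from the pooled frequencies; it conserves composition
only in expectation and is excluded from default reports.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .enc import SignificanceCall, classify_enc_difference, enc_from_codon_counts
from .genetic_code import CODONS, GeneticCode, NUCLEOTIDES, standard_code
from .sequence import CodingSequence

logger = logging.getLogger(__name__)

MODES = ("gc3", "n3", "dn23", "dn31", "dn231")
_COMPARISON_MODES = ("n3_random",)

_MAX_RESTARTS = 100
_ATTEMPT_FACTOR = 20  # cap on swap attempts per requested accepted swap


@dataclass(frozen=True)
class SynonymousSite:
    """Per-codon substrate record for the shuffling algorithms."""

    codon_index: int
    family_id: str
    allowed_third: frozenset[str]
    n2: str
    n3: str
    n1_next: str | None  # None for the final codon

    @property
    def degenerate(self) -> bool:
        return len(self.allowed_third) > 1


@dataclass(frozen=True)
class ShuffleSpec:
    """Configuration of a replicate run."""

    mode: str
    replicates: int = 1000
    seed: int = 0
    swap_sweeps: int = 10
    threshold: float = 1.0
    estimator: str = "corrected"
    engine: str = "swap"
    keep_replicates: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swap_sweeps < 1:
            raise ValueError("swap_sweeps must be >= 1")
        if self.mode.lower() not in MODES + _COMPARISON_MODES:
            raise ValueError(f"unknown shuffle mode {self.mode!r}")


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean/SD of ENC over shuffled replicates and the significance call."""

    mode: str
    enc_original: float
    enc_mean: float
    enc_sd: float
    call: SignificanceCall
    replicates: int
    replicate_encs: np.ndarray | None = field(default=None, repr=False)


def extract_sites(cds: CodingSequence, code: GeneticCode | None = None) -> list[SynonymousSite]:
    """One :class:`SynonymousSite` per codon (stops never appear in a CDS).

    Met/Trp sites have a singleton allowed set and are excluded from every
    shuffle pool; six-fold codons are assigned to their split sub-family.
    """
    if code is None:
        code = cds.code
    codons = cds.codons()
    sites = []
    for k, codon in enumerate(codons):
        fam = code.families[code.family_of_codon[codon]]
        sites.append(
            SynonymousSite(
                codon_index=k,
                family_id=fam.id,
                allowed_third=fam.allowed_third,
                n2=codon[1],
                n3=codon[2],
                n1_next=codons[k + 1][0] if k + 1 < len(codons) else None,
            )
        )
    return sites


class _ShuffleEngine:
    """Precomputed state for repeated shuffles of one CDS under one mode."""

    def __init__(self, cds: CodingSequence, mode: str, swap_sweeps: int = 10,
                 engine: str = "swap"):
        mode = mode.lower()
        if mode not in MODES + _COMPARISON_MODES:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        if engine not in ("swap", "pool"):
            raise ValueError(f"unknown engine {engine!r}")
        if engine == "pool" and mode not in ("n3", "gc3"):
            raise ValueError("the pool engine applies only to modes n3 and gc3")
        self.cds = cds
        self.mode = mode
        self.engine = engine
        self.swap_sweeps = swap_sweeps
        code = cds.code

        idx = cds.codon_indices()
        self.base = (idx // 4) * 4  # 16*p1 + 4*p2
        self.n3_orig = (idx % 4).tolist()
        n_cod = cds.codon_count

        allowed_mask = []
        for codon in cds.codons():
            fam = code.families[code.family_of_codon[codon]]
            m = 0
            for nt in fam.allowed_third:
                m |= 1 << NUCLEOTIDES.index(nt)
            allowed_mask.append(m)
        self.allowed = allowed_mask
        self.n2 = ((idx // 4) % 4).tolist()
        self.n1_next = [(idx[k + 1] // 16) if k + 1 < n_cod else -1 for k in range(n_cod)]

        eligible = [k for k in range(n_cod) if allowed_mask[k].bit_count() > 1]
        if mode in ("dn31", "dn231"):
            # The final codon has no 3-1 junction of its own, but swapping it
            # would rewrite its partner's junction; it stays frozen.
            eligible = [k for k in eligible if k < n_cod - 1]
        self.eligible = eligible

        if mode == "dn23":
            keyf = lambda k: self.n2[k]
        elif mode == "dn31":
            keyf = lambda k: self.n1_next[k]
        elif mode == "dn231":
            keyf = lambda k: (self.n2[k], self.n1_next[k])
        else:
            keyf = lambda k: 0
        buckets: dict = {}
        for k in eligible:
            buckets.setdefault(keyf(k), []).append(k)
        self.buckets = [b for b in buckets.values() if len(b) >= 2]
        sizes = np.array([len(b) for b in self.buckets], dtype=float)
        self.bucket_cum = (np.cumsum(sizes) / sizes.sum()).tolist() if len(sizes) else []

        self.pool_counts = np.zeros(4, dtype=np.int64)
        for k in eligible:
            self.pool_counts[self.n3_orig[k]] += 1

    # -- mechanisms --------------------------------------------------------

    def _swap(self, n3: list[int], rng: np.random.Generator) -> None:
        if not self.buckets:
            return
        target = self.swap_sweeps * len(self.eligible)
        limit = _ATTEMPT_FACTOR * target
        allowed = self.allowed
        cum = self.bucket_cum
        buckets = self.buckets
        accepted = attempts = 0
        chunk = 2048
        while accepted < target and attempts < limit:
            m = min(chunk, limit - attempts)
            u = rng.random((m, 3))
            for a in range(m):
                attempts += 1
                b = buckets[bisect_left(cum, u[a, 0])]
                nb = len(b)
                i = b[int(u[a, 1] * nb)]
                j = b[int(u[a, 2] * nb)]
                ni, nj = n3[i], n3[j]
                # lazy move: i == j or equal nucleotides count as accepted
                if (allowed[i] >> nj) & 1 and (allowed[j] >> ni) & 1:
                    n3[i], n3[j] = nj, ni
                    accepted += 1
                    if accepted >= target:
                        break
        if accepted < target:
            logger.warning(
                "%s/%s: swap chain reached the attempt cap (%d accepted of %d)",
                self.cds.id, self.mode, accepted, target,
            )

    def _redistribute(self, n3: list[int], pool: np.ndarray,
                      rng: np.random.Generator) -> bool:
        """Random constraint-respecting reassignment of a third-position pool.

        Sites are processed most-constrained first (2-fold, then 3-fold,
        then 4-fold families) so unconstrained sites cannot starve the
        constrained ones of their only admissible nucleotides; within a
        constraint level the order and the nucleotide choice (weighted by
        remaining pool counts) are random, with restart on deadlock.  A
        swap-mixing pass afterwards (see ``shuffled_n3``) removes the mild
        arrangement bias this ordering introduces.
        """
        eligible = self.eligible
        allowed = self.allowed
        by_level: dict[int, list[int]] = {}
        for k in eligible:
            by_level.setdefault(allowed[k].bit_count(), []).append(k)
        for _ in range(_MAX_RESTARTS):
            counts = pool.copy()
            assign = {}
            ok = True
            for level in sorted(by_level):
                sites = by_level[level]
                for o in rng.permutation(len(sites)):
                    k = sites[o]
                    mask = allowed[k]
                    choices = [x for x in range(4) if (mask >> x) & 1 and counts[x] > 0]
                    if not choices:
                        ok = False
                        break
                    w = np.array([counts[x] for x in choices], dtype=float)
                    x = choices[int(np.searchsorted(np.cumsum(w) / w.sum(), rng.random()))]
                    assign[k] = x
                    counts[x] -= 1
                if not ok:
                    break
            if ok:
                for k, x in assign.items():
                    n3[k] = x
                return True
        return False

    def _rebalanced_pool(self, rng: np.random.Generator) -> np.ndarray:
        """Set #G = #C and #A = #T in the pool, totals preserved exactly.

        Odd totals leave one unpaired unit, assigned by a fair coin.
        """
        a, c, g, t = (int(self.pool_counts[NUCLEOTIDES.index(x)]) for x in "ACGT")
        out = np.zeros(4, dtype=np.int64)
        gc = g + c
        out[NUCLEOTIDES.index("G")] = gc // 2
        out[NUCLEOTIDES.index("C")] = gc - gc // 2
        if gc % 2 and rng.random() < 0.5:
            out[NUCLEOTIDES.index("G")] += 1
            out[NUCLEOTIDES.index("C")] -= 1
        at = a + t
        out[NUCLEOTIDES.index("A")] = at // 2
        out[NUCLEOTIDES.index("T")] = at - at // 2
        if at % 2 and rng.random() < 0.5:
            out[NUCLEOTIDES.index("A")] += 1
            out[NUCLEOTIDES.index("T")] -= 1
        return out

    # -- public ------------------------------------------------------------

    def shuffled_n3(self, rng: np.random.Generator) -> list[int]:
        """A fresh shuffled third-position assignment (codon order)."""
        n3 = list(self.n3_orig)
        if not self.eligible:
            return n3
        if self.mode == "gc3":
            pool = self._rebalanced_pool(rng)
            if not self._redistribute(n3, pool, rng):
                logger.warning(
                    "%s/gc3: rebalanced pool admits no assignment after %d "
                    "restarts; returning the identity arrangement",
                    self.cds.id, _MAX_RESTARTS,
                )
                return list(self.n3_orig)
            self._swap(n3, rng)  # mix arrangements of the rebalanced pool
        elif self.mode == "n3" and self.engine == "pool":
            if not self._redistribute(n3, self.pool_counts, rng):
                logger.warning(
                    "%s/n3: pool redistribution deadlocked %d times; "
                    "returning the identity arrangement",
                    self.cds.id, _MAX_RESTARTS,
                )
                return list(self.n3_orig)
        elif self.mode == "n3_random":
            freqs = self.pool_counts / self.pool_counts.sum()
            for k in self.eligible:
                mask = self.allowed[k]
                w = np.array([freqs[x] if (mask >> x) & 1 else 0.0 for x in range(4)])
                if w.sum() == 0:
                    w = np.array([float((mask >> x) & 1) for x in range(4)])
                w = w / w.sum()
                n3[k] = int(np.searchsorted(np.cumsum(w), rng.random()))
        else:
            self._swap(n3, rng)
        return n3

    def to_sequence(self, n3: list[int]) -> CodingSequence:
        codon_idx = self.base + np.asarray(n3)
        nt = "".join(CODONS[i] for i in codon_idx)
        return CodingSequence(
            id=self.cds.id, nt=nt, aa=self.cds.aa, code=self.cds.code,
            had_terminal_stop=self.cds.had_terminal_stop,
        )

    def codon_counts(self, n3: list[int]) -> np.ndarray:
        return np.bincount(self.base + np.asarray(n3), minlength=64)


def shuffle_synonymous(
    cds: CodingSequence,
    mode: str,
    rng: np.random.Generator,
    swap_sweeps: int = 10,
    engine: str = "swap",
) -> CodingSequence:
    """Return one shuffled copy of ``cds`` under the given null model.

    The output always translates to the same protein and keeps codon
    positions 1-2 untouched; the mode decides which composition table is
    conserved (see module docstring).
    """
    eng = _ShuffleEngine(cds, mode, swap_sweeps=swap_sweeps, engine=engine)
    return eng.to_sequence(eng.shuffled_n3(rng))


def run_shuffle_replicates(cds: CodingSequence, spec: ShuffleSpec) -> ReplicateSummary:
    """Shuffle ``spec.replicates`` times and summarise ENC over the null.

    The summary reports the sample mean and SD (n-1 denominator) of ENC over
    replicates plus the significance call on mean-minus-original; it is
    fully reproducible from ``spec.seed``.
    """
    enc_orig = enc_from_codon_counts(cds.codon_counts(), cds.code, spec.estimator).enc
    engine = _ShuffleEngine(cds, spec.mode, swap_sweeps=spec.swap_sweeps,
                            engine=spec.engine)
    rng = np.random.default_rng(spec.seed)
    encs = np.empty(spec.replicates)
    for r in range(spec.replicates):
        counts = engine.codon_counts(engine.shuffled_n3(rng))
        encs[r] = enc_from_codon_counts(counts, cds.code, spec.estimator).enc
    mean = float(encs.mean())
    sd = float(encs.std(ddof=1)) if spec.replicates > 1 else 0.0
    return ReplicateSummary(
        mode=spec.mode.lower(),
        enc_original=enc_orig,
        enc_mean=mean,
        enc_sd=sd,
        call=classify_enc_difference(enc_orig, mean, spec.threshold),
        replicates=spec.replicates,
        replicate_encs=encs if spec.keep_replicates else None,
    )
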