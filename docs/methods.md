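# Methods

## Scope and model

`codonshuffle` treats a coding sequence as a string of codons whose
amino-acid sequence is inviolate. All questions about codon usage bias
(CUB) are posed as comparisons between the observed sequence and null
ensembles that permute synonymous third-position nucleotides under a
stated composition constraint. Nothing is fitted; every number is either
a summary statistic of one sequence or a Monte-Carlo summary of a null
ensemble.

## Degeneracy families and the six-fold split

Codons are grouped into synonymous families. For shuffling, the three
six-fold amino acids are split into sub-families that share codon
positions 1-2 — Leu into UUR + CUN, Ser into AGY + UCN, Arg into AGR +
CGN — so exchanging third positions can never alter positions 1-2. Ile is
the lone 3-fold family (allowed set {A,C,U}); Met and Trp are
non-degenerate and excluded from every shuffle pool. Stop codons never
occur inside a validated `CodingSequence` (a single terminal stop is
stripped on input; internal stops are rejected).

For the ENC statistic, by contrast, Leu/Ser/Arg are scored as whole
six-fold families (the convention of the standard EMBOSS-style
implementation). The two views coexist deliberately: the split is a
mechanical requirement of protein-preserving shuffling, not a scoring
choice.

## Effective number of codons

Per amino-acid family observed n times with within-family codon
frequencies pᵢ, homozygosity is estimated as F̂ = (nΣpᵢ² − 1)/(n − 1)
(corrected, default) or F = Σpᵢ² (frequency form, which attains the exact
61 limit on perfectly even usage and is used for that fixture). Families
with n ≤ 1, and corrected estimates ≤ 0 (possible only at tiny n), carry
no signal and are dropped from their class mean. A missing 3-fold class
(no Ile) is imputed as the mean of the 2- and 4-fold class means; if any
other class is empty ENC is reported undefined rather than guessed.
Values are capped to the nominal [20, 61] range with a `capped` flag;
`raw_enc` retains the uncapped value.

The reference curve ENC(s) = 2 + s + 29/(s² + (1−s)²) is Wright's
published approximation for pure GC₃ pressure. Note two caveats
established empirically here: the curve is not symmetric in s (the +s
term), and it is an *approximation*, not a strict envelope — sequences
simulated under exactly its assumptions (G=C, A=T at third positions)
exceed it by up to ≈ 2.6 ENC units near s ≈ 0.65 and fall ≈ 5 below it at
extreme s, because the curve scores every degeneracy class with the
2-fold homozygosity. Tests therefore assert that the curve tracks the
shape of the simulated ENC ceiling, not that it bounds it.

## Shuffling null models

All five modes are built on one mechanism: a lazy random-transposition
Markov chain over degenerate sites. A proposed pair of sites exchanges
third-position nucleotides if each nucleotide is allowed in the other's
family and, for the dinucleotide modes, the flanking context matches
(equal position-2 nucleotide for `dn23`, equal next-codon position-1 for
`dn31`, both for `dn231`). Because moves are swaps, every conservation
contract holds exactly by construction; because the proposal distribution
is state-independent and symmetric and self-pairs are accepted as lazy
no-ops, the chain's stationary distribution is uniform over the reachable
arrangement set. The default run length is `swap_sweeps` (10) accepted
moves per eligible site, with an attempt cap of 20× that to bound run
time on near-frozen inputs.

`gc3` cannot be a pure swap: its pool is first rebalanced so #G = #C and
#A = #T (totals preserved exactly; an odd total leaves one unit assigned
by a fair coin) and then redistributed under the family constraints.
Redistribution assigns most-constrained sites first (2-fold, then Ile,
then 4-fold) with nucleotide choice weighted by remaining pool counts;
naive random-order assignment deadlocks systematically on asymmetric
compositions because unconstrained sites starve the constrained ones.
Deadlocks restart (≤ 100); a structurally infeasible rebalanced pool
(possible for extreme compositions, e.g. when pyrimidine-only sites
outnumber the rebalanced pyrimidine supply) falls back to the identity
arrangement with a logged warning. A swap-mixing pass follows
redistribution. The same pool machinery is available for `n3`
(`engine="pool"`), and a generate-to-target-frequencies `n3_random` mode
exists for comparison only: it conserves composition in expectation
rather than exactly and produces visibly wider, higher ENC nulls, which
is why exact shuffling is the default throughout.

Two boundary decisions: the final codon has no 3-1 junction, so under
`dn31`/`dn231` its third position is frozen — any swap involving it would
rewrite the partner's junction dinucleotide and break exact conservation.
And sites of different families may exchange nucleotides whenever both
family constraints allow it (the less restrictive of the two defensible
readings); the conserved tables are identical either way.

Replicate runs (default R = 1000; the acceptance-scale studies use
R = 200) report the sample mean and SD (n − 1) of ENC over replicates and
call the difference from the original ENC significant when |mean − orig|
exceeds 1.0 strictly — a threshold set well above the replicate SDs seen
in practice (≈ 0.2–0.6), because formal tests against a Monte-Carlo null
of arbitrary size pass at negligible effect sizes.

## Positional dinucleotide bias

A codon offers pairs 1-2 (amino-acid-fixed), 2-3 (within codon) and 3-1
(across the junction; the final codon contributes nothing, no
wrap-around). Relative dinucleotide bias is observed frequency divided by
the product of the *genomic* positional mononucleotide frequencies;
entries with zero expectation are flagged undefined, never zero.
Concatemers are treated as one continuous CDS, so pair-31 dinucleotides
span ORF junctions.

An interpretation caveat quantified by the test suite: pair-31 RDB of an
i.i.d.-generated sequence converges to 1 (junctions are independent
draws), but pair-23 RDB converges to a code-induced value ≠ 1, because
families fix position 2 while restricting position 3 — under uniform
composition the neutral CpG₂₃ baseline is ≈ 0.896. Observed 2-3 vs 3-1
CpG differences should be read against that baseline, not against 1.

## Composition variance

V(x) = (1/n) Σ(xᵢ − 1/n)², the mean squared deviation from the uniform
vector, with n = 2 (GC/AT), 4 (mononucleotides) or 16 (dinucleotides).
V = 0 iff uniform; permutation-invariant; maximal at a one-hot vector
(0.1875 for n = 4). The 1/n normalisation (rather than 1/(n−1), and no
square root) was fixed once as the reading most consistent with comparing
across n; the choice rescales but never reorders comparisons.

## Simulator

The generator emulates a mutational-pressure-only world: amino acids
i.i.d. uniform over the 20 (a virus-like empirical distribution can be
supplied), and within each family the codon drawn with probability
proportional to a target third-position frequency vector restricted and
renormalised to the family's allowed set. A family with zero restricted
mass falls back to uniform over its codons (logged). An optional
multiplier down-weights NCG codons to plant within-codon CpG depletion.
The default panel is 1000 sequences of 3334 codons (10 002 nt), each with
an independently drawn target composition from a symmetric Dirichlet with
α = 0.3 — sparse enough that a 1000-draw panel contains both near-vertex
(max component > 0.9) and near-uniform (max < 0.5) compositions, each at
well above 5 % frequency. Panels are reproducible byte-for-byte from the
seed.

What the simulator does *not* emulate: phylogenetic correlation,
substitution processes, RNA secondary structure, translational selection,
and amino-acid composition bias beyond the optional weights. Passing
tests on simulated panels therefore demonstrate the statistics' internal
consistency under pure composition pressure, not the behaviour of real
evolving genomes.

Across the default panel, ENC falls steeply with the variance of
third-position mononucleotide frequencies (Spearman ρ ≈ −0.84) and
tightest with the 2-3 dinucleotide-frequency variance (ρ ≈ −0.93), while
showing no monotone relation with raw GC₃ (|ρ| ≈ 0.02). The residual
scatter on the mononucleotide axis is structural: equal-variance
compositions dominated by different nucleotides give different ENC
because the code's family structure is not nucleotide-symmetric.

## Study problem sizes

The bundled studies run at sizes chosen to make their Monte-Carlo
assertions stable: the conservation suite uses 500 random sequences of
20–200 codons across the five modes; the null-ordering study uses one
800-codon sequence generated at third-position target
(A,C,G,T) = (0.10, 0.35, 0.25, 0.30) with NCG weight × 0.05 — an A-poor,
C-rich, strongly CpG-suppressed composition in which mononucleotide and
dinucleotide pressure separate cleanly — at R = 200 replicates per mode;
uniformity of the swap chain is checked by exhaustive enumeration on toys
of ≤ 8 degenerate sites with 10 000 replicates (chi-square, α = 0.01).

## Input handling and degenerate cases

FASTA records are validated individually (frame, alphabet, internal
stops) and failures reported per record without aborting a batch. U is
normalised to T, input case is ignored. IUPAC ambiguity codes are
rejected by default; an opt-in mode splices out whole codons containing
them (with a logged count), which joins the flanking codons and thus
perturbs junction statistics near the splice. GenBank CDS extraction
honours join() coordinates and strand; with overlap exclusion, genomic
positions covered by two or more CDS features are excised codon-wise from
the selected CDS so the frame survives. Concatemer segments are stripped
of terminal stops and validated as one in-frame stop-free unit, with an
optional expected-length check.

Group comparisons use the two-sample equal-variance Student's t-test by
default (Welch by flag); rank correlations are Spearman with average
ranks for ties and pairwise omission of undefined values. Report tables
round to 4 decimals; JSON retains full precision, and identical inputs
plus seed give byte-identical reports (per-sequence, per-mode seeds are
derived from the master seed via `numpy` seed sequences).
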