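# codonshuffle

Dissecting the origins of codon usage bias (CUB) in coding sequences —
especially compact RNA virus genomes — by comparing the observed effective
number of codons against constraint-preserving synonymous null models.

Synonymous codons are not used evenly. The bias can come from
*mutational pressure* (the genome's mono- and dinucleotide composition)
or *translational pressure* (selection for codons matched to the host
tRNA pool). `codonshuffle` separates these layers host-independently: it
shuffles the third positions of synonymous codons while preserving an
increasingly detailed composition constraint, and asks at which level the
observed bias is fully explained.

## The statistic and the null models

Wright's effective number of codons summarises CUB in a single number,

```
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,      20 ≤ ENC ≤ 61,
```

where F̄ₖ is the mean codon "homozygosity" of the k-fold degenerate
amino-acid families, estimated per family as F̂ = (n Σpᵢ² − 1)/(n − 1).
ENC = 61 means all synonymous codons are used evenly; ENC = 20 means one
codon per amino acid. The theoretical curve
ENC(s) = 2 + s + 29/(s² + (1−s)²) gives the expected ENC under pure
GC₃-content pressure.

Five null models shuffle a sequence's synonymous third positions, always
preserving the protein and codon positions 1-2, and each conserving more
of the original composition than the last:

| mode | conserves exactly |
|------|-------------------|
| `gc3` | combined G+C count at synonymous third positions |
| `n3` | the full third-position nucleotide multiset |
| `dn23` | joint position-2/position-3 dinucleotide counts |
| `dn31` | joint position-3/next-position-1 dinucleotide counts |
| `dn231` | both dinucleotide tables simultaneously |

If the mean ENC over shuffled replicates stays within 1 of the original
ENC, the conserved constraint explains the observed bias; an elevation
above 1 marks bias the constraint cannot account for. Companion
statistics — positional relative dinucleotide bias (observed/expected at
codon-position pairs 2-3 and 3-1), composition variance
V = (1/n) Σ(xᵢ − 1/n)², and amino-acid-preference correlations — plus a
simulator of coding sequences with controlled third-position composition
round out the toolkit.

## Worked example

Generate three synthetic "virus-like" sequences (C-rich third positions,
within-codon CpG suppressed) and interrogate them:

```
$ codonshuffle stats demo.fasta
id      codon_count  enc      gc3     var_gc3  var_n3
virus1  600          52.0846  0.615   0.0132   0.0066
virus2  600          51.0315  0.6017  0.0103   0.0072
virus3  600          51.1073  0.6083  0.0117   0.0087

$ codonshuffle --seed 1 shuffle demo.fasta --mode gc3 --replicates 100
id      mode  enc_original  enc_mean  enc_sd   delta   significant
virus1  gc3   52.0846       55.5345   1.0112   3.4499  True
virus2  gc3   51.0315       56.5347   1.2179   5.5033  True
virus3  gc3   51.1073       55.6429   1.1971   4.5356  True

$ codonshuffle --seed 1 shuffle demo.fasta --mode dn23 --replicates 100
id      mode   enc_original  enc_mean  enc_sd   delta    significant
virus1  dn23   52.0846       52.6309   0.9258   0.5463   False
virus2  dn23   51.0315       51.815    0.6997   0.7835   False
virus3  dn23   51.1073       50.9794   1.0628   -0.1279  False
```

Reading: shuffling that preserves only GC₃ raises ENC by 3.4–5.5 — GC
content alone cannot explain the bias in these sequences. Preserving the
2-3 dinucleotide table (`dn23`) reproduces the original ENC within the
significance threshold of 1: mononucleotide plus within-codon dinucleotide
composition explains essentially all of it.

Other subcommands: `enc` (per-sequence ENC with class means), `rdb`
(positional dinucleotide bias tables), `simulate` (random-composition
panels), `concat` (in-frame ORF concatemers from GenBank records) and
`report` (everything at once, JSON + TSV). See `codonshuffle --help`.

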