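# alrscan

Logratio-based compositional data analysis for high-dimensional omics
tables, centred on one question: **which component should serve as the
reference of an additive logratio (ALR) transformation?**

## The problem

Microbiome, transcriptome and metabolome tables are compositional: the
total counts or intensities per sample are an artefact of the assay, so
only relative values carry information. The standard remedy is to analyse
logratios. The simplest logratio transform is Aitchison's ALR,

```
ALR(j | ref) = log(X_j / X_ref),   j = 1, …, J,  j ≠ ref,
```

which turns a samples × components table into J−1 interpretable variables —
but it requires choosing a reference component, and a full ALR set is not
exactly *isometric*: it does not reproduce the exact logratio geometry (the
Euclidean geometry of the samples under all pairwise logratios,
equivalently under the centred logratios, CLRs). How much geometry is lost
depends entirely on the reference.

`alrscan` quantifies that loss for **every** candidate reference and ranks
them. For each candidate r it:

1. builds the ALR set with denominator r and its sample configuration by
   PCA;
2. Procrustes-fits that configuration to the exact one (from logratio
   analysis, the PCA of the CLRs), removing translation, scale and
   rotation;
3. records the Procrustes correlation `R = √(1−E) = trace(D)`, where `E` is
   the scaled residual sum of squares and `D` the singular values of the
   standardised cross-product — `R = 1` means the ALR set is exactly
   isometric;
4. records the variance of `log(X_r / total)` across samples — a
   near-constant reference makes every ALR readable as the log of its
   numerator — together with its five-number summary, zero count and
   abundance rank.

The scan has a brute-force mode and a fast mode using the identity
`ALR(j|r) = CLR(j) − CLR(r)`: the centred ALR Gram matrix of each candidate
is a rank-1 update of the CLR Gram matrix, so all J candidates cost
O(J·I²) plus J small eigendecompositions instead of J full SVDs. The two
modes agree to 1e-10 and both are tested against a frozen independent
brute-force oracle.

Also included: closure, CLR/ALR/pairwise transforms, multiplicative and
Bayesian-multiplicative zero replacement, total logratio variance by three
equivalent routes (pairwise, CLR, and the transpose shortcut for wide
tables), logratio distances and ordination, a component-subsampling study
of scan quality versus dimensionality, and a deterministic synthetic-data
generator with planted near-constant references.

## Worked example

```sh
$ alrscan synth --out demo.tsv -i 12 -j 20 --seed 3
wrote 12 x 20 synthetic table to demo.tsv (planted references: c1, c2, c17)

$ alrscan findalr demo.tsv --out report.tsv --top 3
total logratio variance: 0.183484
recommended reference: best by Procrustes correlation: c2 (index 2): R=0.9948 (rank 1), ...
top 3 candidates by Procrustes R:
  c2    (index 2)   R=0.994809  log_var=0.278031  zeros=0
  c17   (index 17)  R=0.994155  log_var=0.265945  zeros=0
  c1    (index 1)   R=0.993955  log_var=0.271395  zeros=0
```

The scan recovers the three planted low-noise components as the most
isometric references: ALRs w.r.t. `c2` reproduce the exact logratio
geometry with Procrustes correlation 0.995. The report (`report.tsv`) has
one row per candidate with R, the log-reference variance, five-number
summary, zero count and abundance rank; `recommend`/`--max-var` surface the
trade-off when the R-optimal and variance-optimal candidates differ.

The same pipeline in Python:

```python
from alrscan import read_abundance, replace_zeros, scan_references, recommend

raw = read_abundance("counts.tsv")
table, info = replace_zeros(raw)             # if the table has zeros
result = scan_references(table)              # all J candidates
print(recommend(result).rationale)
```

Other subcommands: `totvar` (total logratio variance), `alr` (write the
transformed matrix), `lra` (ordination coordinates and explained variance),
`distances` (all I(I−1)/2 logratio distances, optionally compared with the
ALR distances), `simulate` (subsampling study), `synth`.

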