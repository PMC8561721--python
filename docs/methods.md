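# Methods

## Model and procedure

An I × J abundance table X (samples in rows) is treated as compositional:
all statistics are functions of within-sample ratios, hence invariant to
closure and to any per-sample rescaling. With component weights
c₁, …, c_J (Σc_j = 1; equal weights c_j = 1/J by default) the package
computes:

- **CLR**: CLR(i,j) = log X_ij − Σ_k c_k log X_ik (log relative to the
  weighted geometric mean). Weighted rows satisfy Σ_j c_j·CLR(i,j) = 0.
- **ALR**: ALR(j|ref) = log(X_j/X_ref) = CLR(j) − CLR(ref).
- **Total logratio variance**:
  TotVar = Σ_{j<k} c_j c_k Var[log(X_j/X_k)] = Σ_j c_j Var[CLR_j],
  a weight-averaged quantity comparable across datasets of different
  sizes. For wide tables the same number is obtained by closing the
  transpose over component totals and repeating the CLR route with the
  samples as equally weighted parts.
- **Logratio geometry**: d(i,i′) = √(Σ_j c_j (CLR_ij − CLR_i′j)²), the
  Euclidean distance identical to the c_j c_k-weighted distance on all
  pairwise logratios. Samples live in K = min(I−1, J−1) dimensions.
- **Logratio analysis (LRA)**: SVD of the row-mass/column-weight scaled,
  column-centred CLR matrix; principal coordinates reproduce the logratio
  distances exactly and per-axis variances sum to TotVar. The ALR
  configuration is the ordinary PCA of the column-centred ALR matrix with
  its J−1 variables equally weighted, zero-padded to K axes.
- **Procrustes correlation**: after centring and scaling both
  configurations to unit total sum of squares, the SVD
  (X*)ᵀY* = UDVᵀ gives the optimal rotation Q = VUᵀ; the scaled residual
  is E = 1 − (trace D)² and R = trace D = √(1−E), which also equals the
  Pearson correlation of the entries of X* and Y*Q strung out as
  IK-vectors. E is defined on the *scaled* fit — the only reading under
  which E ∈ [0,1] for standardised configurations — so R is symmetric in
  the two configurations even though Q is not.
- **Reference scan**: every component in turn is used as ALR denominator;
  its configuration is fitted to the exact one and R recorded, together
  with the variance, five-number summary and IQR of log(X_ref/total), the
  pre-replacement zero count, and the mean relative abundance and its
  rank. Candidates are ranked primarily by R; the log-variance ranking is
  reported alongside because a near-constant reference lets each ALR be
  read as its numerator on the log scale. The final choice between an
  R-optimal and a variance-optimal candidate is a judgement the tool
  informs but does not make (`recommend` surfaces both with their ranks;
  `--max-var` applies a hard variance ceiling).

## Fast scan

With equal weights the column-centred CLR matrix Zc has zero row sums, so
the centred ALR cross-product for candidate r satisfies

    A_r A_rᵀ = Zc Zcᵀ + J · z_r z_rᵀ        (z_r = column r of Zc),

a rank-1 update of a precomputed I × I Gram matrix. Since R_r is the
nuclear norm of (X*)ᵀA_r divided by ‖A_r‖_F, each candidate reduces to a
K × K eigendecomposition: O(J·I²) overall instead of O(J²·I²). Naive mode
(explicit ALR → PCA → Procrustes per candidate) is retained as the oracle,
is the automatic choice for small tables, and is the fallback for
non-equal weights, where the zero-row-sum identity fails (weighted
Procrustes scanning is exposed but considered experimental). The two modes
are asserted to agree to 1e-10 on every candidate.

## Numerical choices

- **Variance divisor**: population form (divide by I) throughout,
  including the log-reference variance. This is what makes the transpose
  shortcut an exact identity (TotVar = ‖double-centred log matrix‖²_F/(I·J),
  symmetric in rows and columns). Quartiles use linear interpolation
  between order statistics (type 7).
- **Log base**: natural log everywhere; a `--log-base` option rescales
  logratio matrices by 1/ln b and variances by 1/(ln b)².
- **Rank and signs**: singular values below 1e-12 × the largest are
  treated as zero and their axes zero-padded; each retained axis is
  oriented so its largest-magnitude coordinate is positive (reproducible
  plots; R is unaffected). With tied singular values the rotation Q is
  non-unique — only R and E are contracted.
- **Ties in the ranking**: larger R first, then smaller log-variance, then
  smaller input index. Component indices in all reports are 1-based input
  positions, always accompanied by the label.
- **Pairwise expansion guard**: the explicit J(J−1)/2-column expansion is
  refused above J = 200 unless forced; the CLR route is the production
  path and is algebraically identical.
- **Zero replacement**: multiplicative replacement imputes each zero at
  δ_j = 0.65 × the smallest positive relative abundance observed for that
  component, shrinking the row's nonzero parts by a common factor, so
  logratios among observed parts are untouched; a Bayesian-multiplicative
  option imputes the Dirichlet posterior expectation (strength 1, prior
  means = observed mean relative abundances) instead. Both are
  deterministic. These are transparent re-implementations of the standard
  count-zero replacement family, not bit-for-bit reproductions of any
  particular R routine; downstream statistics can differ from published
  values in the last printed digit when zeros are present. Scans run on
  the replaced table but report pre-replacement zero counts, so the
  occupancy criterion (avoid low-occupancy references) can be applied to
  the raw data.

## Synthetic data

The generator draws X_ij = exp(μ_j + δ_gj + ε_ij): fixed per-component
baselines μ_j ~ N(5, spread²), per-cell log-normal noise ε of sd 0.5
(defaults), and a configurable number of planted reference components
whose noise sd is 1/20 of the rest, placed at the median baseline level.
Defaults are I = 30, J = 300, spread = 1.0, 3 planted references. The
spread is deliberately moderate — abundances span roughly two to three
orders of magnitude without any single component dominating the sample
totals, because a dominant part's relative abundance is pinned near 1 and
becomes artificially constant, masking the planted structure. Optional
structural zeros are confined to the low-abundance quartile of components
(emulating detection limits) and an optional two-group mean shift on a
subset of components produces group structure for ordination.

What this emulates — and what it does not: real microbiome/transcriptome
tables have heavier-tailed abundance distributions, count noise at low
abundance, and correlation structure among components; the generator makes
no claim to match those. Passing tests on generated data therefore
demonstrate the *algebraic and algorithmic* correctness of the pipeline
and the recoverability of planted low-variance references under log-normal
noise, not field performance on any particular assay. The embedded toy
tables with frozen brute-force oracle values (computed once by the
standalone `scripts/compute_toy_oracles.py`, which shares no code with the
package) guard the implementation against co-evolving bugs.

## Problem sizes

The default test and acceptance runs use tables up to 30 × 300 for full
scans, 100 repeated draws at 30 × 100 for the recovery experiment, and a
20 × 200 table for the subsampling study — sizes at which the naive and
fast paths can be cross-checked exhaustively while the whole suite runs in
seconds. The fast path scales to the thousands of components of real omics
tables (a 28 × 3147 scan is a few seconds of work; cost grows linearly
in J at fixed I).

## Known limitations

- Weighted-geometry scanning falls back to the naive path and its exact
  convention (correspondence-analysis-style double weighting) is one of
  several in use; equal weighting is the recommended and default mode.
- Isometric/pivot logratio transforms are deliberately out of scope.
- The Procrustes statistic is reported without a permutation significance
  test; with thousands of candidates its distribution across references
  (the histogram output) is the more informative diagnostic.
- BIOM support covers the JSON 1.0 dialect and the core matrix/ids layout
  of HDF5 2.1; observation/sample metadata beyond ids are ignored.
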