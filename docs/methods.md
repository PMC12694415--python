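# Methods

## The mean-intensity scorer

The core statistic is deliberately simple: the enrichment score of gene set
*s* in sample *j* is the arithmetic mean of the log-intensities of the set's
member features in that sample.  Everything else in the engine exists to
compute that mean for tens of thousands of sets and up to millions of samples
as one sparse linear-algebra operation:

1. **Indicator construction.** A GMT collection becomes a binary sparse
   feature-by-set matrix `G` (`gmt2mat`); conversion is lossless up to member
   order and the back conversion (`mat2gmt`) restores the collection on the
   represented universe.  Descriptions do not survive the round trip — the
   indicator has no place for them.
2. **Feature intersection.** Expression matrix and indicator are restricted
   to their shared features, rows aligned in the expression matrix's order.
   Sets emptied by the restriction are dropped with a warning rather than
   scored: a zero-member score is meaningless, and retaining the all-zero
   column would only produce a constant 0.
3. **Column normalization.** Each indicator column is scaled by its sum plus
   an offset `eps = 1e-8`, giving weights `1/(n_s + eps)` at member rows.
   The offset exists to keep empty columns at zero instead of 0/0; its side
   effect is that a score is the member mean times `n_s/(n_s + eps)` — a
   relative deviation below 1e-8, beneath every tolerance used here.  The
   raw score keeps this factor rather than rescaling to an exact mean.
4. **Cross-product.** `S = Wᵀ X`, accumulated in 64-bit floats regardless of
   input precision.  Sparse inputs stay sparse end to end; only the
   set-by-sample result is dense.
5. **Median normalization.** Each sample column of `S` is centered at its
   median and the grand mean of the raw column medians is added back, so all
   normalized columns share one median.  The operation is idempotent.  It is
   applied by default only when more than `min_sets = 20` sets were scored:
   a median over a handful of sets is too unstable to anchor on.  The
   threshold is a soft default, exposed together with an explicit on/off
   override.

**Chunking.** For very large problems the cross-product runs in contiguous
blocks of sample columns.  The block size is `max(1, ⌊L / n_sets⌋)` with
`L = 2³¹ − 1` (the 32-bit signed integer indexing ceiling; configurable so the
logic is testable at tiny sizes), and chunking activates automatically when
the sample count reaches the block size.  Blocks are scored independently and
concatenated, and median normalization is applied once to the combined matrix,
never per block — so the chunked path is bit-identical to the unchunked one.
Whether the activation rule should read "more than" or "at least" the
estimated size is immaterial in practice; this implementation activates at
`n_samples >= chunk_size`.

**Missing values.** Dense matrices may carry NaN entries.  The masked scorer
computes, per (set, sample), the mean over the *observed* members as a ratio
of two cross-products — indicatorᵀ·(values with zeros) over
indicatorᵀ·(observedness) + eps — which preserves cross-product form and
reduces exactly to the plain scorer when nothing is missing.  Pairs with no
observed member score 0 and are counted in a returned report.  Sparse
matrices are defined to have no missing values: stored zeros are data.

## The replication suite

Six published single-sample methods are re-expressed so that each needs only
per-(set, sample) sums of a per-gene vector, obtainable with the same sparse
cross-product back-end.  With `p` shared features, set size `n_s`, ascending
per-sample ranks `a_i` (average ties) and descending ranks `r_i = p + 1 − a_i`:

| method | statistic |
|---|---|
| scSE | Σ member counts / column total; the `mean` variant divides by `n_s`. The raw fraction is emitted (no ×100 display scaling). |
| singscore | `(m − (n_s+1)/2) / (p − n_s)` with `m` the mean member ascending rank; linear rescaling of `m` onto [0, 1]. |
| UCell | descending ranks clipped at `rmax + 1`; `U = Σ clipped − n_s(n_s+1)/2`; score `1 − U/(n_s · rmax)`, clamped to [0, 1]. |
| AUCell | `k = ⌈frac · p⌉`; member at rank `r` contributes `max(0, k − r + 1)` to the recovery-curve area, normalized by the all-members-on-top maximum. |
| ssGSEA | integral form: `ES = (Σ_s w_i a_i)/(Σ_s w_i) − (Σ_{∉s} a_i)/(p − n_s)` with `w_i = a_i^α`. |
| GSVA | stage 1: per-gene cross-sample kernel CDF; stage 2: per-sample descending rank `r` of that statistic, weights `|p/2 − r|^τ`; stage 3: the same integral form with those weights. |

**The integral form.** ssGSEA's score is the area under a weighted
running-sum walk down the per-sample ranking.  Walking from the top-expressed
gene down, the cumulative in-set fraction at step `t` sums `w_i/W` over
members passed so far, so over the whole walk each member contributes
`w_i · a_i / W`, each non-member `a_i/(p − n_s)` — the closed form above,
exactly equal to the explicit step-by-step area (verified exhaustively for
`p ≤ 8` and on random instances with `p ≤ 500`).  GSVA's original statistic
is the walk's *maximum deviation*, which is not a per-gene sum; the area
replaces it here (a mean-statistic approximation).  This substitution, plus
the simplified rank weights and empirical CDF, is the main source of
divergence from the original ssGSEA/GSVA outputs and the reason the
`alpha`/`tau` exponents matter more for these two methods than for the four
genuinely sum-shaped ones.  Concordance with literal reimplementations
reflects this: per-sample Spearman is ≥ 0.99 for singscore/UCell/AUCell/scSE,
≥ 0.9 for ssGSEA and ≥ 0.7 for the GSVA walk on dense continuous fixtures.

**Ranking.** Directions are fixed per method — ascending for singscore and
ssGSEA, descending for UCell, AUCell and GSVA stage 2 — with average ties
throughout, so every rank column sums to `p(p+1)/2` exactly.  On sparse
columns of nonnegative data the implicit zeros share the average rank of the
zero block, computed without densifying the column: the rank matrix stores
only the ranks of stored entries plus one zero-block rank per column, and any
per-gene transform of ranks aggregates through two sparse cross-products
(stored entries, plus `(n_s − observed members) · f(zero rank)`).  This
reproduces dense ranking exactly while staying O(nnz), and echoes UCell's
mitigation of the huge tied zero block of droplet data via the `rmax` clip.

**Parameters** (defaults are the original tools'): `alpha = 0.25` (ssGSEA
rank-weight exponent), `tau = 1` (GSVA weight exponent), `rmax = 1500` (UCell
rank ceiling), `auc_max_frac = 0.05` (AUCell top-rank window),
`scse_aggregate ∈ {sum, mean}`.  GSVA's Gaussian kernel uses bandwidth
`sd/4` per gene (zero-variance genes get a flat 0.5 with a warning); the
`ecdf` kernel (ranks/n) is the appropriate choice for counts and heavily tied
data, and is what the structured-count tests use.  Whole-matrix rescalings
performed by some originals (ssGSEA max−min normalization, GSVA's final
scaling) are not applied: they break single-sample independence.

**Choices on ambiguous points.** UCell's published statistic is implemented
as stated above; descriptions of the method as adding "a pseudo-rank of 1"
paraphrase the `rmax + 1` clipping and are not reproduced literally.  scSE's
×100 display scaling is omitted.  Duplicate feature rows in an expression
matrix are rejected rather than collapsed — collapsing would silently change
set statistics.

## Synthetic data

`simulate_counts` draws gamma–Poisson (negative binomial) counts with
lognormal gene-mean heterogeneity (`mean_sigma`, default 1.0 on the log
scale — gene means in real expression data are roughly lognormal), target
mean 1.0 and dispersion 0.5 (variance = μ + 0.5μ²), then masks entries to
zero with the Bernoulli probability needed to reach the requested total zero
fraction (default 0.8, droplet-like) on top of the model's intrinsic zeros.
A requested zero fraction below the intrinsic zero probability cannot be
reached; defaults are far above it.  Spikes multiply the Poisson intensity of
chosen (gene, cell) blocks by a fold factor *before* sampling, so a fold of 1
is bit-identical to no spike and spiked counts remain integer.  All draws use
`numpy.random.default_rng` (PCG64) with explicit seeds; fixtures are fully
reproducible.  `log_transform` applies log1p elementwise, keeping zeros at
zero and sparsity intact.

Two composed fixtures cover the test surface: `spiked_fixture` (one fold-4
signature of 200 genes in 20% of 1000 cells among 2000 genes, plus random
background sets — every scoring method recovers it with AUROC ≈ 1) and
`celltype_fixture` (cells partitioned into three types, each up-regulating
its own 100-gene marker block 6-fold — coordinated between-cell-type
structure like real single-cell data).

What the generator does *not* emulate: library-size gradients, batch effects,
doublets, gene–gene correlation beyond the spiked blocks, or realistic
set-to-set overlap structure.  Passing tests therefore demonstrate the
engine's numerical correctness and the methods' qualitative behavior under
controlled signal, not biological fidelity on real data.

## The centering observation

Row-centering two score matrices (subtracting each set's cross-sample mean)
before correlating them removes per-set baselines.  Methods disagree most on
exactly those baselines — a mean-intensity score is log-scale and unbounded,
UCell/AUCell saturate through rank clipping and top-k windows, GSVA is
already centered by construction — so on the cell-type fixture, centering
improves the mean per-sample Pearson between the mean-intensity scores and
UCell on every draw, GSVA enormously (≈0.44 → ≈0.95 with the ecdf kernel),
AUCell on most draws, and the six-method average on every draw.  The
exception is scSE's mean variant: it shares the member count sums with the
mean-intensity score almost affinely, its un-centered agreement is already
the highest of all pairs, and centering removes that best-agreeing component
without anything to fix — centered Pearson for this one pair is typically
equal or slightly lower.  The acceptance checks assert the suite-wide
improvement and report the scSE-pair fraction alongside it.

## Numerical notes and test scales

- Tolerances: cross-product vs loop-mean oracle 1e-10; chunked vs unchunked
  1e-12 (empirically bit-identical); median-normalization postcondition and
  idempotence 1e-9; sparse/dense representation equivalence 1e-12; ssGSEA
  closed form vs walk area 1e-12 exhaustively for p ≤ 8 and 1e-11 on random
  p ≤ 500 (the sequential walk oracle itself accrues ~1e-12 of rounding at
  that size).
- Problem sizes: oracle equivalence on 50 random instances up to
  1000 × 100 × 100; concordance on 100 × 50 with 20 sets over 5 seeds;
  centering on 20 draws of the 600 × 120 cell-type fixture; spike recovery on
  10 seeds of the 2000 × 1000 fixture; the scale smoke test scores 2864 sets
  on 1000 sparse cells through a densification-guarded matrix.  The whole
  suite runs in about half a minute on one CPU.
- Degenerate inputs: all-equal columns rank to (p+1)/2; a set equal to the
  whole universe is rejected by the rank-based methods (zero denominator);
  samples with zero total count are rejected by scSE by name; zero-variance
  genes get a flat kernel CDF with a warning; empty weight columns stay
  all-zero.

## Known limitations

Directional (activating vs inhibitory) signatures are not supported — scores
treat all members as one coordinated block.  GSVA's Poisson kernel, gene
identifier aliasing/organism mapping, and differential gene-set testing
between groups are out of scope.  Bit-compatibility with the original R
tools' outputs is not a goal; the replication suite targets their statistics,
not their implementations.
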