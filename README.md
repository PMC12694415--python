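# plaid

Ultrafast single-sample gene-set enrichment scoring on sparse matrices, plus a
unified replication suite for six established single-sample scoring methods
(singscore, scSE, ssGSEA, GSVA, UCell, AUCell).

## The problem

Gene-set enrichment scores (GSESs) summarize, per sample or per cell, the
coordinated activity of a named list of features — genes, proteins or
metabolites.  They are the workhorse of pathway-level analysis and patient
stratification, but most single-sample scoring methods rank or transform the
full expression matrix per sample and become impractical on modern single-cell
and biobank-scale data.

This package scores a gene set in a sample as the **average log-intensity of
the set's member features**, computed for all sets and all samples at once as
a single sparse matrix cross-product.  With `X` the feature-by-sample
log-expression matrix, `G` the binary feature-by-set indicator and `W` the
column-normalized weight matrix with entries

    W[i, s] = 1 / (n_s + eps)   for member features i of set s,

where `n_s` is the member count and `eps = 1e-8` guards empty columns, the
set-by-sample score matrix is

    S = Wᵀ X,        S[s, j] = mean_{i in s} X[i, j] · n_s / (n_s + eps).

The input is neither centered nor ranked; missing values in dense matrices are
excluded per (set, sample) via a ratio of two cross-products.  Very wide
matrices are scored in contiguous sample-column chunks sized from an
integer-indexing limit (`chunk = ⌊(2³¹−1)/n_sets⌋`), bit-identically to the
unchunked product.  When more than 20 sets are scored, the score matrix is
median-normalized by default: each sample column is centered at its median and
the grand mean of the raw column medians is added back.

The same sparse back-end aggregates per-gene transforms, which lets the six
replicated methods run as cross-products too: rank sums for singscore,
clipped-rank Mann–Whitney U for UCell, top-k recovery-curve areas for AUCell,
count fractions for scSE, and the integral (area) form of the weighted
running-sum statistic for ssGSEA and GSVA.  See `docs/methods.md` for the
exact statistics and their assumptions.

## Worked example

```python
from plaid import (spiked_fixture, log_transform, score,
                   signal_recovery_check, concordance_report)

# synthetic zero-inflated counts: a 60-gene signature up-regulated 4-fold
# in 20% of 300 cells, plus 10 random background sets
counts, coll, spiked_sets, spiked_cells = spiked_fixture(
    seed=0, n_genes=500, n_cells=300, set_size=60, cell_frac=0.2,
    fold=4.0, n_background_sets=10)

logX = log_transform(counts)          # log1p, sparsity-preserving
S = score(logX, coll, method="plaid")  # 11 sets x 300 cells

spiked = [S.sample_ids.index(c) for c in spiked_cells]
print(S.matrix[0, spiked].mean())      # 0.554  mean signature score, spiked cells
background = [j for j, c in enumerate(S.sample_ids) if c not in set(spiked_cells)]
print(S.matrix[0, background].mean())  # 0.221  mean signature score, background
print(signal_recovery_check(S, spiked_sets, spiked_cells))  # 0.999  AUROC

U = score(logX, coll, method="ucell")
print(concordance_report(S, U, center=True)["pearson"].median())  # 0.948
```

The spiked cells score roughly 2.5× the background on the spiked signature
and are separated almost perfectly (AUROC 0.999); after row-centering, the
mean-intensity scores agree closely with UCell's rank-based scores (median
per-cell Pearson 0.948).

The same pipeline is available from the shell:

```sh
plaid simulate --seed 4 -o fixture/
plaid score -x fixture/counts.mtx --format mtx -g fixture/sets.gmt \
      -m plaid -o scores.tsv
plaid convert gmt2mat -i fixture/sets.gmt -o sets.mtx
```

Supported methods: `plaid`, `singscore`, `scse`, `scse.mean`, `ssgsea`,
`gsva`, `ucell`, `aucell`.

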