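"""Deterministic synthetic expression matrices and gene-set collections.

The count model is a gamma–Poisson (negative binomial) with lognormal
gene-level mean heterogeneity and independent Bernoulli zero-masking on top of
the model's intrinsic zeros, giving zero-inflated sparse matrices like
droplet scRNA-seq counts.  Spiked signatures multiply the Poisson intensity of
chosen (gene, cell) blocks by a fold factor before sampling, so a fold of 1 is
a bit-identical no-op.  Everything draws from ``numpy.random.default_rng``
(PCG64) with an explicit seed, so fixtures are reproducible across platforms.

These generators emulate the statistical shape of real data — sparsity, mean
heterogeneity, overdispersion, coordinated set signals — not its biology: no
library-size gradients, batch effects or doublets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from .core import ScoreMatrix
from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "Spike",
    "FixtureSpec",
    "simulate_counts",
    "log_transform",
    "simulate_collection",
    "signal_recovery_check",
    "celltype_fixture",
    "spiked_fixture",
]


@dataclass(frozen=True)
class Spike:
    """A coordinated signal: multiply the intensity of ``genes`` x ``cells`` by ``fold``."""

    genes: tuple[int, ...]   # gene indices
    cells: tuple[int, ...]   # cell indices
    fold: float = 4.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("spike fold must be >= 1")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic count matrix.

    ``zero_fraction`` is the total target fraction of zero entries; masking is
    added only on top of the count model's intrinsic zero probability, so a
    target below that intrinsic level cannot be reached exactly.
    ``mean_sigma`` is the log-sd of the lognormal gene-mean distribution
    (0 = homogeneous genes).
    """

    n_genes: int = 2000
    n_cells: int = 1000
    zero_fraction: float = 0.8
    count_model: str = "negative_binomial"  # or "poisson"
    mean: float = 1.0
    dispersion: float = 0.5   # var = mean + dispersion * mean^2
    mean_sigma: float = 1.0
    log_base: str = "log1p"   # 'log1p' (natural) or 'log2'
    seed: int = 0
    spikes: tuple[Spike, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must lie in [0, 1)")
        if self.count_model not in ("negative_binomial", "poisson"):
            raise ValueError("count_model must be 'negative_binomial' or 'poisson'")
        if self.mean <= 0 or self.dispersion < 0 or self.mean_sigma < 0:
            raise ValueError("mean must be positive; dispersion and mean_sigma nonnegative")
        for s in self.spikes:
            if max(s.genes, default=-1) >= self.n_genes or min(s.genes, default=0) < 0:
                raise ValueError("spike genes outside the gene universe")
            if max(s.cells, default=-1) >= self.n_cells or min(s.cells, default=0) < 0:
                raise ValueError("spike cells outside the cell universe")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _cell_ids(n: int) -> list[str]:
    return [f"c{i:05d}" for i in range(n)]


def simulate_counts(spec: FixtureSpec) -> ExpressionMatrix:
    """Draw a sparse zero-inflated count matrix per the spec, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    g, c = spec.n_genes, spec.n_cells

    # lognormal gene means, normalized so the expectation stays spec.mean
    if spec.mean_sigma > 0:
        mu = spec.mean * rng.lognormal(0.0, spec.mean_sigma, size=g)
        mu /= math.exp(spec.mean_sigma**2 / 2.0)
    else:
        mu = np.full(g, spec.mean)

    if spec.count_model == "negative_binomial" and spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        lam = rng.gamma(r, (mu / r)[:, None], size=(g, c))
        p0 = np.mean((r / (r + mu)) ** r)
    else:
        lam = np.tile(mu[:, None], (1, c))
        p0 = float(np.mean(np.exp(-mu)))

    for s in spec.spikes:
        lam[np.ix_(s.genes, s.cells)] *= s.fold

    counts = rng.poisson(lam).astype(float)

    # Bernoulli masking on top of the model's intrinsic zeros
    q = max(0.0, 1.0 - (1.0 - spec.zero_fraction) / max(1.0 - p0, 1e-12))
    if q > 0:
        counts[rng.random((g, c)) < q] = 0.0

    mat = sp.csr_array(counts)
    return ExpressionMatrix(mat, _gene_ids(g), _cell_ids(c), value_kind="raw_counts")


def log_transform(X: ExpressionMatrix, log_base: str = "log1p") -> ExpressionMatrix:
    """Elementwise log(1 + x); zeros stay zero, so sparsity is preserved."""
    if log_base not in ("log1p", "log2"):
        raise ValueError("log_base must be 'log1p' or 'log2'")
    fn = np.log1p if log_base == "log1p" else lambda v: np.log2(1.0 + v)
    if X.is_sparse:
        if X.matrix.nnz and X.matrix.data.min() < 0:
            raise ValueError("log transform requires nonnegative counts")
        mat = X.matrix.copy()
        mat.data = fn(mat.data)
    else:
        if np.nanmin(X.matrix) < 0:
            raise ValueError("log transform requires nonnegative counts")
        mat = fn(X.matrix)
    return ExpressionMatrix(mat, list(X.feature_ids), list(X.sample_ids), "log_intensity")


def simulate_collection(
    n_sets: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    seed: int = 0,
    spiked_members: Sequence[Sequence[str]] = (),
) -> GeneSetCollection:
    """Random gene sets drawn without replacement from a feature universe.

    Set sizes are uniform over ``size_range``.  ``spiked_members`` lists
    become additional sets named SPIKE_0, SPIKE_1, ... placed first.
    """
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= |universe|")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, GeneSet] = {}
    for i, members in enumerate(spiked_members):
        sets[f"SPIKE_{i}"] = GeneSet("spiked signature", tuple(members))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"RAND_{i:05d}"] = GeneSet("random set", tuple(universe[j] for j in members))
    return GeneSetCollection(sets)


def signal_recovery_check(
    scores: ScoreMatrix,
    spiked_sets: Sequence[str],
    spiked_cells: Sequence[str],
) -> float:
    """AUROC of spiked-set scores separating spiked from background cells.

    Rank-based, hence invariant under any strictly monotone transform of the
    scores.  Returns the mean AUROC over the spiked sets.
    """
    spiked_cells = set(spiked_cells)
    labels = np.array([s in spiked_cells for s in scores.sample_ids], dtype=int)
    if labels.all() or not labels.any():
        raise ValueError("need both spiked and non-spiked cells to measure separation")
    set_index = {n: i for i, n in enumerate(scores.set_names)}
    aucs = [
        roc_auc_score(labels, scores.matrix[set_index[name], :])
        for name in spiked_sets
    ]
    if not aucs:
        raise ValueError("no spiked sets named")
    return float(np.mean(aucs))


def celltype_fixture(
    seed: int = 0,
    n_genes: int = 600,
    n_cells: int = 120,
    n_types: int = 3,
    marker_block: int = 100,
    fold: float = 6.0,
    zero_fraction: float = 0.8,
    n_sets: int = 30,
):
    """Cells partitioned into discrete types with up-regulated marker blocks.

    Each type t up-regulates its own block of ``marker_block`` genes by
    ``fold``, emulating the coordinated between-cell-type differences of real
    single-cell data; random gene sets overlap the blocks partially.  Returns
    ``(raw_counts, collection)``.
    """
    rng = np.random.default_rng(seed)
    types = rng.integers(0, n_types, size=n_cells)
    spikes = tuple(
        Spike(
            tuple(range(t * marker_block, (t + 1) * marker_block)),
            tuple(int(j) for j in np.flatnonzero(types == t)),
            fold,
        )
        for t in range(n_types)
    )
    spec = FixtureSpec(
        n_genes=n_genes, n_cells=n_cells, zero_fraction=zero_fraction,
        seed=seed, spikes=spikes,
    )
    counts = simulate_counts(spec)
    collection = simulate_collection(n_sets, (10, 50), counts.feature_ids, seed=seed + 1)
    return counts, collection


def spiked_fixture(
    seed: int = 0,
    n_genes: int = 2000,
    n_cells: int = 1000,
    set_size: int = 200,
    cell_frac: float = 0.2,
    fold: float = 4.0,
    n_background_sets: int = 30,
    zero_fraction: float = 0.8,
):
    """One spiked signature plus random background sets — the shared sanity surface.

    Returns ``(raw_counts, collection, spiked_set_names, spiked_cell_ids)``;
    apply :func:`log_transform` before log-intensity methods.
    """
    rng = np.random.default_rng(seed)
    genes = rng.choice(n_genes, size=set_size, replace=False)
    cells = rng.choice(n_cells, size=int(round(cell_frac * n_cells)), replace=False)
    spec = FixtureSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        zero_fraction=zero_fraction,
        seed=seed,
        spikes=(Spike(tuple(int(i) for i in genes), tuple(int(j) for j in cells), fold),),
    )
    counts = simulate_counts(spec)
    gene_ids = counts.feature_ids
    collection = simulate_collection(
        n_background_sets,
        (min(50, n_genes // 4), min(200, n_genes // 2)),
        gene_ids,
        seed=seed + 1,
        spiked_members=[[gene_ids[i] for i in genes]],
    )
    spiked_cell_ids = [counts.sample_ids[j] for j in cells]
    return counts, collection, ["SPIKE_0"], spiked_cell_ids
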