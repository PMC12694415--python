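"""PLAID scoring engine.

PLAID (Pathway Level Average Intensity Detection) scores a gene set in a
sample as the average log-intensity of the set's member features in that
sample.  The whole computation is a single sparse cross-product: with X the
feature-by-sample log-expression matrix and W the column-normalized sparse
feature-by-set indicator (each non-empty column sums to ~1), the set-by-sample
score matrix is ``W.T @ X``.  Because W's column j holds 1/(s_j + eps) at
member rows (s_j = member count, eps a small offset guarding empty columns),
each score is the member mean times s_j/(s_j + eps) — within 1e-8 of the exact
mean.  The input matrix is neither centered nor ranked.

For very large problems the cross-product runs in contiguous chunks of sample
columns sized from an integer-indexing limit, and the chunk results are
concatenated before any normalization; the chunked path is bit-identical to
the unchunked one.  Score matrices with more than ``min_sets`` sets are
median-normalized by default: each sample column is centered at its median and
the grand mean of the raw column medians is added back, so every normalized
column shares the same median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, GeneSetCollection, GeneSetMatrix, gmt2mat

logger = logging.getLogger("plaid")

__all__ = [
    "DEFAULT_OFFSET",
    "DEFAULT_MIN_SETS",
    "DEFAULT_INT_LIMIT",
    "WeightMatrix",
    "ScoreMatrix",
    "ChunkPlan",
    "MissingnessReport",
    "intersect_features",
    "normalize_set_columns",
    "estimate_chunk_plan",
    "plaid_score",
    "masked_plaid_score",
    "median_normalize",
    "plaid",
]

DEFAULT_OFFSET = 1e-8
DEFAULT_MIN_SETS = 20
DEFAULT_INT_LIMIT = 2**31 - 1  # 32-bit signed integer ceiling


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WeightMatrix:
    """Column-normalized sparse feature-by-set weight matrix.

    Column j holds 1/(s_j + offset) at each member row, so its sum is
    s_j/(s_j + offset) — within 1e-6 of 1 for any non-empty set.  Zero-member
    columns (if retained) stay all-zero instead of dividing by zero.
    """

    matrix: sp.csc_array
    feature_ids: list[str]
    set_names: list[str]
    offset: float = DEFAULT_OFFSET


@dataclass
class ScoreMatrix:
    """Dense set-by-sample enrichment score matrix."""

    matrix: np.ndarray
    set_names: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix dimensions do not match name lists")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("score matrix contains non-finite values")


@dataclass
class ChunkPlan:
    """Partition of sample columns into contiguous blocks.

    ``chunk_size = max(1, floor(int_limit / n_sets))`` bounds the number of
    entries any single cross-product block can index; chunking activates
    automatically once the sample count reaches that size.
    """

    chunk_size: int
    boundaries: list[tuple[int, int]]
    int_limit: int = DEFAULT_INT_LIMIT
    active: bool = False


@dataclass
class MissingnessReport:
    """Count of (set, sample) pairs with zero observed members (scored 0)."""

    n_empty_pairs: int
    n_pairs: int
    n_missing_values: int = 0


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def intersect_features(
    X: ExpressionMatrix, G: GeneSetMatrix
) -> tuple[ExpressionMatrix, GeneSetMatrix]:
    """Restrict both matrices to their shared features, rows aligned.

    The shared features keep X's row order.  Sets left empty by the
    restriction are dropped (with a warning).  A fast path returns the inputs
    unchanged when the two feature lists are already identical.
    """
    if X.feature_ids == G.feature_ids:
        return X, G
    g_index = {f: i for i, f in enumerate(G.feature_ids)}
    shared = [f for f in X.feature_ids if f in g_index]
    if not shared:
        raise ValueError("no shared features between expression matrix and gene sets")
    logger.info(
        "feature intersection: %d shared of %d expression / %d gene-set features",
        len(shared), len(X.feature_ids), len(G.feature_ids),
    )
    x_index = {f: i for i, f in enumerate(X.feature_ids)}
    x_rows = np.array([x_index[f] for f in shared])
    g_rows = np.array([g_index[f] for f in shared])

    x_mat = X.matrix[x_rows, :] if not X.is_sparse else sp.csr_array(X.matrix)[x_rows, :]
    X2 = ExpressionMatrix(x_mat, shared, list(X.sample_ids), X.value_kind)

    g_mat = sp.csc_array(G.matrix[g_rows, :])
    sizes = np.asarray(g_mat.sum(axis=0)).ravel()
    keep = sizes > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(G.set_names, keep) if not k]
        logger.warning(
            "dropping %d gene set(s) with no members among shared features: %s",
            len(dropped), ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
        g_mat = g_mat[:, np.flatnonzero(keep)]
    names = [n for n, k in zip(G.set_names, keep) if k]
    if not names:
        raise ValueError("no gene set has members among the shared features")
    return X2, GeneSetMatrix(sp.csc_array(g_mat), shared, names)


def normalize_set_columns(
    G: GeneSetMatrix, offset: float = DEFAULT_OFFSET
) -> WeightMatrix:
    """Scale each indicator column by its sum plus a small offset.

    The offset keeps all-zero columns at zero instead of producing 0/0, and
    leaves every non-empty column summing to s/(s + offset), within 1e-6 of 1.
    """
    if offset <= 0:
        raise ValueError("offset must be a positive real")
    sizes = G.set_sizes
    inv = 1.0 / (sizes + offset)
    W = sp.csc_array(G.matrix.astype(float) @ sp.diags_array(inv))
    return WeightMatrix(W, list(G.feature_ids), list(G.set_names), offset)


def estimate_chunk_plan(
    n_sets: int,
    n_samples: int,
    int_limit: int = DEFAULT_INT_LIMIT,
    force: bool = False,
    chunk_size: int | None = None,
) -> ChunkPlan:
    """Plan the sample-column blocks for the cross-product.

    The automatic chunk size is ``max(1, int_limit // n_sets)`` so a single
    block of the set-by-sample result never exceeds the integer-indexing
    limit.  Chunking activates when ``n_samples >= chunk_size`` (or when
    forced, or when an explicit ``chunk_size`` is supplied).
    """
    if n_sets <= 0 or n_samples <= 0 or int_limit <= 0:
        raise ValueError("n_sets, n_samples and int_limit must be positive")
    if chunk_size is not None:
        if chunk_size <= 0:
            raise ValueError("chunk_size must be positive")
        size, active = int(chunk_size), True
    else:
        size = max(1, int_limit // n_sets)
        active = force or n_samples >= size
    if active:
        boundaries = [(a, min(a + size, n_samples)) for a in range(0, n_samples, size)]
    else:
        boundaries = [(0, n_samples)]
    return ChunkPlan(size, boundaries, int_limit, active)


def plaid_score(
    X: ExpressionMatrix, W: WeightMatrix, plan: ChunkPlan | None = None
) -> ScoreMatrix:
    """Raw PLAID scores: the cross-product ``W.T @ X``, optionally chunked.

    score(s, j) = sum_i W(i,s)·X(i,j) = mean of X over set s's members in
    sample j, times s/(s+offset).  Chunked and unchunked paths are
    bit-identical: blocks of sample columns are scored independently and
    concatenated.  Accumulation is in 64-bit floats regardless of input dtype.
    """
    if X.feature_ids != W.feature_ids:
        raise ValueError("expression and weight matrices have misaligned feature rows")
    if X.has_missing():
        raise ValueError(
            "expression matrix has missing values; use masked_plaid_score"
        )
    if plan is None:
        plan = estimate_chunk_plan(len(W.set_names), X.n_samples)
    if plan.active:
        logger.info(
            "chunked scoring: %d block(s) of up to %d samples",
            len(plan.boundaries), plan.chunk_size,
        )
    Wt = W.matrix.T.astype(np.float64)
    blocks: list[np.ndarray] = []
    single = plan.boundaries == [(0, X.n_samples)]
    for a, b in plan.boundaries:
        xb = X.matrix if single else X.matrix[:, a:b]
        prod = Wt @ xb
        blocks.append(prod.toarray() if sp.issparse(prod) else np.asarray(prod, dtype=np.float64))
    scores = blocks[0] if len(blocks) == 1 else np.concatenate(blocks, axis=1)
    return ScoreMatrix(scores, list(W.set_names), list(X.sample_ids), normalized=False)


def masked_plaid_score(
    X: ExpressionMatrix,
    G: GeneSetMatrix,
    offset: float = DEFAULT_OFFSET,
) -> tuple[ScoreMatrix, MissingnessReport]:
    """Missing-value-aware PLAID scores for dense matrices with NaN entries.

    Each score is the mean over the set's members *observed* in that sample,
    computed as a ratio of two cross-products: (indicator' @ values-with-zeros)
    over (indicator' @ observedness + offset).  A (set, sample) pair with no
    observed member scores 0 and is counted in the returned report.  With no
    missing values this reduces exactly to :func:`plaid_score`.
    """
    if X.feature_ids != G.feature_ids:
        raise ValueError("expression and gene-set matrices have misaligned feature rows")
    if X.is_sparse:
        raise ValueError("sparse matrices carry no missing-value flag; use plaid_score")
    if offset <= 0:
        raise ValueError("offset must be a positive real")
    observed = ~np.isnan(X.matrix)
    if not observed.any():
        raise ValueError("expression matrix is entirely missing")
    values = np.where(observed, X.matrix, 0.0)
    Gt = G.matrix.T.astype(np.float64)
    num = np.asarray(Gt @ values)
    cnt = np.asarray(Gt @ observed.astype(np.float64))
    scores = num / (cnt + offset)
    empty = int((cnt == 0).sum())
    report = MissingnessReport(
        n_empty_pairs=empty,
        n_pairs=scores.size,
        n_missing_values=int((~observed).sum()),
    )
    if empty:
        logger.warning("%d (set, sample) pairs had no observed members; scored 0", empty)
    return (
        ScoreMatrix(scores, list(G.set_names), list(X.sample_ids), normalized=False),
        report,
    )


def median_normalize(
    S: ScoreMatrix,
    min_sets: int = DEFAULT_MIN_SETS,
    enable: bool | None = None,
) -> ScoreMatrix:
    """Median-normalize a raw score matrix.

    Each sample column is centered at its median, then the grand mean of the
    raw column medians is added back, so every normalized column's median
    equals that grand mean.  Applied by default only when more than
    ``min_sets`` sets were scored (medians over a handful of sets are too
    unstable to anchor on); ``enable`` overrides the rule either way.  The
    operation is idempotent.
    """
    active = enable if enable is not None else len(S.set_names) > min_sets
    if not active:
        return ScoreMatrix(S.matrix.copy(), list(S.set_names), list(S.sample_ids), False)
    med = np.median(S.matrix, axis=0)
    out = S.matrix - med[None, :] + med.mean()
    return ScoreMatrix(out, list(S.set_names), list(S.sample_ids), normalized=True)


def plaid(
    X: ExpressionMatrix,
    collection: GeneSetCollection | GeneSetMatrix,
    offset: float = DEFAULT_OFFSET,
    min_sets: int = DEFAULT_MIN_SETS,
    normalize: bool | None = None,
    chunk_size: int | None = None,
    int_limit: int = DEFAULT_INT_LIMIT,
) -> ScoreMatrix:
    """End-to-end PLAID: indicator build, intersection, scoring, normalization.

    Dense matrices containing NaN route through the masked (missing-value
    aware) scorer; otherwise the plain cross-product path runs with an
    automatically estimated chunk plan.  Deterministic for fixed inputs.
    """
    if isinstance(collection, GeneSetMatrix):
        G = collection
    else:
        G = gmt2mat(collection, feature_universe=None)
    X2, G2 = intersect_features(X, G)
    if X2.has_missing():
        raw, report = masked_plaid_score(X2, G2, offset=offset)
        logger.info(
            "masked scoring: %d missing values, %d empty (set, sample) pairs",
            report.n_missing_values, report.n_empty_pairs,
        )
    else:
        W = normalize_set_columns(G2, offset=offset)
        plan = estimate_chunk_plan(
            len(W.set_names), X2.n_samples, int_limit=int_limit, chunk_size=chunk_size
        )
        raw = plaid_score(X2, W, plan)
    return median_normalize(raw, min_sets=min_sets, enable=normalize)
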