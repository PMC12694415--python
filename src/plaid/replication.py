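"""Six single-sample scoring methods re-expressed as sparse cross-products.

singscore, scSE, ssGSEA, GSVA, UCell and AUCell all reduce, per sample, to a
per-gene transform (of raw values or of per-column ranks) followed by a sum of
the transformed values over each gene set's members.  That sum is exactly a
cross-product of the sparse set indicator with a per-gene vector, so all six
run through the same aggregation back-end as PLAID itself.

Where an original statistic is not a per-gene sum — the running-walk extrema of
ssGSEA and GSVA — the integral (area) form of the weighted running sum replaces
it: the area under the walk equals a closed form in per-gene rank sums (see
:func:`replaid_ssgsea`).  This substitution, together with the simplified rank
weights and empirical CDF, is why concordance with the original ssGSEA/GSVA is
lower than for the four genuinely sum-shaped methods, and why it is sensitive
to the ``alpha`` and ``tau`` exponents.

Rank conventions are fixed per method: ascending ranks for singscore and
ssGSEA, descending for UCell, AUCell and GSVA's second stage.  On sparse
columns the zeros share the average rank of the zero block (computed without
densifying the column), which keeps rank matrices O(nnz) on zero-inflated
single-cell data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata, spearmanr

from .core import ScoreMatrix
from .io import ExpressionMatrix, GeneSetMatrix

__all__ = [
    "RankMatrix",
    "MethodParams",
    "column_ranks",
    "replaid_scse",
    "replaid_sing",
    "replaid_ucell",
    "replaid_aucell",
    "replaid_ssgsea",
    "replaid_gsva",
    "concordance_report",
]


# ---------------------------------------------------------------------------
# parameters and rank machinery
# ---------------------------------------------------------------------------

@dataclass
class MethodParams:
    """Tunable parameters of the replicated methods (originals' defaults).

    alpha: ssGSEA rank-weight exponent; tau: GSVA weight exponent;
    rmax: UCell rank ceiling (ranks beyond it clip to rmax+1);
    auc_max_frac: AUCell top-rank window as a fraction of shared features;
    scse_aggregate: 'sum' (original scSE fraction) or 'mean' (divided by set
    size, the variant most concordant with PLAID).
    """

    alpha: float = 0.25
    tau: float = 1.0
    rmax: int = 1500
    auc_max_frac: float = 0.05
    scse_aggregate: str = "sum"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.rmax < 1:
            raise ValueError("rmax must be a positive integer")
        if not 0 < self.auc_max_frac <= 1:
            raise ValueError("auc_max_frac must lie in (0, 1]")
        if self.scse_aggregate not in ("sum", "mean"):
            raise ValueError("scse_aggregate must be 'sum' or 'mean'")


@dataclass
class RankMatrix:
    """Per-sample ranks of a feature-by-sample matrix, average ties.

    Dense inputs store the full rank matrix.  Sparse inputs (nonnegative data)
    store only the ranks of the stored entries plus, per column, the shared
    rank of the zero block (``zeros_share_bottom`` policy) — identical to
    dense ranking, at O(nnz) memory.
    """

    matrix: np.ndarray | sp.csc_array
    direction: str  # 'ascending' | 'descending'
    n_features: int
    tie_policy: str = "average"
    sparse_policy: str = "dense_full"  # or 'zeros_share_bottom'
    zero_rank: np.ndarray | None = None  # per-column rank of the zero block

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def toarray(self) -> np.ndarray:
        """Materialize the full rank matrix (testing/small data only)."""
        if not self.is_sparse:
            return self.matrix
        dense = np.tile(self.zero_rank, (self.n_features, 1)).astype(float)
        csc = self.matrix
        for j in range(csc.shape[1]):
            rows = csc.indices[csc.indptr[j]:csc.indptr[j + 1]]
            dense[rows, j] = csc.data[csc.indptr[j]:csc.indptr[j + 1]]
        return dense

    def column_sums(self) -> np.ndarray:
        """Rank totals per column; p(p+1)/2 exactly under average ties."""
        if not self.is_sparse:
            return self.matrix.sum(axis=0)
        nnz_per_col = np.diff(self.matrix.indptr)
        stored = np.asarray(self.matrix.sum(axis=0)).ravel()
        return stored + (self.n_features - nnz_per_col) * self.zero_rank


def column_ranks(
    X: ExpressionMatrix,
    direction: str = "ascending",
    sparse_policy: str | None = None,
) -> RankMatrix:
    """Rank each sample column with average ties.

    Sparse input under ``zeros_share_bottom`` ranks only the stored (strictly
    positive) entries of each column and assigns all implicit zeros the
    average rank of the zero block — matching dense ranking of the same column
    without ever densifying it.  Descending ranks are p + 1 − ascending.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    p = X.n_features
    if X.is_sparse and sparse_policy != "dense_full":
        sparse_policy = "zeros_share_bottom"
        csc = sp.csc_array(X.matrix).copy()
        csc.eliminate_zeros()
        if csc.nnz and csc.data.min() < 0:
            raise ValueError(
                "zeros_share_bottom ranking requires nonnegative data"
            )
        data = np.empty_like(csc.data, dtype=float)
        zero_rank = np.empty(csc.shape[1], dtype=float)
        for j in range(csc.shape[1]):
            lo, hi = csc.indptr[j], csc.indptr[j + 1]
            nz = hi - lo
            nzero = p - nz
            zero_rank[j] = (nzero + 1) / 2.0
            if nz:
                data[lo:hi] = nzero + rankdata(csc.data[lo:hi])
        ranks = sp.csc_array((data, csc.indices.copy(), csc.indptr.copy()), shape=csc.shape)
        if direction == "descending":
            ranks.data = p + 1 - ranks.data
            zero_rank = p + 1 - zero_rank
        return RankMatrix(ranks, direction, p, "average", "zeros_share_bottom", zero_rank)

    dense = X.matrix.toarray() if X.is_sparse else np.asarray(X.matrix, dtype=float)
    if np.isnan(dense).any():
        raise ValueError("rank-based methods do not support missing values")
    r = rankdata(dense, axis=0)
    if direction == "descending":
        r = p + 1 - r
    return RankMatrix(r, direction, p, "average", "dense_full")


def _member_transformed_rank_sums(G: GeneSetMatrix, R: RankMatrix, fn) -> np.ndarray:
    """sum over each set's members of fn(rank), as a (sets x samples) array.

    For sparse ranks the zero block contributes (|S| − observed members) times
    fn(zero_rank_j), so only two sparse cross-products are needed.
    """
    Gt = G.matrix.T.astype(np.float64)
    if not R.is_sparse:
        out = Gt @ fn(R.matrix)
        return np.asarray(out)
    T = R.matrix.copy()
    T.data = fn(T.data)
    prod = Gt @ T
    stored = np.asarray(prod.toarray() if sp.issparse(prod) else prod)
    pattern = R.matrix.copy()
    pattern.data = np.ones_like(pattern.data)
    observed = np.asarray((Gt @ pattern).toarray())
    sizes = G.set_sizes[:, None]
    return stored + (sizes - observed) * fn(R.zero_rank)[None, :]


def _member_value_sums(G: GeneSetMatrix, values) -> np.ndarray:
    out = G.matrix.T.astype(np.float64) @ values
    return np.asarray(out.toarray() if sp.issparse(out) else out)


def _check_aligned(X: ExpressionMatrix, G: GeneSetMatrix) -> None:
    if X.feature_ids != G.feature_ids:
        raise ValueError(
            "expression and gene-set matrices must share aligned feature rows; "
            "run intersect_features first"
        )


# ---------------------------------------------------------------------------
# the six methods
# ---------------------------------------------------------------------------

def replaid_scse(
    X: ExpressionMatrix, G: GeneSetMatrix, params: MethodParams | None = None
) -> ScoreMatrix:
    """scSE: per-sample member-count fraction of the total count.

    score(S, j) = sum of X over S's members / column total; the 'mean' variant
    divides additionally by |S|.  Requires nonnegative values (UMI counts in
    the original) and a positive total per sample.  The raw fraction is
    emitted (the original tool's ×100 display scaling is not applied).
    """
    params = params or MethodParams()
    _check_aligned(X, G)
    data = X.matrix.data if X.is_sparse else X.matrix
    if data.size and np.min(data) < 0:
        raise ValueError("scSE requires nonnegative values")
    totals = np.asarray(X.matrix.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = X.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    member = _member_value_sums(G, X.matrix)
    scores = member / totals[None, :]
    if params.scse_aggregate == "mean":
        scores = scores / G.set_sizes[:, None]
    return ScoreMatrix(scores, list(G.set_names), list(X.sample_ids))


def replaid_sing(X: ExpressionMatrix, G: GeneSetMatrix) -> ScoreMatrix:
    """singscore: normalized mean member rank, in [0, 1].

    With ascending per-sample ranks a_i over p shared features, the mean
    member rank m ranges from (|S|+1)/2 (members fill the bottom) to
    p − (|S|−1)/2 (members fill the top); the score rescales m linearly onto
    [0, 1]: (m − (|S|+1)/2) / (p − |S|).
    """
    _check_aligned(X, G)
    p = X.n_features
    sizes = G.set_sizes
    if np.any(sizes >= p):
        raise ValueError("a gene set equal to the whole feature universe cannot be scored")
    R = column_ranks(X, "ascending")
    sums = _member_transformed_rank_sums(G, R, lambda r: r)
    m = sums / sizes[:, None]
    scores = (m - (sizes[:, None] + 1) / 2.0) / (p - sizes[:, None])
    return ScoreMatrix(scores, list(G.set_names), list(X.sample_ids))


def replaid_ucell(
    X: ExpressionMatrix, G: GeneSetMatrix, params: MethodParams | None = None
) -> ScoreMatrix:
    """UCell: Mann–Whitney U score on rank-ceiling-clipped descending ranks.

    Descending ranks beyond ``rmax`` clip to rmax + 1 (mitigating the huge
    tied zero block of droplet data); with R the member sum of clipped ranks,
    U = R − |S|(|S|+1)/2 and score = 1 − U / (|S|·rmax), clamped to [0, 1].
    """
    params = params or MethodParams()
    _check_aligned(X, G)
    sizes = G.set_sizes
    if params.rmax < sizes.max():
        raise ValueError(
            f"rmax={params.rmax} is smaller than the largest set ({int(sizes.max())})"
        )
    R = column_ranks(X, "descending")
    clip = float(params.rmax + 1)
    rsum = _member_transformed_rank_sums(G, R, lambda r: np.minimum(r, clip))
    U = rsum - sizes[:, None] * (sizes[:, None] + 1) / 2.0
    scores = 1.0 - U / (sizes[:, None] * float(params.rmax))
    return ScoreMatrix(np.clip(scores, 0.0, 1.0), list(G.set_names), list(X.sample_ids))


def replaid_aucell(
    X: ExpressionMatrix, G: GeneSetMatrix, params: MethodParams | None = None
) -> ScoreMatrix:
    """AUCell: area under the member recovery curve within the top-k window.

    k = ceil(auc_max_frac · p).  A member at descending rank r contributes
    max(0, k − r + 1) to the area (it is counted at every window position from
    r to k); the maximum area, with all members packed at the top, normalizes
    the score onto [0, 1].
    """
    params = params or MethodParams()
    _check_aligned(X, G)
    p = X.n_features
    k = math.ceil(params.auc_max_frac * p)
    if k < 1:
        raise ValueError("auc_max_frac yields an empty top-rank window")
    sizes = G.set_sizes
    R = column_ranks(X, "descending")
    raw = _member_transformed_rank_sums(G, R, lambda r: np.maximum(0.0, k - r + 1))
    m = np.minimum(sizes, k).astype(float)
    max_raw = k * m - m * (m - 1) / 2.0
    scores = raw / max_raw[:, None]
    return ScoreMatrix(scores, list(G.set_names), list(X.sample_ids))


def replaid_ssgsea(
    X: ExpressionMatrix, G: GeneSetMatrix, params: MethodParams | None = None
) -> ScoreMatrix:
    """ssGSEA in integral (area) form, via three rank cross-products.

    With ascending ranks a_i and member weights w_i = a_i^alpha, the area under
    the weighted running sum walked from the top-expressed gene downward is

        ES = (sum_S w_i a_i) / (sum_S w_i) − (sum_notS a_i) / (p − |S|),

    where sum_notS a_i = p(p+1)/2 − sum_S a_i.  This closed form equals the
    explicit step-by-step walk area exactly; only the walk's *maximum
    deviation* (not used by ssGSEA, which integrates the walk) would differ.
    No across-matrix max−min rescaling is applied.
    """
    params = params or MethodParams()
    _check_aligned(X, G)
    p = X.n_features
    sizes = G.set_sizes
    if np.any(sizes >= p):
        raise ValueError("a gene set equal to the whole feature universe cannot be scored")
    R = column_ranks(X, "ascending")
    a = params.alpha
    w_sum = _member_transformed_rank_sums(G, R, lambda r: np.power(r, a))
    wa_sum = _member_transformed_rank_sums(G, R, lambda r: np.power(r, a + 1.0))
    a_sum = _member_transformed_rank_sums(G, R, lambda r: r)
    total = p * (p + 1) / 2.0
    out_mean = (total - a_sum) / (p - sizes[:, None])
    scores = wa_sum / w_sum - out_mean
    return ScoreMatrix(scores, list(G.set_names), list(X.sample_ids))


def _gaussian_kcdf(dense: np.ndarray) -> np.ndarray:
    """Cross-sample Gaussian-kernel CDF per gene, bandwidth sd/4.

    F(i, j) = mean_k Phi((x_ij − x_ik) / h_i).  Zero-variance genes get a flat
    0.5 (with a warning) — they carry no cross-sample information.
    """
    p, n = dense.shape
    sd = dense.std(axis=1, ddof=1)
    flat = sd <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s): kernel CDF set to 0.5",
            stacklevel=3,
        )
    F = np.full((p, n), 0.5)
    h = sd / 4.0
    idx = np.flatnonzero(~flat)
    # batch genes to keep the (genes x n x n) kernel tensor small
    batch = max(1, int(2e6 // max(n * n, 1)))
    for start in range(0, idx.size, batch):
        g = idx[start:start + batch]
        diff = (dense[g, :, None] - dense[g, None, :]) / h[g, None, None]
        F[g] = norm.cdf(diff).mean(axis=2)
    return F


def replaid_gsva(
    X: ExpressionMatrix,
    G: GeneSetMatrix,
    params: MethodParams | None = None,
    kcdf: str = "gaussian",
) -> ScoreMatrix:
    """GSVA-style scoring with integral-form enrichment.

    Stage 1 estimates, per gene, each sample's position in the gene's
    cross-sample distribution: a Gaussian-kernel CDF (bandwidth sd/4) or the
    empirical CDF (ranks/n, appropriate for counts and heavily tied data).
    Stage 2 ranks genes within each sample by that statistic, descending, and
    weights gene i by |p/2 − r_i|^tau — large for genes at either extreme of
    the sample's profile.  Stage 3 computes the same integral-form weighted
    enrichment as ssGSEA with these weights.  The original's max-deviation
    walk is replaced by the walk's area (the mean-statistic approximation),
    which is the main source of divergence from the reference GSVA output.
    """
    params = params or MethodParams()
    _check_aligned(X, G)
    n = X.n_samples
    if n < 3:
        raise ValueError("GSVA needs at least 3 samples for cross-sample density estimation")
    if kcdf not in ("gaussian", "ecdf"):
        raise ValueError("kcdf must be 'gaussian' or 'ecdf'")
    dense = X.matrix.toarray() if X.is_sparse else np.asarray(X.matrix, dtype=float)
    if kcdf == "gaussian":
        F = _gaussian_kcdf(dense)
    else:
        F = rankdata(dense, axis=1, method="max") / float(n)

    p = X.n_features
    sizes = G.set_sizes
    if np.any(sizes >= p):
        raise ValueError("a gene set equal to the whole feature universe cannot be scored")
    r = p + 1 - rankdata(F, axis=0)          # descending rank by F
    a = p + 1 - r                             # ascending-equivalent position
    w = np.abs(p / 2.0 - r) ** params.tau

    w_sum = _member_value_sums(G, w)
    wa_sum = _member_value_sums(G, w * a)
    a_sum = _member_value_sums(G, a)
    total = p * (p + 1) / 2.0
    out_mean = (total - a_sum) / (p - sizes[:, None])
    with np.errstate(invalid="ignore"):
        scores = np.where(w_sum > 0, wa_sum / np.where(w_sum > 0, w_sum, 1.0), (p + 1) / 2.0)
    scores = scores - out_mean
    return ScoreMatrix(scores, list(G.set_names), list(X.sample_ids))


# ---------------------------------------------------------------------------
# cross-method concordance
# ---------------------------------------------------------------------------

def concordance_report(
    S1: ScoreMatrix,
    S2: ScoreMatrix,
    center: bool = False,
    axis: str = "samples",
) -> pd.DataFrame:
    """Pearson and Spearman correlation between two score matrices.

    By default one row per sample (correlating across sets); ``axis='sets'``
    correlates across samples instead.  With ``center=True`` each set row of
    both matrices is mean-centered first — removing per-set baselines, which
    typically improves cross-method agreement.
    """
    if S1.set_names != S2.set_names or S1.sample_ids != S2.sample_ids:
        raise ValueError("score matrices must share set and sample spaces")
    A, B = S1.matrix, S2.matrix
    if center:
        A = A - A.mean(axis=1, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
    if axis == "samples":
        labels, pairs = S1.sample_ids, ((A[:, j], B[:, j]) for j in range(A.shape[1]))
    elif axis == "sets":
        labels, pairs = S1.set_names, ((A[i, :], B[i, :]) for i in range(A.shape[0]))
    else:
        raise ValueError("axis must be 'samples' or 'sets'")
    rows = []
    for label, (x, y) in zip(labels, pairs):
        with np.errstate(invalid="ignore"):
            pear = np.corrcoef(x, y)[0, 1]
            spear = spearmanr(x, y).statistic
        rows.append({"id": label, "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows).set_index("id")
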