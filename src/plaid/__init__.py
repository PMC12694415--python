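"""Ultrafast single-sample gene-set enrichment scoring on sparse matrices.

The core scorer, :func:`plaid`, computes the average log-intensity of each
gene set's members in each sample as a single sparse cross-product between a
column-normalized set indicator matrix and the expression matrix, with
automatic chunking for very large inputs and median normalization of the
resulting score matrix.  The replication suite re-expresses singscore, scSE,
ssGSEA, GSVA, UCell and AUCell as per-gene transforms aggregated through the
same sparse back-end.
"""

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    GeneSetMatrix,
    gmt2mat,
    mat2gmt,
    read_expression,
    read_gmt,
    write_expression,
    write_gmt,
    write_scores,
)
from .core import (
    ChunkPlan,
    MissingnessReport,
    ScoreMatrix,
    WeightMatrix,
    estimate_chunk_plan,
    intersect_features,
    masked_plaid_score,
    median_normalize,
    normalize_set_columns,
    plaid,
    plaid_score,
)
from .replication import (
    MethodParams,
    RankMatrix,
    column_ranks,
    concordance_report,
    replaid_aucell,
    replaid_gsva,
    replaid_scse,
    replaid_sing,
    replaid_ssgsea,
    replaid_ucell,
)
from .simulate import (
    FixtureSpec,
    Spike,
    celltype_fixture,
    log_transform,
    signal_recovery_check,
    simulate_collection,
    simulate_counts,
    spiked_fixture,
)

__version__ = "0.1.0"

METHODS = (
    "plaid",
    "singscore",
    "scse",
    "scse.mean",
    "ssgsea",
    "gsva",
    "ucell",
    "aucell",
)


def score(X, collection, method: str = "plaid", params=None, **plaid_kwargs):
    """Score ``collection`` on ``X`` with any supported method.

    ``method`` is one of :data:`METHODS`.  PLAID applies its own pipeline
    (intersection, weighting, chunking, median normalization); the replication
    methods intersect features and dispatch to their ``replaid_*`` function.
    """
    if method == "plaid":
        return plaid(X, collection, **plaid_kwargs)
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(METHODS)}"
        )
    params = params or MethodParams()
    # rank-based methods rank over the whole shared universe, so the indicator
    # is built on X's feature space (members outside it drop out)
    if isinstance(collection, GeneSetMatrix):
        G = collection
    else:
        G = gmt2mat(collection, feature_universe=X.feature_ids)
    X2, G2 = intersect_features(X, G)
    if method == "scse":
        return replaid_scse(X2, G2, params)
    if method == "scse.mean":
        from dataclasses import replace

        return replaid_scse(X2, G2, replace(params, scse_aggregate="mean"))
    if method == "singscore":
        return replaid_sing(X2, G2)
    if method == "ucell":
        return replaid_ucell(X2, G2, params)
    if method == "aucell":
        return replaid_aucell(X2, G2, params)
    if method == "ssgsea":
        return replaid_ssgsea(X2, G2, params)
    return replaid_gsva(X2, G2, params)
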