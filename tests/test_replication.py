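"""Rank machinery and the six replicated scoring methods vs brute-force oracles."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from plaid import (
    ExpressionMatrix,
    GeneSetCollection,
    MethodParams,
    column_ranks,
    concordance_report,
    gmt2mat,
    intersect_features,
    replaid_aucell,
    replaid_gsva,
    replaid_scse,
    replaid_sing,
    replaid_ssgsea,
    replaid_ucell,
    score,
)
from plaid.core import ScoreMatrix

from conftest import random_collection, to_sparse
from oracles import (
    loop_aucell,
    loop_scse,
    loop_singscore,
    loop_ucell,
    member_rows_from,
    ssgsea_walk_area,
    walk_gsva,
)


def _X(values, sparse=False):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    mat = sp.csr_array(values) if sparse else values
    return ExpressionMatrix(mat, [f"g{i}" for i in range(p)],
                            [f"s{j}" for j in range(n)])


def _prep(X, members: dict):
    G = gmt2mat(GeneSetCollection.from_dict(members), feature_universe=X.feature_ids)
    return intersect_features(X, G)


# ------------------------------------------------------------------- ranking

def test_column_ranks_with_ties():
    X = _X(np.array([[2.0], [5.0], [5.0], [1.0]]))
    asc = column_ranks(X, "ascending").matrix
    np.testing.assert_array_equal(asc.ravel(), [2, 3.5, 3.5, 1])
    desc = column_ranks(X, "descending").matrix
    np.testing.assert_array_equal(desc.ravel(), [3, 1.5, 1.5, 4])


def test_sparse_zero_block_shares_average_rank():
    col = np.zeros(10)
    col[[1, 4, 6]] = [3.0, 1.0, 2.0]
    X = _X(col[:, None], sparse=True)
    R = column_ranks(X, "ascending")
    assert R.is_sparse and R.zero_rank[0] == 4.0
    np.testing.assert_array_equal(R.toarray().ravel(), rankdata(col))


def test_sparse_and_dense_ranking_agree(rng):
    dense = rng.poisson(1.0, size=(60, 8)).astype(float)
    Xs, Xd = _X(dense, sparse=True), _X(dense)
    for direction in ("ascending", "descending"):
        Rs = column_ranks(Xs, direction)
        Rd = column_ranks(Xd, direction)
        np.testing.assert_allclose(Rs.toarray(), Rd.matrix)


def test_all_equal_column_ranks():
    X = _X(np.full((5, 1), 2.0))
    np.testing.assert_array_equal(column_ranks(X, "ascending").matrix.ravel(), 3.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 4), min_size=2, max_size=40))
def test_rank_column_sums_conserved(values):
    col = np.array(values, dtype=float)
    p = col.size
    expected = p * (p + 1) / 2
    for sparse in (False, True):
        X = _X(col[:, None], sparse=sparse)
        for direction in ("ascending", "descending"):
            R = column_ranks(X, direction)
            np.testing.assert_allclose(R.column_sums(), [expected])


# ---------------------------------------------------------------------- scSE

def test_scse_fraction_and_mean_modes():
    vals = np.zeros((10, 1))
    vals[0], vals[1] = 12.0, 8.0   # members sum 20
    vals[2:] = 10.0                # total 100
    X = _X(vals)
    X2, G2 = _prep(X, {"A": ["g0", "g1"]})
    assert replaid_scse(X2, G2).matrix[0, 0] == pytest.approx(0.2)
    assert replaid_scse(X2, G2, MethodParams(scse_aggregate="mean")).matrix[0, 0] == pytest.approx(0.1)


def test_scse_whole_universe_scores_one(rng):
    X = _X(rng.poisson(2.0, size=(20, 5)) + 1.0)
    X2, G2 = _prep(X, {"ALL": list(X.feature_ids)})
    np.testing.assert_allclose(replaid_scse(X2, G2).matrix, 1.0)


def test_scse_matches_loop_oracle(rng):
    dense = rng.poisson(1.0, size=(100, 20)).astype(float) + rng.random((100, 20))
    X = _X(dense)
    coll = random_collection(rng, 15, X.feature_ids)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    got = replaid_scse(X2, G2).matrix
    expected = loop_scse(dense, member_rows_from(coll, X.feature_ids))
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_scse_zero_total_sample_errors():
    X = _X(np.array([[1.0, 0.0], [2.0, 0.0]]))
    X2, G2 = _prep(X, {"A": ["g0"]})
    with pytest.raises(ValueError, match="s1"):
        replaid_scse(X2, G2)


# ----------------------------------------------------------------- singscore

@pytest.mark.parametrize(
    "member_positions, expected",
    [((3, 4), 1.0), ((0, 1), 0.0), ((1, 3), 0.5)],
)
def test_singscore_rank_placements(member_positions, expected):
    # column whose ascending ranks equal positions + 1
    X = _X(np.arange(5, dtype=float)[:, None])
    members = [f"g{i}" for i in member_positions]
    X2, G2 = _prep(X, {"A": members})
    assert replaid_sing(X2, G2).matrix[0, 0] == pytest.approx(expected)


def test_singscore_matches_loop_oracle(rng):
    dense = rng.normal(size=(80, 15))
    X = _X(dense)
    coll = random_collection(rng, 12, X.feature_ids)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    expected = loop_singscore(dense, member_rows_from(coll, X.feature_ids))
    np.testing.assert_allclose(replaid_sing(X2, G2).matrix, expected, atol=1e-12)


def test_singscore_whole_universe_errors():
    X = _X(np.arange(4, dtype=float)[:, None])
    X2, G2 = _prep(X, {"A": list(X.feature_ids)})
    with pytest.raises(ValueError):
        replaid_sing(X2, G2)


# --------------------------------------------------------------------- UCell

def test_ucell_perfect_signature_scores_one():
    X = _X(np.array([9.0, 8.0, 1.0, 2.0, 3.0])[:, None])
    X2, G2 = _prep(X, {"A": ["g0", "g1"]})  # descending ranks 1 and 2
    assert replaid_ucell(X2, G2, MethodParams(rmax=5)).matrix[0, 0] == pytest.approx(1.0)


def test_ucell_mid_ranks():
    # p=10, members at descending ranks 3 and 5 -> U=5, score 0.75 at rmax=10
    vals = np.arange(10, 0, -1, dtype=float)  # descending rank == index+1
    X = _X(vals[:, None])
    X2, G2 = _prep(X, {"A": ["g2", "g4"]})
    assert replaid_ucell(X2, G2, MethodParams(rmax=10)).matrix[0, 0] == pytest.approx(0.75)


def test_ucell_all_members_beyond_rmax():
    # members at the bottom: clipped ranks all rmax+1
    vals = np.arange(10, 0, -1, dtype=float)
    X = _X(vals[:, None])
    X2, G2 = _prep(X, {"A": ["g8", "g9"]})
    rmax = 5
    got = replaid_ucell(X2, G2, MethodParams(rmax=rmax)).matrix[0, 0]
    s = 2
    unclamped = 1 - (s * (rmax + 1) - s * (s + 1) / 2) / (s * rmax)
    assert got == pytest.approx(max(0.0, unclamped))


def test_ucell_matches_loop_oracle(rng):
    dense = rng.normal(size=(100, 10))
    X = _X(dense)
    coll = random_collection(rng, 10, X.feature_ids)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    got = replaid_ucell(X2, G2, MethodParams(rmax=40)).matrix
    expected = loop_ucell(dense, member_rows_from(coll, X.feature_ids), 40)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_ucell_rmax_smaller_than_set_errors():
    X = _X(np.arange(5, dtype=float)[:, None])
    X2, G2 = _prep(X, {"A": ["g0", "g1", "g2"]})
    with pytest.raises(ValueError, match="rmax"):
        replaid_ucell(X2, G2, MethodParams(rmax=2))


# -------------------------------------------------------------------- AUCell

def test_aucell_extremes_and_example():
    vals = np.arange(10, 0, -1, dtype=float)  # descending rank == index+1
    X = _X(vals[:, None])
    params = MethodParams(auc_max_frac=0.5)  # k = 5
    X2, G2 = _prep(X, {"A": ["g0", "g1", "g2"]})
    assert replaid_aucell(X2, G2, params).matrix[0, 0] == pytest.approx(1.0)
    X2, G2 = _prep(X, {"B": ["g7", "g8", "g9"]})
    assert replaid_aucell(X2, G2, params).matrix[0, 0] == pytest.approx(0.0)
    X2, G2 = _prep(X, {"C": ["g0", "g2", "g6"]})  # ranks 1, 3, 7 -> 8/12
    assert replaid_aucell(X2, G2, params).matrix[0, 0] == pytest.approx(8 / 12)


def test_aucell_matches_recovery_curve_oracle(rng):
    dense = rng.normal(size=(100, 12))
    X = _X(dense)
    coll = random_collection(rng, 10, X.feature_ids)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    got = replaid_aucell(X2, G2, MethodParams(auc_max_frac=0.1)).matrix
    expected = loop_aucell(dense, member_rows_from(coll, X.feature_ids), 10)
    np.testing.assert_allclose(got, expected, atol=1e-12)


# -------------------------------------------------------------------- ssGSEA

def test_ssgsea_small_example_equals_walk():
    # p=4, member ascending ranks {3, 4}, alpha 0.25
    col = np.array([1.0, 2.0, 3.0, 4.0])
    X = _X(col[:, None])
    X2, G2 = _prep(X, {"A": ["g2", "g3"]})
    es = replaid_ssgsea(X2, G2).matrix[0, 0]
    assert es == pytest.approx(2.018, abs=1e-3)
    assert es == pytest.approx(ssgsea_walk_area(col, np.array([2, 3]), 0.25), abs=1e-12)


def test_ssgsea_integral_identity_exhaustive_small_p():
    for p in range(3, 9):
        col = np.arange(1.0, p + 1)
        X = _X(col[:, None])
        for s in range(1, p):
            for rows in itertools.combinations(range(p), s):
                X2, G2 = _prep(X, {"A": [f"g{i}" for i in rows]})
                es = replaid_ssgsea(X2, G2).matrix[0, 0]
                area = ssgsea_walk_area(col, np.array(rows), 0.25)
                assert es == pytest.approx(area, abs=1e-12)


def test_ssgsea_top_placement_maximizes_score():
    p = 7
    col = np.arange(1.0, p + 1)
    X = _X(col[:, None])
    s = 3
    best = None
    for rows in itertools.combinations(range(p), s):
        X2, G2 = _prep(X, {"A": [f"g{i}" for i in rows]})
        es = replaid_ssgsea(X2, G2).matrix[0, 0]
        if rows == (p - 3, p - 2, p - 1):
            top_es = es
        best = es if best is None else max(best, es)
    assert top_es == pytest.approx(best)


def test_ssgsea_unweighted_random_null_near_zero(rng):
    p = 60
    X = _X(rng.normal(size=(p, 1)))
    vals = []
    for _ in range(300):
        rows = rng.choice(p, size=10, replace=False)
        X2, G2 = _prep(X, {"A": [f"g{i}" for i in rows]})
        vals.append(replaid_ssgsea(X2, G2, MethodParams(alpha=0.0)).matrix[0, 0])
    assert abs(np.mean(vals)) < 0.02 * p


# ---------------------------------------------------------------------- GSVA

def test_gsva_identical_samples_get_identical_scores(rng):
    col = rng.normal(size=50)
    dense = np.column_stack([col, rng.normal(size=50), col, rng.normal(size=50)])
    X = _X(dense)
    coll = random_collection(rng, 8, X.feature_ids)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    S = replaid_gsva(X2, G2).matrix
    np.testing.assert_allclose(S[:, 0], S[:, 2], atol=1e-12)


def test_gsva_zero_variance_gene_warns(rng):
    dense = rng.normal(size=(10, 5))
    dense[3] = 2.0
    X = _X(dense)
    X2, G2 = _prep(X, {"A": ["g0", "g1"]})
    with pytest.warns(UserWarning, match="zero-variance"):
        replaid_gsva(X2, G2)


def test_gsva_needs_three_samples(rng):
    X = _X(rng.normal(size=(10, 2)))
    X2, G2 = _prep(X, {"A": ["g0", "g1"]})
    with pytest.raises(ValueError, match="3 samples"):
        replaid_gsva(X2, G2)


def test_gsva_concordant_with_max_deviation_walk(rng):
    dense = rng.normal(size=(50, 20))
    X = _X(dense)
    coll = random_collection(rng, 10, X.feature_ids, lo=5, hi=15)
    X2, G2 = _prep(X, {n: list(coll.members(n)) for n in coll.names()})
    got = replaid_gsva(X2, G2).matrix
    ref = walk_gsva(dense, member_rows_from(coll, X.feature_ids))
    rhos = [spearmanr(got[:, j], ref[:, j]).statistic for j in range(20)]
    assert min(rhos) >= 0.7


# --------------------------------------------------- bounds and monotonicity

def test_bounded_methods_stay_in_unit_interval(rng):
    dense = rng.poisson(1.0, size=(120, 15)).astype(float)
    X = _X(dense, sparse=True)
    coll = random_collection(rng, 12, X.feature_ids)
    for method in ("singscore", "ucell", "aucell", "scse"):
        S = score(X, coll, method=method).matrix
        assert np.isfinite(S).all()
        assert S.min() >= 0.0 and S.max() <= 1.0


def test_monotonicity_in_member_expression(rng):
    dense = rng.normal(3.0, 1.0, size=(60, 4))
    ids = [f"g{i}" for i in range(60)]
    coll = GeneSetCollection.from_dict({"A": ids[:8]})
    bumped = dense.copy()
    bumped[2, 1] += 2.5  # raise one member gene in one sample
    for method in ("singscore", "ucell", "aucell"):
        before = score(_X(dense), coll, method=method).matrix[0, 1]
        after = score(_X(bumped), coll, method=method).matrix[0, 1]
        assert after >= before - 1e-12
    counts = np.abs(dense)
    bumped = counts.copy()
    bumped[2, 1] += 2.5
    before = score(_X(counts), coll, method="scse").matrix[0, 1]
    after = score(_X(bumped), coll, method="scse").matrix[0, 1]
    assert after >= before - 1e-12


def test_tie_safety_on_heavily_zero_inflated_columns(rng):
    dense = np.zeros((80, 6))
    dense[:4, :] = rng.poisson(2.0, size=(4, 6))
    X = _X(dense, sparse=True)
    coll = random_collection(rng, 8, X.feature_ids)
    for method in ("singscore", "ucell", "aucell", "ssgsea"):
        S = score(X, coll, method=method).matrix
        assert np.isfinite(S).all()


# --------------------------------------------------------------- concordance

def test_concordance_affine_and_sign():
    A = ScoreMatrix(np.random.default_rng(0).normal(size=(10, 4)),
                    [f"S{i}" for i in range(10)], list("wxyz"))
    B = ScoreMatrix(2 * A.matrix + 1, A.set_names, A.sample_ids)
    rep = concordance_report(A, B)
    np.testing.assert_allclose(rep["pearson"], 1.0)
    C = ScoreMatrix(-A.matrix, A.set_names, A.sample_ids)
    np.testing.assert_allclose(concordance_report(A, C)["pearson"], -1.0)


def test_concordance_dimension_mismatch_errors():
    A = ScoreMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "y"])
    B = ScoreMatrix(np.zeros((2, 2)), ["a", "c"], ["x", "y"])
    with pytest.raises(ValueError):
        concordance_report(A, B)


def test_centering_improves_cross_method_agreement():
    """Row-centering removes per-set baselines, on which rank-clipped methods
    and PLAID disagree most; agreement with UCell improves on a structured
    single-cell-like fixture."""
    from plaid import celltype_fixture, log_transform

    improved = 0
    for seed in range(5):
        counts, coll = celltype_fixture(seed=seed)
        logX = log_transform(counts)
        A = score(logX, coll, method="plaid", normalize=False)
        B = score(logX, coll, method="ucell")
        un = concordance_report(A, B, center=False)["pearson"].mean()
        ce = concordance_report(A, B, center=True)["pearson"].mean()
        improved += ce > un
    assert improved >= 4
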