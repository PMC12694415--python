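"""Independent brute-force reference implementations used only by the tests.

Every function here recomputes a score per (set, sample) with explicit loops
over members and explicit running-sum walks, deliberately avoiding the sparse
cross-product machinery of the package under test.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata


def loop_plaid(dense: np.ndarray, member_rows: dict[str, np.ndarray], offset: float = 1e-8):
    """Mean member value per (set, sample), times s/(s+offset), by explicit loop."""
    n = dense.shape[1]
    out = np.zeros((len(member_rows), n))
    for si, rows in enumerate(member_rows.values()):
        s = len(rows)
        for j in range(n):
            out[si, j] = dense[rows, j].mean() * s / (s + offset)
    return out


def loop_masked_plaid(dense: np.ndarray, member_rows: dict[str, np.ndarray]):
    """Mean over observed (non-NaN) member values; 0 when none observed."""
    n = dense.shape[1]
    out = np.zeros((len(member_rows), n))
    for si, rows in enumerate(member_rows.values()):
        for j in range(n):
            vals = dense[rows, j]
            vals = vals[~np.isnan(vals)]
            out[si, j] = vals.mean() if vals.size else 0.0
    return out


def loop_singscore(dense: np.ndarray, member_rows: dict[str, np.ndarray]):
    p, n = dense.shape
    out = np.zeros((len(member_rows), n))
    for si, rows in enumerate(member_rows.values()):
        s = len(rows)
        for j in range(n):
            a = rankdata(dense[:, j])
            m = a[rows].mean()
            out[si, j] = (m - (s + 1) / 2.0) / (p - s)
    return out


def loop_ucell(dense: np.ndarray, member_rows: dict[str, np.ndarray], rmax: int):
    p, n = dense.shape
    out = np.zeros((len(member_rows), n))
    for si, rows in enumerate(member_rows.values()):
        s = len(rows)
        for j in range(n):
            r = p + 1 - rankdata(dense[:, j])           # descending
            r = np.minimum(r, rmax + 1)
            U = r[rows].sum() - s * (s + 1) / 2.0
            out[si, j] = min(1.0, max(0.0, 1.0 - U / (s * rmax)))
    return out


def loop_aucell(dense: np.ndarray, member_rows: dict[str, np.ndarray], k: int):
    """Explicit recovery-curve summation: area = sum over top-k window positions
    of the cumulative member count."""
    p, n = dense.shape
    out = np.zeros((len(member_rows), n))
    for si, rows in enumerate(member_rows.values()):
        member = np.zeros(p, dtype=bool)
        member[rows] = True
        s = len(rows)
        m = min(s, k)
        max_area = sum(range(k - m + 1, k + 1))
        for j in range(n):
            order = np.argsort(-dense[:, j], kind="stable")
            hits = np.cumsum(member[order][:k])
            out[si, j] = hits.sum() / max_area
    return out


def loop_scse(dense: np.ndarray, member_rows: dict[str, np.ndarray], mean: bool = False):
    n = dense.shape[1]
    out = np.zeros((len(member_rows), n))
    totals = dense.sum(axis=0)
    for si, rows in enumerate(member_rows.values()):
        for j in range(n):
            out[si, j] = dense[rows, j].sum() / totals[j]
            if mean:
                out[si, j] /= len(rows)
    return out


def ssgsea_walk_area(column: np.ndarray, rows: np.ndarray, alpha: float) -> float:
    """Step-by-step weighted running-sum area, walking from the top gene down."""
    p = column.size
    a = rankdata(column)                     # ascending ranks
    member = np.zeros(p, dtype=bool)
    member[rows] = True
    order = np.argsort(-a)                   # descending walk
    w = a**alpha
    W = w[member].sum()
    n_out = p - member.sum()
    p_in = p_out = area = 0.0
    for g in order:
        if member[g]:
            p_in += w[g] / W
        else:
            p_out += 1.0 / n_out
        area += p_in - p_out
    return area


def walk_gsva(dense: np.ndarray, member_rows: dict[str, np.ndarray],
              tau: float = 1.0, kcdf: str = "gaussian"):
    """Full GSVA-style scoring with the max-deviation walk (mx.diff form)."""
    p, n = dense.shape
    if kcdf == "gaussian":
        F = np.zeros((p, n))
        for i in range(p):
            x = dense[i]
            sd = x.std(ddof=1)
            if sd <= 0:
                F[i] = 0.5
                continue
            h = sd / 4.0
            for j in range(n):
                F[i, j] = norm.cdf((x[j] - x) / h).mean()
    else:
        F = np.vstack([rankdata(dense[i], method="max") / n for i in range(p)])

    out = np.zeros((len(member_rows), n))
    for j in range(n):
        r = p + 1 - rankdata(F[:, j])        # descending rank by F
        w = np.abs(p / 2.0 - r) ** tau
        order = np.argsort(r, kind="stable")  # walk from top
        for si, rows in enumerate(member_rows.values()):
            member = np.zeros(p, dtype=bool)
            member[rows] = True
            W = w[member].sum()
            n_out = p - member.sum()
            v = vmax = vmin = 0.0
            for g in order:
                v += w[g] / W if member[g] else -1.0 / n_out
                vmax = max(vmax, v)
                vmin = min(vmin, v)
            out[si, j] = max(0.0, vmax) + min(0.0, vmin)
    return out


def member_rows_from(collection, feature_ids) -> dict[str, np.ndarray]:
    index = {f: i for i, f in enumerate(feature_ids)}
    return {
        name: np.array([index[m] for m in collection.members(name) if m in index])
        for name in collection.names()
    }
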