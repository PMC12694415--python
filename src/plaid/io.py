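"""Gene-set and expression-matrix I/O.

Gene-set collections use GMT (Gene Matrix Transposed) semantics: one set per
line, tab-separated ``name<TAB>description<TAB>member...``.  Collections
convert to and from a sparse feature-by-set binary indicator matrix
(:func:`gmt2mat` / :func:`mat2gmt`), the representation the scoring engine
consumes.  Expression matrices load from MatrixMarket coordinate files (with
plain-text row/column name sidecars, the de facto single-cell triplet layout)
or from dense TSV/CSV with feature rows and sample columns.

Feature-identifier matching throughout the package is exact, case-sensitive
string equality; symbol aliasing or organism mapping is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("plaid")

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GeneSetMatrix",
    "ExpressionMatrix",
    "read_gmt",
    "write_gmt",
    "gmt2mat",
    "mat2gmt",
    "read_expression",
    "write_expression",
    "write_scores",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named gene set: free-text description plus duplicate-free members."""

    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Ordered mapping from set name to :class:`GeneSet` (GMT semantics).

    Set names are unique and non-empty; member lists are non-empty and
    duplicate-free (duplicates collapse on construction, keeping first
    occurrence order).
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, GeneSet] = {}
        for name, gs in self.sets.items():
            if not name:
                raise ValueError("gene-set names must be non-empty")
            members = _dedupe(gs.members)
            if not members:
                raise ValueError(f"gene set {name!r} has no members")
            cleaned[name] = GeneSet(gs.description, tuple(members))
        self.sets = cleaned

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]]) -> "GeneSetCollection":
        return cls({name: GeneSet("", tuple(m)) for name, m in d.items()})

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name].members

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def setwise_equal(self, other: "GeneSetCollection") -> bool:
        """Equality on names and memberships, ignoring member order."""
        if self.names() != other.names():
            return False
        return all(
            set(self.members(n)) == set(other.members(n)) for n in self.sets
        )


@dataclass
class GeneSetMatrix:
    """Sparse binary feature-by-set indicator matrix.

    Entry (i, s) is 1 iff feature i belongs to set s.  Stored entries must be
    exactly 1 (zeros are implicit).
    """

    matrix: sp.csc_array
    feature_ids: list[str]
    set_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csc_array(self.matrix)
        self.matrix.eliminate_zeros()
        if self.matrix.shape != (len(self.feature_ids), len(self.set_names)):
            raise ValueError("indicator matrix dimensions do not match id lists")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.set_names, "set names")
        if self.matrix.nnz and not np.all(self.matrix.data == 1):
            raise ValueError("indicator matrix entries must be binary (0/1)")

    @property
    def set_sizes(self) -> np.ndarray:
        """Member count per set (column sums of the indicator)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()


@dataclass
class ExpressionMatrix:
    """Feature-by-sample numeric matrix, sparse or dense.

    Dense matrices may carry NaN entries, interpreted as missing values.
    Sparse matrices have no missing-value flag: stored zeros are data and
    every stored entry must be finite.
    """

    matrix: sp.csr_array | sp.csc_array | np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    value_kind: str = "log_intensity"  # or "raw_counts"

    def __post_init__(self) -> None:
        if sp.issparse(self.matrix):
            if self.matrix.nnz and not np.all(np.isfinite(self.matrix.data)):
                raise ValueError(
                    "sparse expression matrices must not contain non-finite values"
                )
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
            if np.isinf(self.matrix).any():
                raise ValueError("expression matrix contains infinite values")
        if self.matrix.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("expression matrix dimensions do not match id lists")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.value_kind not in ("log_intensity", "raw_counts"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def has_missing(self) -> bool:
        if self.is_sparse:
            return False
        return bool(np.isnan(self.matrix).any())


def _dedupe(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} are not allowed")


# ---------------------------------------------------------------------------
# GMT read / write
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must hold at least three tab-separated fields: set name,
    description (may be empty), and one or more members.  Trailing empty
    fields are ignored; duplicate members within a line collapse to one.
    Comment lines are not part of the GMT format and are rejected.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                raise ValueError(
                    f"{path}: line {lineno}: comment lines are not valid GMT"
                )
            fields = line.split("\t")
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = _dedupe(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(description, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; inverse of :func:`read_gmt` up to member order."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, gs in collection.sets.items():
            fh.write("\t".join([name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# collection <-> sparse indicator
# ---------------------------------------------------------------------------

def gmt2mat(
    collection: GeneSetCollection,
    feature_universe: Sequence[str] | None = None,
) -> GeneSetMatrix:
    """Convert a collection to a sparse binary feature-by-set indicator.

    Rows are the union of all members in first-appearance order, or
    ``feature_universe`` (in its given order) when supplied, in which case
    members outside the universe are dropped.  Sets left empty by universe
    filtering are dropped with a warning: scoring a zero-member set is not
    meaningful.
    """
    if len(collection) == 0:
        raise ValueError("cannot convert an empty gene-set collection")
    if feature_universe is not None:
        _check_unique(feature_universe, "feature universe ids")
        features = list(feature_universe)
    else:
        features = _dedupe(
            m for gs in collection.sets.values() for m in gs.members
        )
    index = {f: i for i, f in enumerate(features)}

    rows: list[int] = []
    cols: list[int] = []
    set_names: list[str] = []
    for name, gs in collection.sets.items():
        hit = [index[m] for m in gs.members if m in index]
        if not hit:
            logger.warning("dropping gene set %r: no members in feature universe", name)
            continue
        col = len(set_names)
        set_names.append(name)
        rows.extend(hit)
        cols.extend([col] * len(hit))
    if not set_names:
        raise ValueError("no gene set has members in the feature universe")

    mat = sp.csc_array(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(features), len(set_names)),
    )
    return GeneSetMatrix(mat, features, set_names)


def mat2gmt(gsm: GeneSetMatrix) -> GeneSetCollection:
    """Convert a sparse indicator back to a collection (descriptions empty)."""
    csc = gsm.matrix
    sets: dict[str, GeneSet] = {}
    for j, name in enumerate(gsm.set_names):
        rows = csc.indices[csc.indptr[j]:csc.indptr[j + 1]]
        members = tuple(gsm.feature_ids[i] for i in rows)
        if members:
            sets[name] = GeneSet("", members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _sidecar_paths(mtx_path: Path) -> tuple[Path, Path]:
    base = mtx_path.with_suffix("")  # strip .mtx
    return Path(str(base) + ".rows.txt"), Path(str(base) + ".cols.txt")


def _read_names(path: Path) -> list[str]:
    with path.open("r", encoding="utf-8") as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_expression(
    path: str | Path,
    format: str = "mtx",
    value_kind: str = "log_intensity",
    feature_file: str | Path | None = None,
    sample_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix.

    ``format="mtx"``: MatrixMarket coordinate file, loaded as sparse without
    densification, plus plain-text name sidecars (one id per line) found at
    ``<base>.rows.txt`` / ``<base>.cols.txt`` next to the ``.mtx`` file unless
    given explicitly.  ``format="tsv"`` (or ``"csv"``): dense table whose
    header row holds sample ids and whose first column holds feature ids.
    """
    path = Path(path)
    if format == "mtx":
        default_rows, default_cols = _sidecar_paths(path)
        rows_path = Path(feature_file) if feature_file else default_rows
        cols_path = Path(sample_file) if sample_file else default_cols
        mat = sp.csr_array(scipy.io.mmread(path))
        features = _read_names(rows_path)
        samples = _read_names(cols_path)
        if mat.shape[0] != len(features):
            raise ValueError(
                f"{path}: matrix has {mat.shape[0]} rows but {rows_path} "
                f"lists {len(features)} feature names"
            )
        if mat.shape[1] != len(samples):
            raise ValueError(
                f"{path}: matrix has {mat.shape[1]} columns but {cols_path} "
                f"lists {len(samples)} sample names"
            )
        return ExpressionMatrix(mat, features, samples, value_kind)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric cell in expression table: {exc}")
        return ExpressionMatrix(
            values, [str(i) for i in df.index], [str(c) for c in df.columns], value_kind
        )
    raise ValueError(f"unknown expression format {format!r} (expected mtx or tsv)")


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    """Write as MatrixMarket coordinate plus ``.rows.txt`` / ``.cols.txt`` sidecars."""
    path = Path(path)
    mat = X.matrix if X.is_sparse else sp.coo_array(X.matrix)
    scipy.io.mmwrite(path, sp.coo_array(mat))
    rows_path, cols_path = _sidecar_paths(path)
    rows_path.write_text("\n".join(X.feature_ids) + "\n", encoding="utf-8")
    cols_path.write_text("\n".join(X.sample_ids) + "\n", encoding="utf-8")


def write_scores(scores, path: str | Path) -> None:
    """Write a set-by-sample score matrix as TSV (sets in rows)."""
    df = pd.DataFrame(scores.matrix, index=scores.set_names, columns=scores.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_set")
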