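"""Distance, similarity, and Gower-centered matrices.

Multivariate distance matrix regression (MDMR) starts from an N x N matrix of
pairwise dissimilarities between the multivariate profiles of N samples.  This
module builds that matrix from a samples x variables data table (Euclidean,
Manhattan, or correlation-based dissimilarity, with pairwise-complete handling
of missing values), converts distances to bounded similarities for display
purposes, applies the Gower double-centering that turns squared distances into
a centered inner-product (Gram-like) matrix, and reads/writes the square CSV
interchange format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DataMatrix",
    "DistanceMatrix",
    "SimilarityMatrix",
    "GowerMatrix",
    "compute_distance_matrix",
    "gower_center",
    "similarity_from_distance",
    "read_data_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
]

_SYMMETRY_TOL = 1e-8
_MEASURES = ("euclidean", "manhattan", "pearson_corr")


@dataclass
class DataMatrix:
    """N x P table of outcome variables; NaN entries mark missing values.

    Parameters
    ----------
    values : ndarray of shape (N, P)
        Profile of P variables per sample; missing entries are NaN.
    sample_ids : list of str
        Unique sample labels, one per row.
    variable_ids : list of str
        Unique variable labels, one per column.
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 variable")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.variable_ids) != p:
            raise ValueError("variable_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.variable_ids)) != p:
            raise ValueError("variable_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean N x P mask, True where the entry is missing."""
        return np.isnan(self.values)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_ids)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative N x N matrix of pairwise dissimilarities."""

    d: np.ndarray
    sample_ids: list[str]
    measure_name: str = "unknown"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = self.d.shape[0]
        if self.d.ndim != 2 or self.d.shape[1] != n:
            raise ValueError(f"distance matrix must be square, got shape {self.d.shape}")
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match matrix size")
        asym = np.max(np.abs(self.d - self.d.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"distance matrix asymmetric (max |d_ij - d_ji| = {asym:.3g})")
        # symmetrize away roundoff within tolerance
        self.d = 0.5 * (self.d + self.d.T)
        if np.max(np.abs(np.diag(self.d))) > _SYMMETRY_TOL:
            raise ValueError("distance matrix diagonal must be zero")
        np.fill_diagonal(self.d, 0.0)
        if np.min(self.d) < -_SYMMETRY_TOL:
            raise ValueError("distances must be nonnegative")
        np.clip(self.d, 0.0, None, out=self.d)

    @property
    def n_samples(self) -> int:
        return self.d.shape[0]


@dataclass
class SimilarityMatrix:
    """N x N similarity matrix with entries in [0, 1] (1 on the diagonal)."""

    s: np.ndarray
    sample_ids: list[str]
    max_distance_used: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.max_distance_used <= 0:
            raise ValueError("max_distance_used must be positive")
        if np.min(self.s) < -1e-12 or np.max(self.s) > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")


@dataclass
class GowerMatrix:
    """Double-centered inner-product matrix G = C A C.

    A = -(1/2) D∘D and C = I - (1/N) 1 1' is the centering operator, so every
    row and column of G sums to zero.  For Euclidean distances G equals the
    Gram matrix of the column-centered data, hence tr(G) is the total sum of
    squares.
    """

    g: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        n = self.g.shape[0]
        if self.g.ndim != 2 or self.g.shape[1] != n:
            raise ValueError("Gower matrix must be square")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(n)]
        if np.max(np.abs(self.g - self.g.T)) > _SYMMETRY_TOL:
            raise ValueError("Gower matrix must be symmetric")
        scale = max(1.0, float(np.max(np.abs(self.g))))
        if np.max(np.abs(self.g.sum(axis=0))) > 1e-8 * scale:
            raise ValueError("Gower matrix rows/columns must sum to zero")

    @property
    def n_samples(self) -> int:
        return self.g.shape[0]

    @property
    def total_trace(self) -> float:
        return float(np.trace(self.g))


def _pairwise_complete(values: np.ndarray, measure: str, min_shared: int,
                       sample_ids: list[str]) -> np.ndarray:
    """Pairwise-complete distances with rescaling for unequal missingness.

    Euclidean sums of squares over the shared coordinates are rescaled by
    P/P_shared (sqrt on the distance scale), Manhattan sums by P/P_shared,
    so expected magnitudes are comparable across pairs with different
    amounts of missing data.
    """
    n, p = values.shape
    mask = (~np.isnan(values)).astype(float)
    shared = mask @ mask.T  # N x N counts of jointly observed variables
    bad = np.argwhere(np.triu(shared < min_shared, k=1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"samples {sample_ids[i]!r} and {sample_ids[j]!r} share only "
            f"{int(shared[i, j])} non-missing variables (need >= {min_shared})"
        )
    z = np.nan_to_num(values, nan=0.0)
    if measure == "euclidean":
        w = z * z
        ss = w @ mask.T + mask @ w.T - 2.0 * z @ z.T
        np.clip(ss, 0.0, None, out=ss)
        d = np.sqrt(ss * (p / shared))
    elif measure == "manhattan":
        d = np.zeros((n, n))
        for i in range(n):
            diff = np.abs(z[i] - z[i + 1:]) * (mask[i] * mask[i + 1:])
            d[i, i + 1:] = diff.sum(axis=1) * (p / shared[i, i + 1:])
        d = d + d.T
    else:  # pearson_corr
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m = (mask[i] * mask[j]).astype(bool)
                xi, xj = values[i, m], values[j, m]
                sx, sy = xi.std(), xj.std()
                if sx == 0 or sy == 0:
                    flat = sample_ids[i] if sx == 0 else sample_ids[j]
                    raise ValueError(
                        f"profile {flat!r} has zero variance on the shared "
                        f"coordinates of pair ({sample_ids[i]!r}, {sample_ids[j]!r}); "
                        "correlation distance undefined"
                    )
                r = float(np.corrcoef(xi, xj)[0, 1])
                d[i, j] = d[j, i] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def compute_distance_matrix(data: DataMatrix, measure: str = "euclidean",
                            min_shared_fraction: float = 0.5) -> DistanceMatrix:
    """Pairwise dissimilarities between sample profiles.

    Parameters
    ----------
    data : DataMatrix
        N x P profiles; NaN marks missing values.
    measure : {"euclidean", "manhattan", "pearson_corr"}
        ``pearson_corr`` is 1 - r where r is the Pearson correlation of the
        two profiles (range [0, 2]); the other two act on shared non-missing
        coordinates with a P/P_shared magnitude correction.
    min_shared_fraction : float in (0, 1]
        Each pair of samples must share at least ceil(fraction * P)
        non-missing variables.

    Returns
    -------
    DistanceMatrix
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {_MEASURES}")
    if not 0 < min_shared_fraction <= 1:
        raise ValueError("min_shared_fraction must be in (0, 1]")
    p = data.n_variables
    min_shared = math.ceil(min_shared_fraction * p)
    if measure == "pearson_corr":
        min_shared = max(min_shared, 2)

    if not data.missing_mask.any():
        if measure == "pearson_corr":
            stds = data.values.std(axis=1)
            if np.any(stds == 0):
                flat = data.sample_ids[int(np.argmin(stds))]
                raise ValueError(
                    f"profile {flat!r} has zero variance; correlation distance undefined"
                )
            d = squareform(pdist(data.values, metric="correlation"))
        else:
            metric = "cityblock" if measure == "manhattan" else "euclidean"
            d = squareform(pdist(data.values, metric=metric))
    else:
        d = _pairwise_complete(data.values, measure, min_shared, data.sample_ids)
    return DistanceMatrix(d, data.sample_ids, measure_name=measure)


def gower_center(dm: DistanceMatrix) -> GowerMatrix:
    """Gower double-centering: G = C A C with A = -(1/2) D∘D, C = I - 11'/N.

    Equivalent to the elementwise form
    g_ij = a_ij - rowmean_i(A) - colmean_j(A) + grandmean(A).
    """
    a = -0.5 * dm.d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    g = 0.5 * (g + g.T)
    return GowerMatrix(g, dm.sample_ids)


def similarity_from_distance(dm: DistanceMatrix,
                             max_distance: float | str = "empirical") -> SimilarityMatrix:
    """Map distances to similarities s_ij = 1 - d_ij / max_distance.

    With ``max_distance="empirical"`` the observed maximum is used, so the
    most dissimilar pair gets similarity exactly 0 and the diagonal stays 1.
    """
    if max_distance == "empirical":
        scale = float(np.max(dm.d))
        if scale <= 0:
            raise ValueError("all distances are zero; empirical maximum undefined")
    else:
        scale = float(max_distance)
        if scale <= 0:
            raise ValueError("max_distance must be positive")
    s = 1.0 - dm.d / scale
    return SimilarityMatrix(s, dm.sample_ids, scale)


def read_data_matrix(path, sep: str | None = None) -> DataMatrix:
    """Read a samples x variables table (CSV/TSV, first column = sample ID).

    Empty cells and "NA" are treated as missing.  The separator is sniffed
    from the extension (.tsv/.txt = tab, otherwise comma) unless given.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    return DataMatrix.from_frame(frame)


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square CSV distance matrix with an ID header row and column."""
    frame = pd.read_csv(path, index_col=0)
    ids_row = [str(c) for c in frame.columns]
    ids_col = [str(i) for i in frame.index]
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: distance matrix must be square, got {frame.shape}")
    if ids_row != ids_col:
        raise ValueError(f"{path}: header IDs and index IDs disagree")
    return DistanceMatrix(frame.to_numpy(dtype=float), ids_col)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix as square CSV (round-trips to 1e-12)."""
    frame = pd.DataFrame(dm.d, index=dm.sample_ids, columns=dm.sample_ids)
    frame.to_csv(path, float_format="%.17g")
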