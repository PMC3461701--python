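"""MDMR-based selection of the number of clusters.

Cluster analysis rarely offers a formal test for how many groups a data set
contains.  MDMR supplies one: fit k clusters (UPGMA cut of the distance
matrix, or k-means on the raw data), dummy-code the memberships as
regressors, and regress the distance matrix on them.  The chosen k is the
smallest number of clusters beyond which adding clusters no longer explains
a significant share of the distance-based variation, assessed by a
restricted permutation test of the added indicator columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import core
from .core import DesignMatrix
from .distance import DataMatrix, DistanceMatrix, GowerMatrix

__all__ = [
    "ClusterAssignment",
    "ClusterScan",
    "upgma",
    "cut_tree",
    "kmeans_assign",
    "dummy_code",
    "select_k",
]


@dataclass
class ClusterAssignment:
    """Labels in {1..k}, canonically renumbered by first occurrence."""

    labels: np.ndarray
    k: int
    method: str
    linkage_heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        found = set(np.unique(self.labels))
        if found != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover exactly 1..{self.k}, found {sorted(found)}"
            )

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


@dataclass
class ClusterScan:
    """Per-k MDMR records plus the selected cluster count and its rationale."""

    records: list[dict]
    selected_k: int
    selected_k_argmax_f: int
    selection_rule_trace: list[str]

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "selected_k": self.selected_k,
            "selected_k_argmax_f": self.selected_k_argmax_f,
            "selection_rule_trace": self.selection_rule_trace,
        }


def _canonical_labels(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..k in order of first occurrence (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out, len(mapping)


def upgma(dm: DistanceMatrix) -> np.ndarray:
    """Average-linkage (UPGMA) dendrogram as a scipy linkage matrix.

    At each step the two clusters with the smallest average inter-cluster
    distance are merged, and the merge height is that average.
    """
    return linkage(squareform(dm.d, checks=False), method="average")


def cut_tree(dendrogram: np.ndarray, k: int) -> ClusterAssignment:
    """Cut a dendrogram to exactly k groups (the clusters present just
    before the (N-k)-th merge)."""
    n = dendrogram.shape[0] + 1
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        raw = fcluster(dendrogram, t=k, criterion="maxclust")
    labels, k_found = _canonical_labels(raw)
    if k_found != k:
        # ties in merge heights can make maxclust return fewer groups
        raise ValueError(f"could not cut tree into exactly {k} groups (got {k_found})")
    return ClusterAssignment(labels, k, "upgma_cut",
                             linkage_heights=[float(h) for h in dendrogram[:, 2]])


def kmeans_assign(data: DataMatrix, k: int, seed: int | None = None,
                  n_restarts: int = 10) -> ClusterAssignment:
    """k-means on the raw data matrix, best inertia over seeded restarts."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_restarts,
                random_state=None if seed is None else int(seed) % (2**32))
    raw = km.fit_predict(data.values) + 1
    labels, k_found = _canonical_labels(raw)
    if k_found != k:
        raise ValueError(f"k-means produced {k_found} nonempty clusters, wanted {k}")
    return ClusterAssignment(labels, k, "kmeans")


def dummy_code(assignment: ClusterAssignment) -> DesignMatrix:
    """k-1 indicator columns (cluster k is the reference level)."""
    if assignment.k < 2:
        raise ValueError("dummy coding needs k >= 2")
    if np.any(assignment.sizes() == 0):
        raise ValueError("all clusters must be nonempty")
    cols = [(assignment.labels == j).astype(float) for j in range(1, assignment.k)]
    return DesignMatrix(np.column_stack(cols),
                        [f"cluster_{j}" for j in range(1, assignment.k)])


def _tr_model(g: np.ndarray, x: np.ndarray) -> float:
    """tr(HG) for the projector onto span{1, columns of x}."""
    proj = core.build_projection(DesignMatrix(x))
    return float(np.sum(proj.h * g))


def _gain_pvalue(g: GowerMatrix, base: np.ndarray, added: np.ndarray,
                 n_perm: int, rng: np.random.Generator) -> tuple[float, float]:
    """Permutation p-value of the variance explained beyond the base design.

    The base (k-level) columns stay fixed; the added columns' rows are
    permuted jointly, a restricted permutation of the incremental fit.
    """
    gm = g.g
    tr_base = _tr_model(gm, base)
    gain_obs = _tr_model(gm, np.column_stack([base, added])) - tr_base
    exceed = 0
    n = base.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gain = _tr_model(gm, np.column_stack([base, added[perm]])) - tr_base
        if gain >= gain_obs - 1e-12 * max(1.0, abs(gain_obs)):
            exceed += 1
    return (1 + exceed) / (n_perm + 1), gain_obs


def _structure_pvalue(data: DataMatrix, f_obs: float, method: str,
                      n_ref: int, rng: np.random.Generator,
                      measure: str = "euclidean") -> float:
    """Selection-aware test that any cluster structure exists at all.

    Labels produced by clustering the very distances being tested always
    explain a large share of them, so the naive permutation p-value of a
    fitted k=2 solution is anti-conservative even on pure noise.  The
    reference null here destroys inter-sample structure while keeping every
    variable's marginal distribution: each variable is independently
    permuted across samples, the pipeline (distance, clustering at k=2,
    dummy-coded MDMR trace ratio) is re-run, and the observed statistic is
    compared to the resulting reference distribution.
    """
    from .distance import compute_distance_matrix, gower_center

    values = data.values
    n, p = values.shape
    exceed = 0
    for _ in range(n_ref):
        ref = np.empty_like(values)
        for j in range(p):
            ref[:, j] = values[rng.permutation(n), j]
        rdat = DataMatrix(ref, data.sample_ids, data.variable_ids)
        rdm = compute_distance_matrix(rdat, measure=measure)
        rg = gower_center(rdm)
        try:
            if method == "upgma":
                assign = cut_tree(upgma(rdm), 2)
            else:
                assign = kmeans_assign(rdat, 2, seed=int(rng.integers(2**31)))
            f_ref = core.pseudo_f(rg, core.build_projection(dummy_code(assign)))[0]
        except ValueError:
            continue
        if f_ref >= f_obs - 1e-12 * max(1.0, abs(f_obs)):
            exceed += 1
    return (1 + exceed) / (n_ref + 1)


def select_k(dm: DistanceMatrix, g: GowerMatrix, k_max: int,
             method: str = "upgma", n_perm: int = 199, seed: int = 0,
             data: DataMatrix | None = None, alpha: float = 0.05,
             p_variables: int = 1) -> ClusterScan:
    """Scan k = 2..k_max cluster solutions and pick the supported count.

    For each k the data are clustered (UPGMA cut of ``dm``, or k-means on
    ``data``), memberships are dummy-coded, and a full MDMR fit is recorded.
    selected_k is the smallest k whose own test is significant but whose
    k -> k+1 incremental gain in explained variation is not (restricted
    permutation test at ``alpha``); 1 is reported when no cluster structure
    is detected at all, and the argmax-F fallback is always recorded
    alongside.  When the raw ``data`` are available the any-structure gate
    uses a selection-aware reference null (variables independently permuted
    across samples, clustering re-run per draw); without raw data it falls
    back on the k=2 fit's own permutation p-value, which is
    anti-conservative because the labels were derived from the distances
    under test.
    """
    n = dm.n_samples
    if not 2 <= k_max < n:
        raise ValueError(f"k_max must be in 2..{n - 1}, got {k_max}")
    if method not in ("upgma", "kmeans"):
        raise ValueError("method must be 'upgma' or 'kmeans'")
    if method == "kmeans" and data is None:
        raise ValueError("k-means selection requires the raw data matrix")
    rng = np.random.default_rng(seed)
    tree = upgma(dm) if method == "upgma" else None

    assignments: dict[int, ClusterAssignment] = {}
    records: list[dict] = []
    trace: list[str] = []
    for k in range(2, k_max + 2):  # one past k_max to test the last increment
        if k > n - 1:
            break
        try:
            if method == "upgma":
                assignments[k] = cut_tree(tree, k)
            else:
                assignments[k] = kmeans_assign(data, k, seed=int(rng.integers(2**31)))
        except ValueError as err:
            trace.append(f"k={k}: clustering failed ({err})")
            continue
        if k > k_max:
            continue
        design = dummy_code(assignments[k])
        try:
            res = core.mdmr(g, design, n_perm=n_perm,
                            seed=int(rng.integers(2**31)),
                            p_variables=p_variables)
            records.append({"k": k, "f_raw": res.f_raw,
                            "f_scaled": res.f_scaled,
                            "p_permutation": res.p_permutation,
                            "variance_fraction": res.variance_fraction})
        except ValueError as err:
            trace.append(f"k={k}: MDMR failed ({err})")

    by_k = {r["k"]: r for r in records}
    argmax_k = max(by_k, key=lambda k: by_k[k]["f_scaled"]) if by_k else 1

    selected = None
    if 2 in by_k and data is not None:
        p_gate = _structure_pvalue(data, by_k[2]["f_raw"], method, n_perm,
                                   rng, measure=dm.measure_name
                                   if dm.measure_name in ("euclidean", "manhattan",
                                                          "pearson_corr")
                                   else "euclidean")
        trace.append(f"any-structure gate (selection-aware reference null): "
                     f"p = {p_gate:.4g}")
    elif 2 in by_k:
        p_gate = by_k[2]["p_permutation"]
        trace.append(f"any-structure gate (naive k=2 permutation p, raw data "
                     f"unavailable): p = {p_gate:.4g}")
    else:
        p_gate = 1.0
    if p_gate > alpha:
        selected = 1
        trace.append("k=2 not significant: no cluster structure detected, "
                     "selected_k = 1")
    else:
        for k in sorted(by_k):
            if k + 1 not in assignments:
                break
            base = dummy_code(assignments[k]).x
            added = dummy_code(assignments[k + 1]).x
            p_gain, gain = _gain_pvalue(g, base, added, n_perm, rng)
            trace.append(f"k={k}->{k + 1}: gain in tr(HGH) = {gain:.4g}, "
                         f"permutation p = {p_gain:.4g}")
            if p_gain > alpha:
                selected = k
                trace.append(f"increment {k}->{k + 1} not significant "
                             f"(p > {alpha}): selected_k = {k}")
                break
        if selected is None:
            selected = argmax_k
            trace.append("all increments significant: falling back to "
                         f"argmax f_scaled = {argmax_k}")
    return ClusterScan(records, selected, argmax_k, trace)
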