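"""Perturbation adjustment: cluster subjects by their PV profiles, then
standardize over the clusters.

Adjusting for a whole panel of m binary PVs directly is impossible — the
joint variable has 2^m levels — so subjects are grouped by agglomerative
complete-linkage clustering on the distance

    D(A, B) = (1/m) * sum_k (PV_k^A - PV_k^B)^2 ,

the mean squared coordinate difference between PV profiles (for binary
profiles, the Hamming distance). Starting from singletons, the two
closest clusters are merged repeatedly — inter-cluster distance updated
by the complete-linkage rule D(CD, E) = max(D(C,E), D(D,E)) — until every
cluster holds at least ``n_c`` subjects. In high PV dimension, within-
stratum pairs of the unmeasured factor are systematically closer than
between-stratum pairs, so the clusters reconstruct the latent strata and
standardizing over them (formula in :mod:`perturbkit.adjust`) removes the
confounding bias.

Estimator classes follow scikit-learn conventions (`fit`, `labels_`,
`get_params`); `perturbation_adjusted_rr` and friends are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .adjust import Stratification, adjusted_rr
from .errors import NonEstimableError, ValidationError
from .simulate import SubjectPanel

__all__ = [
    "pv_distance",
    "ClusterAssignment",
    "agglomerate",
    "PVClusterer",
    "PerturbationAdjuster",
    "perturbation_adjusted_rr",
    "stratified_perturbation_adjusted_rr",
]


def pv_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared coordinate difference between two PV profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("pv_distance needs two equal-length non-empty vectors")
    return float(np.mean((x - y) ** 2))


@dataclass(frozen=True)
class ClusterAssignment:
    """Result of one agglomeration: labels, sizes and the merge trace.

    ``merge_trace`` rows are ``(id_a, id_b, distance)`` in merge order,
    where a cluster's id is the smallest subject index it contains.
    """

    labels: np.ndarray
    sizes: np.ndarray
    merge_trace: list[tuple[int, int, float]]
    n_c: int

    @property
    def n_clusters(self) -> int:
        return self.sizes.shape[0]


def agglomerate(pv_matrix: np.ndarray, n_c: int = 20) -> ClusterAssignment:
    """Complete-linkage agglomeration until every cluster has >= n_c subjects.

    Deterministic: among equally close pairs the one with the
    lexicographically smallest (id, id) is merged, ids being the smallest
    subject index in each cluster. If n < n_c everything ends up in a
    single cluster.
    """
    X = np.asarray(pv_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("pv_matrix must be (n, m) with m >= 1")
    if n_c < 1:
        raise ValidationError("n_c must be >= 1")
    n, m = X.shape

    sizes = np.ones(n)
    # pairwise mean squared differences via the Gram expansion
    sq = np.sum(X * X, axis=1)
    D = (sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)) / m
    np.fill_diagonal(D, np.inf)
    D[np.tril_indices(n)] = np.inf  # keep only i < j; also masks merged rows
    active = np.ones(n, dtype=bool)
    member_of = np.arange(n)  # subject -> current cluster id (min member index)
    trace: list[tuple[int, int, float]] = []

    while active.sum() > 1 and sizes[active].min() < n_c:
        flat = int(np.argmin(D))
        i, j = divmod(flat, n)  # i < j, lexicographically first minimum
        dist = D[i, j]
        trace.append((int(i), int(j), float(max(dist, 0.0))))
        # complete linkage: new distances are elementwise maxima
        row = np.maximum(
            np.minimum(D[i, :], D[:, i]), np.minimum(D[j, :], D[:, j])
        )
        D[i, i + 1 :] = row[i + 1 :]
        D[:i, i] = row[:i]
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        active[j] = False
        member_of[member_of == j] = i

    labels = np.unique(member_of, return_inverse=True)[1]
    out_sizes = np.bincount(labels).astype(int)
    return ClusterAssignment(
        labels=labels, sizes=out_sizes, merge_trace=trace, n_c=n_c
    )


class PVClusterer(ClusterMixin, BaseEstimator):
    """Scikit-learn style wrapper around :func:`agglomerate`.

    Parameters
    ----------
    min_cluster_size : int, default=20
        The stopping threshold n_c: merging continues while any cluster
        is smaller than this.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster label per subject.
    sizes_ : ndarray
        Cluster sizes.
    assignment_ : ClusterAssignment
        Full result including the merge trace.
    """

    def __init__(self, min_cluster_size: int = 20):
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.assignment_ = agglomerate(X, self.min_cluster_size)
        self.labels_ = self.assignment_.labels
        self.sizes_ = self.assignment_.sizes
        self.n_features_in_ = X.shape[1]
        return self


def _complete_linkage_cluster_distances(
    X: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Max pairwise PV distance between clusters, from raw profiles."""
    n, m = X.shape
    sq = np.sum(X * X, axis=1)
    D = (sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)) / m
    K = labels.max() + 1
    out = np.full((K, K), -np.inf)
    for a in range(K):
        ia = labels == a
        for b in range(a + 1, K):
            d = D[np.ix_(ia, labels == b)].max()
            out[a, b] = out[b, a] = d
    return out


def _standardize_over_clusters(
    e: np.ndarray,
    d: np.ndarray,
    labels: np.ndarray,
    pv: np.ndarray,
    invalid_policy: str,
) -> float:
    """Apply the standardization formula with clusters as strata."""
    if invalid_policy == "merge":
        # force-merge clusters lacking an exposure group into their
        # complete-linkage nearest neighbour until all are valid
        labels = np.asarray(labels).copy()
        while True:
            strat = Stratification.from_labels(e, d, labels)
            codes = np.unique(labels)
            bad = codes[~strat.valid.astype(bool)]
            if bad.size == 0 or codes.size == 1:
                break
            dense = np.searchsorted(codes, labels)
            cd = _complete_linkage_cluster_distances(pv, dense)
            worst = bad[0]
            wi = int(np.searchsorted(codes, worst))
            target = int(np.argmin(np.where(np.isfinite(cd[wi]), cd[wi], np.inf)))
            labels[labels == worst] = codes[target]
        return adjusted_rr(Stratification.from_labels(e, d, labels), "drop")
    return adjusted_rr(Stratification.from_labels(e, d, labels), invalid_policy)


class PerturbationAdjuster(BaseEstimator):
    """Perturbation adjustment of a risk ratio.

    Clusters subjects on their PV panel (complete linkage, minimum
    cluster size ``min_cluster_size``) and standardizes the exposure-
    disease risk ratio over the clusters. With enough informative PVs the
    result converges to the standardized risk ratio the unmeasured
    confounder would have allowed, had it been observed.

    Parameters
    ----------
    min_cluster_size : int, default=20
        Stopping threshold n_c of the agglomeration.
    invalid_policy : {"drop", "collapse", "merge"}, default="drop"
        How clusters lacking exposed or unexposed subjects enter the
        standardization: dropped from both sums, collapsed into the
        largest valid cluster, or force-merged into their nearest
        neighbour.

    Attributes
    ----------
    adjusted_rr_ : float
        The perturbation-adjusted risk ratio.
    assignment_ : ClusterAssignment
        Clustering audit trail (single assignment, or per confounder
        level when ``confounders`` were given to :meth:`fit`).
    """

    def __init__(self, min_cluster_size: int = 20, invalid_policy: str = "drop"):
        self.min_cluster_size = min_cluster_size
        self.invalid_policy = invalid_policy

    def fit(self, X, y, confounders: pd.DataFrame | None = None):
        """Fit on a PV matrix X (n, m) and y = (n, 2) array of [E, D].

        ``confounders``: optional categorical frame; clustering then runs
        separately within each measured-confounder level and the final
        standardization spans the union of all clusters.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != X.shape[0]:
            raise ValidationError("y must be an (n, 2) array of [E, D] columns")
        e, d = y[:, 0].astype(int), y[:, 1].astype(int)
        if not (np.isin(e, (0, 1)).all() and np.isin(d, (0, 1)).all()):
            raise ValidationError("E and D must be binary")

        if confounders is None:
            assignment = agglomerate(X, self.min_cluster_size)
            labels = assignment.labels
            self.assignment_ = assignment
        else:
            conf = pd.DataFrame(confounders).reset_index(drop=True)
            if len(conf) != X.shape[0]:
                raise ValidationError("confounders must have one row per subject")
            key = conf.astype(str).agg("|".join, axis=1).to_numpy()
            labels = np.empty(X.shape[0], dtype=int)
            per_level: dict[str, ClusterAssignment] = {}
            offset = 0
            for lev in np.unique(key):
                idx = np.flatnonzero(key == lev)
                asg = agglomerate(X[idx], self.min_cluster_size)
                labels[idx] = asg.labels + offset
                offset += asg.n_clusters
                per_level[lev] = asg
            self.assignment_ = per_level
        self.labels_ = labels
        self.adjusted_rr_ = _standardize_over_clusters(
            e, d, labels, X, self.invalid_policy
        )
        self.n_features_in_ = X.shape[1]
        return self


def perturbation_adjusted_rr(
    panel: SubjectPanel, n_c: int = 20, invalid_policy: str = "drop"
) -> tuple[float, ClusterAssignment]:
    """Perturbation-adjusted RR of a subject panel, plus the clustering."""
    if panel.pv is None:
        raise ValidationError("panel has no PV columns")
    adj = PerturbationAdjuster(min_cluster_size=n_c, invalid_policy=invalid_policy)
    adj.fit(panel.pv, np.column_stack([panel.e, panel.d]))
    return adj.adjusted_rr_, adj.assignment_


def stratified_perturbation_adjusted_rr(
    panel: SubjectPanel,
    n_c: int = 20,
    invalid_policy: str = "drop",
    confounders: list[str] | None = None,
) -> float:
    """Perturbation adjustment honouring measured confounders.

    Clustering runs separately within each level delineated by the
    measured-confounder columns of the panel; the standardization then
    spans all resulting clusters. With a constant confounder this equals
    the plain perturbation adjustment.
    """
    if panel.pv is None:
        raise ValidationError("panel has no PV columns")
    if panel.confounders is None or len(panel.confounders.columns) == 0:
        raise ValidationError("panel has no confounder columns")
    conf = panel.confounders
    if confounders is not None:
        missing = set(confounders) - set(conf.columns)
        if missing:
            raise ValidationError(f"unknown confounder columns: {sorted(missing)}")
        conf = conf[confounders]
    adj = PerturbationAdjuster(min_cluster_size=n_c, invalid_policy=invalid_policy)
    adj.fit(panel.pv, np.column_stack([panel.e, panel.d]), confounders=conf)
    return adj.adjusted_rr_
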