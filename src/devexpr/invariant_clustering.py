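"""Translation/scale-invariant profile distance and hierarchical clustering.

The distance between two ratio profiles X and Y on a shared N-point grid is

    D(X, Y) = sqrt( (s_X s_Y / N) * sum_k (x_k -+ y_k)^2 ),

where x, y are the standardized profiles ((X - <X>)/s_X with population
standard deviation s) and the sign minimizing D is chosen.  Expanding the
square gives the closed form

    D(X, Y) = sqrt( 2 s_X s_Y (1 - |r|) ),

with r the Pearson correlation.  D is translation-invariant
(D(X, Y+b) = D(X, Y)) and scale-invariant with scaling dimension 1/2
(D(X, aY) = sqrt(a) D(X, Y) for a > 0), which makes it insensitive to the
gene-specific reference-intensity scalings inherent in ratio data.

Profiles are grouped by unweighted average-linkage hierarchical clustering
on this distance, the tree is cut at a user-chosen number of classes C, and
each class is summarized by the pointwise mean of its members after each is
affinely superimposed (a*X+b, least squares) on the class representative
(the member with minimal mean distance to the rest).  These cluster-average
trajectories are the state variables of the ODE models downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .profile_data import ProfileSet, TimeGrid

logger = logging.getLogger(__name__)

#: conventional class counts: 10 for an embryonic-only series, 12 for a
#: full developmental series (choosing C is a judgement call; these are the
#: documented defaults for the two canonical series shapes)
DEFAULT_N_CLUSTERS = {"embryonic": 10, "full": 12}

__all__ = [
    "DEFAULT_N_CLUSTERS",
    "ProfileMoments",
    "MergeTree",
    "ClusterSet",
    "AlignmentParams",
    "ClusterProfiles",
    "profile_moments",
    "invariant_distance",
    "pairwise_invariant_distance",
    "average_linkage_cluster",
    "representative_profile",
    "align_to_reference",
    "cluster_average_profiles",
    "InvariantProfileClustering",
]


@dataclass(frozen=True)
class ProfileMoments:
    mean: float
    sd: float  # population (1/N) standard deviation


@dataclass(frozen=True)
class MergeTree:
    """Average-linkage merge history in scipy linkage-matrix form.

    Heights are average pairwise distances; with average linkage they are
    not guaranteed monotone (inversions possible) and this is not enforced.
    """

    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.linkage_matrix.shape[0] + 1


@dataclass(frozen=True)
class ClusterSet:
    """Flat cut of the tree: C classes labelled 1..C."""

    n_clusters: int
    assignment: dict[str, int]           # gene_id -> class in 1..C
    representatives: dict[int, str]      # class -> representative gene_id

    def members(self, c: int) -> list[str]:
        return [g for g, cc in self.assignment.items() if cc == c]


@dataclass(frozen=True)
class AlignmentParams:
    scale: float
    shift: float


@dataclass(frozen=True)
class ClusterProfiles:
    """Cluster-average trajectories Xbar_c(tau_k), shape (C, N)."""

    grid: TimeGrid
    trajectories: np.ndarray

    def __post_init__(self):
        tr = np.atleast_2d(np.asarray(self.trajectories, float))
        object.__setattr__(self, "trajectories", tr)
        if tr.shape[1] != self.grid.n_points:
            raise ValueError("trajectory length does not match grid")
        if not np.all(np.isfinite(tr)):
            raise ValueError("non-finite cluster trajectory")

    @property
    def n_clusters(self) -> int:
        return self.trajectories.shape[0]


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def profile_moments(values) -> ProfileMoments:
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 points")
    return ProfileMoments(float(v.mean()), float(v.std()))


def invariant_distance(x, y) -> float:
    """Two-profile invariant distance; 0 when either profile is constant
    (the prefactor s_X s_Y vanishes in the limit)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the grid")
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.dot(x - x.mean(), y - y.mean()) / (x.size * sx * sy))
    return float(np.sqrt(2.0 * sx * sy * max(0.0, 1.0 - min(1.0, abs(r)))))


def pairwise_invariant_distance(X: np.ndarray) -> np.ndarray:
    """Symmetric (n, n) matrix of invariant distances between the rows of X.

    Constant rows (zero sd) are at distance 0 from everything; flat genes
    therefore merge early, which is logged.
    """
    X = np.asarray(X, float)
    n, N = X.shape
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        logger.warning("%d constant profile(s): at invariant distance 0 "
                       "from every profile", int(flat.sum()))
    Z = np.zeros_like(X)
    np.divide(X - mu, sd[:, None], out=Z, where=~flat[:, None])
    R = np.abs(Z @ Z.T / N)
    np.clip(R, 0.0, 1.0, out=R)
    D = 2.0 * np.outer(sd, sd) * (1.0 - R)
    np.clip(D, 0.0, None, out=D)
    D = np.sqrt(D)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def average_linkage_cluster(distance_matrix: np.ndarray, n_clusters: int
                            ) -> tuple[MergeTree, np.ndarray]:
    """Unweighted average linkage (UPGMA merge criterion over all
    inter-class pairs of original profiles), cut to exactly ``n_clusters``
    flat classes.

    Returns the merge tree and 1-based labels (relabelled in order of first
    appearance, so label numbering is deterministic).
    """
    D = np.asarray(distance_matrix, float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric distance matrix with zero diagonal")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n == 1:
        return MergeTree(np.empty((0, 4))), np.array([1])
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel by first appearance for determinism
    relabel, labels = {}, np.empty(n, int)
    for i, c in enumerate(raw):
        labels[i] = relabel.setdefault(c, len(relabel) + 1)
    return MergeTree(Z), labels


def representative_profile(members: list[str], D: np.ndarray) -> str:
    """Member with minimal mean distance to the other members
    (ties: lexicographically smallest gene_id; singleton: that member)."""
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    mean_d = D.sum(axis=1) / (len(members) - 1)
    best = min(range(len(members)), key=lambda i: (mean_d[i], members[i]))
    return members[best]


def align_to_reference(x, r) -> tuple[AlignmentParams, np.ndarray]:
    """Least-squares affine superposition a*x + b -> r.

    a = cov(x, r)/var(x), b = <r> - a<x>.  A constant member (zero sd) is
    mapped to the constant <r> with a = 0.  The slope may be negative,
    consistent with the minimizing-sign freedom of the distance.
    """
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    var = x.var()
    if var == 0.0:
        a = 0.0
    else:
        a = float(np.dot(x - x.mean(), r - r.mean()) / (x.size * var))
    b = float(r.mean() - a * x.mean())
    return AlignmentParams(a, b), a * x + b


def cluster_average_profiles(pset: ProfileSet, clusters: ClusterSet
                             ) -> ClusterProfiles:
    """Pointwise mean over cluster members after affine superposition on
    the class representative."""
    by_id = {p.gene_id: p.values for p in pset.profiles}
    out = np.empty((clusters.n_clusters, pset.grid.n_points))
    for c in range(1, clusters.n_clusters + 1):
        ref = by_id[clusters.representatives[c]]
        aligned = [align_to_reference(by_id[g], ref)[1]
                   for g in clusters.members(c)]
        out[c - 1] = np.mean(aligned, axis=0)
    return ClusterProfiles(pset.grid, out)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class InvariantProfileClustering(ClusterMixin, BaseEstimator):
    """Average-linkage clustering of expression profiles under the
    invariant distance, with representative selection and cluster-average
    trajectories.

    Parameters
    ----------
    n_clusters : int, default=10
        Number of classes C the tree is cut to.  Choosing C is a judgement
        call; 10 suits an embryonic-only series and 12 a full
        developmental series at the scale this method targets.

    Attributes
    ----------
    labels_ : (n_genes,) int array, classes 1..C.
    merge_tree_ : MergeTree.
    distance_matrix_ : (n, n) invariant distances.
    cluster_set_ : ClusterSet (assignment + representatives).
    cluster_profiles_ : ClusterProfiles, shape (C, N).
    """

    def __init__(self, n_clusters: int = 10):
        self.n_clusters = n_clusters

    def fit(self, X, y=None, *, grid: TimeGrid | None = None,
            gene_ids: list[str] | None = None):
        """Cluster rows of X ((n_genes, N) array or a ProfileSet)."""
        if isinstance(X, ProfileSet):
            pset = X
        else:
            X = np.asarray(X, float)
            if grid is None:
                grid = TimeGrid(np.arange(X.shape[1], dtype=float),
                                ("embryonic",) * X.shape[1])
            ids = gene_ids or [f"g{i+1}" for i in range(X.shape[0])]
            from .profile_data import ExpressionProfile
            pset = ProfileSet(grid, tuple(
                ExpressionProfile(g, np.clip(row, 0.0, None))
                for g, row in zip(ids, X)))
        M = pset.values_matrix()
        self.distance_matrix_ = pairwise_invariant_distance(M)
        self.merge_tree_, self.labels_ = average_linkage_cluster(
            self.distance_matrix_, self.n_clusters)
        ids = pset.gene_ids
        assignment = {g: int(c) for g, c in zip(ids, self.labels_)}
        reps = {}
        for c in range(1, self.n_clusters + 1):
            idx = np.flatnonzero(self.labels_ == c)
            sub = self.distance_matrix_[np.ix_(idx, idx)]
            reps[c] = representative_profile([ids[i] for i in idx], sub)
        self.cluster_set_ = ClusterSet(self.n_clusters, assignment, reps)
        self.cluster_profiles_ = cluster_average_profiles(pset, self.cluster_set_)
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, **kw).labels_
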