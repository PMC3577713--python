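"""Ordination and group statistics over presence/absence fingerprints.

Dice distances between samples, classical (metric) MDS, seeded k-means
clusters with bivariate-normal confidence ellipses, and per-group TRF
richness contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .trflp import BinnedMatrix, to_presence_absence

__all__ = [
    "DistanceMatrix",
    "Ellipse",
    "RichnessSummary",
    "dice_distance",
    "mds_ordination",
    "kmeans_clusters",
    "confidence_ellipse",
    "richness_contrast",
    "CommunityOrdination",
]


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must have zero diagonal")


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse: center, semi-axes lengths, rotation angle."""

    center: tuple[float, float]
    axes: tuple[float, float]  # (major, minor) semi-axis lengths
    angle: float  # radians, orientation of the major axis
    level: float
    degenerate: bool = False


@dataclass(frozen=True)
class RichnessSummary:
    group_label: str
    n: int
    mean_trf_count: float
    sd_trf_count: float
    test_p: float


def dice_distance(
    presence: np.ndarray, sample_ids: tuple[str, ...] | None = None
) -> DistanceMatrix:
    """Dice dissimilarity 1 - 2a/(2a+b+c) between presence/absence rows.

    A pair of all-absent samples is defined to have distance 0 (they are
    identical in presence/absence space).
    """
    presence = np.asarray(presence)
    if presence.ndim != 2 or presence.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.isin(presence, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if sample_ids is None:
        sample_ids = tuple(f"S{i}" for i in range(presence.shape[0]))
    with np.errstate(invalid="ignore"):
        condensed = pdist(presence.astype(bool), metric="dice")
    condensed = np.nan_to_num(condensed, nan=0.0)  # both-empty pairs
    return DistanceMatrix(tuple(sample_ids), squareform(condensed))


def mds_ordination(
    dist: DistanceMatrix, dims: int = 2
) -> tuple[np.ndarray, float]:
    """Classical (metric) scaling / principal coordinates.

    Double-centers the squared-distance matrix, eigendecomposes it, and
    returns the top ``dims`` coordinate axes ordered by eigenvalue plus
    the proportion of positive eigenvalue mass they capture. Axis signs
    are canonicalized (first nonzero loading of each axis positive), so
    the embedding is deterministic.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d = dist.d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    coords = np.zeros((n, dims))
    kept = 0.0
    for k in range(min(dims, n)):
        lam = eigvals[k]
        if lam > 1e-12:
            coords[:, k] = eigvecs[:, k] * np.sqrt(lam)
            kept += lam
    pos_mass = float(eigvals[eigvals > 1e-12].sum())
    fit = kept / pos_mass if pos_mass > 0 else 1.0

    for k in range(dims):  # sign canonicalization
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords, float(fit)


def kmeans_clusters(
    coordinates: np.ndarray, k: int, seed: int = 0, restarts: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded k-means on ordination coordinates.

    Best of ``restarts`` initializations by within-cluster sum of
    squares; labels are canonicalized by ascending first coordinate of
    the cluster centers so the labelling is reproducible.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    n = coordinates.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw_labels = km.fit_predict(coordinates)
    centers = km.cluster_centers_
    order = np.argsort(centers[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw_labels], centers[order]


def confidence_ellipse(points: np.ndarray, level: float) -> Ellipse:
    """Bivariate-normal confidence ellipse of a 2-D point cloud.

    The ellipse is centered on the mean with shape given by the sample
    covariance scaled by the chi-square(2 df) quantile at ``level``;
    semi-axes are sqrt(eigenvalue x quantile) and the angle comes from
    the leading eigenvector. Collinear points give a degenerate ellipse
    (minor axis 0, flagged).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    q = stats.chi2.ppf(level, df=2)
    eigvals, eigvecs = linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0, None)
    # eigh returns ascending order; major axis last
    major, minor = np.sqrt(eigvals[1] * q), np.sqrt(eigvals[0] * q)
    vec = eigvecs[:, 1]
    angle = float(np.arctan2(vec[1], vec[0]))
    degenerate = bool(eigvals[0] <= 1e-12 * max(eigvals[1], 1.0))
    return Ellipse(
        center=(float(center[0]), float(center[1])),
        axes=(float(major), float(minor)),
        angle=angle,
        level=level,
        degenerate=degenerate,
    )


def point_in_ellipse(point: np.ndarray, ellipse: Ellipse) -> bool:
    """Whether a 2-D point lies inside (or on) the ellipse."""
    c, s = np.cos(ellipse.angle), np.sin(ellipse.angle)
    rot = np.array([[c, s], [-s, c]])
    rel = rot @ (np.asarray(point, dtype=float) - np.asarray(ellipse.center))
    a, b = ellipse.axes
    if b == 0:
        return False
    return float((rel[0] / a) ** 2 + (rel[1] / b) ** 2) <= 1.0


def _trf_counts(matrix: BinnedMatrix) -> np.ndarray:
    return to_presence_absence(matrix).sum(axis=1)


def welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch two-sample t-test p-value (1 if both degenerate)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def permutation_p(
    x: np.ndarray, y: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> float:
    """Two-sided permutation test on the difference of group means."""
    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    observed = abs(x.mean() - y.mean())
    nx = len(x)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:nx].mean() - perm[nx:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def richness_contrast(
    matrix: BinnedMatrix,
    group_assignment: dict[str, str],
    focal: str = "focal",
    other: str = "other",
) -> tuple[RichnessSummary, RichnessSummary]:
    """Per-group TRF richness (nonzero bins per sample) comparison.

    Returns (focal, other) summaries carrying the common two-sided
    Welch p-value. Groups of size 1 are rejected (sd undefined).
    """
    counts = _trf_counts(matrix)
    groups: dict[str, list[int]] = {focal: [], other: []}
    for sid, c in zip(matrix.sample_ids, counts):
        g = group_assignment.get(sid)
        if g in groups:
            groups[g].append(int(c))
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has a single sample; sd undefined")
    xf = np.array(groups[focal], dtype=float)
    xo = np.array(groups[other], dtype=float)
    p = welch_p(xf, xo)
    return (
        RichnessSummary(focal, len(xf), float(xf.mean()), float(xf.std(ddof=1)), p),
        RichnessSummary(other, len(xo), float(xo.mean()), float(xo.std(ddof=1)), p),
    )


class CommunityOrdination(BaseEstimator):
    """Dice -> MDS -> k-means -> confidence ellipses, sklearn-style.

    Parameters
    ----------
    n_clusters:
        k for the k-means step (default 2: baseline vs shifted regime).
    random_state:
        Seed for k-means initializations.
    restarts:
        Number of k-means initializations.
    levels:
        Confidence levels for the per-cluster ellipses.

    Attributes (after ``fit`` on a binary samples x TRFs matrix)
    ----------
    distance_ : DistanceMatrix
    coordinates_ : ndarray of shape (n_samples, 2)
    fit_ : float — positive-eigenvalue mass captured by the 2 axes
    labels_ : ndarray of cluster labels
    cluster_centers_ : ndarray of shape (n_clusters, 2)
    ellipses_ : dict[(cluster, level) -> Ellipse]
    """

    def __init__(
        self,
        n_clusters: int = 2,
        random_state: int = 0,
        restarts: int = 50,
        levels: tuple[float, ...] = (0.50, 0.95),
    ):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.restarts = restarts
        self.levels = levels

    def fit(self, X: np.ndarray, y=None, sample_ids=None) -> "CommunityOrdination":
        X = np.asarray(X)
        self.distance_ = dice_distance(X, sample_ids)
        self.coordinates_, self.fit_ = mds_ordination(self.distance_, dims=2)
        self.labels_, self.cluster_centers_ = kmeans_clusters(
            self.coordinates_,
            self.n_clusters,
            seed=self.random_state,
            restarts=self.restarts,
        )
        self.ellipses_ = {}
        for c in range(self.n_clusters):
            pts = self.coordinates_[self.labels_ == c]
            for level in self.levels:
                if len(pts) >= 3:
                    self.ellipses_[(c, level)] = confidence_ellipse(pts, level)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_
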