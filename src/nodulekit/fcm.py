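"""Fuzzy C-means clustering and the nodule-segmentation wrapper.

Fuzzy C-means (FCM) assigns every point a graded membership in each of the
``c`` clusters and minimises the weighted within-cluster squared error

    D(W, C) = sum_i sum_k  w_ik^x  ||h_k - d_i||^2,

where the fuzzifier ``x > 1`` controls how soft the memberships are.  The
classical alternating updates are

    w_ik = 1 / sum_j (||h_k - d_i|| / ||h_k - d_j||)^(2 / (x - 1)),
    d_i  = sum_k w_ik^x h_k / sum_k w_ik^x,

and each half-step decreases the objective, so ``objective_history`` is
non-increasing.

:func:`segment_nodules` clusters per-pixel feature vectors (smoothed
intensity, plus optional backbone channels) inside the lung mask and
returns the brightest cluster as the nodule mask, guarded by a
cluster-separation gate so that a nodule-free lung yields an empty mask
rather than half of the noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage import morphology
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)

__all__ = [
    "FCMConfig",
    "FuzzyPartition",
    "fcm_objective",
    "update_memberships",
    "update_centers",
    "fcm_cluster",
    "FuzzyCMeans",
    "segment_nodules",
]


@dataclass(frozen=True)
class FCMConfig:
    n_clusters: int = 2
    fuzzifier: float = 2.0
    tolerance: float = 1e-5
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1 (1 degenerates to hard clustering)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class FuzzyPartition:
    """Row-stochastic membership matrix plus cluster centers."""

    memberships: np.ndarray          # (n_points, c), rows sum to 1
    centers: np.ndarray              # (c, dim)
    objective_history: list = field(default_factory=list)
    n_iter: int = 0

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment: argmax membership, ties to the lower index."""
        return np.argmax(self.memberships, axis=1)


def fcm_objective(W: np.ndarray, C: np.ndarray, data: np.ndarray, x: float) -> float:
    """Weighted within-cluster squared error D(W, C)."""
    d2 = cdist(np.atleast_2d(data), np.atleast_2d(C), "sqeuclidean")  # (n, c)
    return float(np.sum((W ** x) * d2))


def update_memberships(data: np.ndarray, C: np.ndarray, x: float) -> np.ndarray:
    """Membership update; a point sitting exactly on a center gets membership 1 there.

    When a point coincides with several centers the unit membership is
    split uniformly among them (limit of the update along any approach
    path is ambiguous; the uniform split keeps rows stochastic).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    dist = cdist(data, C)  # (n, c)
    W = np.zeros_like(dist)
    zero_rows = (dist == 0).any(axis=1)
    if zero_rows.any():
        hits = dist[zero_rows] == 0
        W[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    reg = ~zero_rows
    if reg.any():
        p = 2.0 / (x - 1.0)
        ratios = (dist[reg][:, :, None] / dist[reg][:, None, :]) ** p  # (n, c, c)
        W[reg] = 1.0 / ratios.sum(axis=2)
    return W


def update_centers(
    data: np.ndarray,
    W: np.ndarray,
    x: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Center update: fuzzily weighted means of the data.

    A cluster whose total membership weight is zero is re-seeded at a
    random data point (warning logged); with ``rng=None`` the first data
    point is used so the operation stays deterministic.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    Wx = W ** x
    weights = Wx.sum(axis=0)  # (c,)
    centers = np.empty((W.shape[1], data.shape[1]))
    for i in range(W.shape[1]):
        if weights[i] == 0:
            logger.warning("cluster %d lost all membership weight; re-seeding", i)
            idx = int(rng.integers(len(data))) if rng is not None else 0
            centers[i] = data[idx]
        else:
            centers[i] = (Wx[:, i] @ data) / weights[i]
    return centers


def fcm_cluster(data: np.ndarray, config: FCMConfig,
                init_centers: np.ndarray | None = None) -> FuzzyPartition:
    """Alternate the membership/center updates from a seeded start.

    Centers are initialised at ``c`` distinct random data points (or at the
    explicitly supplied ``init_centers``); iteration stops when the maximum
    center displacement drops below the tolerance or ``max_iter`` is
    reached.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if n < config.n_clusters:
        raise ValueError("too few points: need at least one point per cluster")
    rng = np.random.default_rng(config.seed)
    if init_centers is not None:
        centers = np.atleast_2d(np.asarray(init_centers, dtype=float)).copy()
        if centers.shape != (config.n_clusters, data.shape[1]):
            raise ValueError("init_centers shape must be (n_clusters, dim)")
    else:
        # distinct starting points; fall back to distinct *values* when the
        # data contain duplicates that would collapse two centers
        idx = rng.choice(n, size=config.n_clusters, replace=False)
        centers = data[idx].astype(float).copy()
        if config.n_clusters > 1 and len(np.unique(centers, axis=0)) < config.n_clusters:
            uniq = np.unique(data, axis=0)
            take = min(len(uniq), config.n_clusters)
            centers[:take] = uniq[rng.choice(len(uniq), size=take, replace=False)]

    history: list[float] = []
    W = update_memberships(data, centers, config.fuzzifier)
    for it in range(1, config.max_iter + 1):
        new_centers = update_centers(data, W, config.fuzzifier, rng)
        W = update_memberships(data, new_centers, config.fuzzifier)
        history.append(fcm_objective(W, new_centers, data, config.fuzzifier))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < config.tolerance:
            break
    return FuzzyPartition(memberships=W, centers=centers,
                          objective_history=history, n_iter=it)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means as a scikit-learn style clusterer.

    Parameters
    ----------
    n_clusters : int, default=2
    fuzzifier : float, default=2.0
        Softness exponent ``x > 1``; as ``x -> 1+`` assignments approach
        k-means hardness.
    tol : float, default=1e-5
        Convergence threshold on the maximum center displacement.
    max_iter : int, default=300
    random_state : int or None
        Seed for center initialisation.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    memberships_ : ndarray of shape (n_samples, n_clusters)
    labels_ : ndarray of shape (n_samples,)
    objective_history_ : list of float, non-increasing
    n_iter_ : int
    """

    def __init__(self, n_clusters=2, fuzzifier=2.0, tol=1e-5, max_iter=300,
                 random_state=None):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        config = FCMConfig(
            n_clusters=self.n_clusters,
            fuzzifier=self.fuzzifier,
            tolerance=self.tol,
            max_iter=self.max_iter,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        part = fcm_cluster(X, config)
        self.cluster_centers_ = part.centers
        self.memberships_ = part.memberships
        self.labels_ = part.labels
        self.objective_history_ = part.objective_history
        self.n_iter_ = part.n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict_memberships(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return update_memberships(X, self.cluster_centers_, self.fuzzifier)

    def predict(self, X):
        return np.argmax(self.predict_memberships(X), axis=1)


def segment_nodules(
    roi: np.ndarray,
    lobe_mask: np.ndarray,
    backbone=None,
    config: FCMConfig | None = None,
    separation_threshold: float = 4.0,
    opening_radius: int = 1,
    smoothing_sigma: float = 1.5,
) -> np.ndarray:
    """Segment bright nodule candidates inside the lung mask by FCM.

    Per-pixel feature vectors are built for every in-mask pixel: the
    Gaussian-smoothed intensity (``smoothing_sigma``), which suppresses
    pixel noise so that a small bright nodule forms its own mode, plus
    (when a ``backbone`` exposing ``pixel_maps(image)`` is supplied)
    per-pixel backbone channels.  Channels are standardised over the
    in-mask pixels; cluster centers start evenly spread between the
    per-channel data minima and maxima, so the extreme (bright) center is
    seeded on the nodule mode when one exists and the whole procedure is
    deterministic.  The default fuzzifier here is 1.5 — nearly hard:
    softer memberships let the large parenchyma population drag the bright
    center off a sub-percent nodule mode.

    The argmax-membership cluster with the highest mean raw intensity is
    the nodule candidate; it is accepted only when its mean raw intensity
    separates from the remaining in-mask pixels by more than
    ``separation_threshold`` pooled within-cluster standard deviations —
    otherwise the lung is considered nodule-free and an empty mask is
    returned.  A final morphological opening removes thin vessel-like
    clutter.
    """
    from scipy import ndimage

    roi = np.asarray(roi, dtype=float)
    lobe_mask = np.asarray(lobe_mask) != 0
    if roi.shape != lobe_mask.shape:
        raise ValueError("incompatible mask: shape differs from image")
    if not lobe_mask.any():
        raise ValueError("empty ROI")
    config = config or FCMConfig(fuzzifier=1.5)

    intensity = roi[lobe_mask]
    feats = [ndimage.gaussian_filter(roi, smoothing_sigma)[lobe_mask]]
    if backbone is not None:
        for channel in backbone.pixel_maps(roi):
            feats.append(channel[lobe_mask])
    X = np.column_stack(feats)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if config.n_clusters == 1:
        init = Z.mean(axis=0, keepdims=True)
    else:
        steps = np.linspace(0.0, 1.0, config.n_clusters)[:, None]
        init = Z.min(axis=0) + steps * (Z.max(axis=0) - Z.min(axis=0))
    part = fcm_cluster(Z, config, init_centers=init)
    labels = part.labels

    means = np.array([
        intensity[labels == k].mean() if (labels == k).any() else -np.inf
        for k in range(config.n_clusters)
    ])
    bright = int(np.argmax(means))
    out = np.zeros(roi.shape, dtype=np.uint8)

    if config.n_clusters > 1:
        in_b = labels == bright
        rest = ~in_b
        if not rest.any():
            return out
        pooled = np.sqrt(
            (intensity[in_b].var() * in_b.sum() + intensity[rest].var() * rest.sum())
            / intensity.size
        )
        gap = means[bright] - intensity[rest].mean()
        if pooled > 0 and gap < separation_threshold * pooled:
            logger.info("cluster separation %.2f below gate; no nodule reported",
                        gap / pooled)
            return out

    sel = np.zeros(roi.shape, dtype=bool)
    sel[lobe_mask] = labels == bright
    if opening_radius > 0:
        sel = morphology.opening(sel, morphology.disk(opening_radius))
    out[sel] = 1
    return out
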