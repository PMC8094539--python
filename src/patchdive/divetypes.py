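"""Dive-type classification by k-means with Calinski-Harabasz selection.

Dives are clustered on (bottom time, dive duration, maximum depth) — the
features tied to prey pursuit at depth.  Features are z-scored before
clustering (depth and duration live on different scales; unstandardized
k-means would be dominated by duration), but centroids are reported in raw
units.  The number of clusters is chosen by the Calinski-Harabasz
criterion CH(k) = [B/(k-1)] / [W/(n-k)] over a candidate range, and the
three clusters are mapped to travel / explore / forage labels by centroid
depth (shallowest -> travel, deepest -> forage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

logger = logging.getLogger(__name__)

FEATURES = ["bottom_time", "u", "max_depth"]
DIVE_TYPES = ("travel", "explore", "forage")
K_RANGE_DEFAULT = range(2, 9)
N_INIT_DEFAULT = 25

__all__ = ["ClusterModel", "select_k", "cluster_dives", "assign_type_labels", "classify_dives"]


@dataclass
class ClusterModel:
    k: int
    centroids_std: np.ndarray
    centroids_raw: np.ndarray  # columns in FEATURES order
    label_map: dict[int, str] = field(default_factory=dict)
    ch_scores: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _feature_matrix(dives: pd.DataFrame) -> np.ndarray:
    X = dives[FEATURES].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite dive features")
    return X


def select_k(
    dives: pd.DataFrame,
    k_range=K_RANGE_DEFAULT,
    n_init: int = N_INIT_DEFAULT,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count maximizing the Calinski-Harabasz criterion."""
    X = _feature_matrix(dives)
    Z, _, _ = _standardize(X)
    ks = sorted(k_range)
    if len(dives) <= max(ks):
        ks = [k for k in ks if k < len(dives)]
        logger.warning("fewer dives than max k; shrinking candidate range to %s", ks)
        if not ks:
            raise ValueError("too few dives to cluster")
    scores: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + k)
        labels = km.fit_predict(Z)
        scores[k] = float(calinski_harabasz_score(Z, labels))
    k_star = max(scores, key=scores.get)
    return k_star, scores


def cluster_dives(
    dives: pd.DataFrame,
    k: int,
    n_init: int = N_INIT_DEFAULT,
    seed: int = 0,
) -> tuple[pd.DataFrame, ClusterModel]:
    """k-means cluster the dive table; adds a ``cluster`` column."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _feature_matrix(dives)
    Z, mu, sd = _standardize(X)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(Z)
    counts = np.bincount(labels, minlength=k)
    if (counts == 0).any():
        raise RuntimeError(f"k-means produced an empty cluster (k={k}, seed={seed})")
    out = dives.copy()
    out["cluster"] = labels
    raw = km.cluster_centers_ * sd + mu
    model = ClusterModel(
        k=k,
        centroids_std=km.cluster_centers_,
        centroids_raw=raw,
        ch_scores={},
        seed=seed,
        feature_means=mu,
        feature_sds=sd,
    )
    return out, model


def assign_type_labels(model: ClusterModel) -> dict[int, str]:
    """Map the three clusters to dive types by centroid depth ordering.

    Shallowest -> travel, deepest -> forage, middle -> explore.  When the
    duration or bottom-time orderings disagree with depth a warning is
    emitted and the depth ordering wins.
    """
    if model.k != 3:
        logger.warning("label mapping requires k=3 (got k=%d); leaving cluster indices", model.k)
        model.label_map = {i: str(i) for i in range(model.k)}
        return model.label_map
    raw = model.centroids_raw
    depth_order = np.argsort(raw[:, FEATURES.index("max_depth")])
    for feat in ("u", "bottom_time"):
        if not np.array_equal(np.argsort(raw[:, FEATURES.index(feat)]), depth_order):
            logger.warning("centroid ordering by %s disagrees with depth ordering; depth wins", feat)
    model.label_map = {int(c): DIVE_TYPES[rank] for rank, c in enumerate(depth_order)}
    return model.label_map


def classify_dives(
    dives: pd.DataFrame,
    k: int | None = None,
    k_range=K_RANGE_DEFAULT,
    n_init: int = N_INIT_DEFAULT,
    seed: int = 0,
) -> tuple[pd.DataFrame, ClusterModel]:
    """Full typing step: optional CH selection, k-means, label mapping.

    Adds ``dive_type`` to the dive table (cluster indices as strings when
    the selected k is not 3).
    """
    ch_scores: dict[int, float] = {}
    if k is None:
        k, ch_scores = select_k(dives, k_range=k_range, n_init=n_init, seed=seed)
    labeled, model = cluster_dives(dives, k=k, n_init=n_init, seed=seed)
    model.ch_scores = ch_scores
    label_map = assign_type_labels(model)
    labeled["dive_type"] = labeled["cluster"].map(label_map)
    return labeled, model
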