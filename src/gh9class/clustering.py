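"""Class-specific β centroids (β′) via seeded k-means with outlier removal.

The training β values form three one-dimensional clusters corresponding to
subclasses A, B and C.  k-means with k = 3 (best of many seeded restarts,
judged by between_SS/total_SS) yields one centroid per cluster; clusters
are mapped to classes by majority training label, since the centroid
ordering is an empirical outcome rather than a rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .profiles import CLASSES


class ClusterError(ValueError):
    pass


@dataclass
class ClusterConfig:
    k: int = 3
    n_init: int = 100
    seed: int = 0
    outlier_method: str = "manual"  # or "centroid_distance"
    outlier_sd: float = 2.5
    manual_exclude: tuple = ()

    def __post_init__(self) -> None:
        if self.k != 3:
            raise ClusterError("the A/B/C schema requires k = 3")
        if self.n_init < 1:
            raise ClusterError("n_init must be >= 1")
        if self.outlier_method not in ("manual", "centroid_distance"):
            raise ClusterError(f"bad outlier_method {self.outlier_method!r}")


@dataclass
class ClusterModel:
    """Fitted centroids β′ per class plus assignment bookkeeping."""

    centroids: Mapping[str, float]  # class -> beta'
    assignments: Mapping[str, str]  # seq_id -> class (via cluster mapping)
    ss_ratio: float
    excluded_uids: tuple = ()

    def centroid_of(self, label: str) -> float:
        return self.centroids[label]


def _fit_kmeans(x: np.ndarray, cfg: ClusterConfig) -> KMeans:
    if len(np.unique(x)) < cfg.k:
        raise ClusterError(f"need at least {cfg.k} distinct values, got {len(np.unique(x))}")
    km = KMeans(n_clusters=cfg.k, n_init=cfg.n_init, random_state=cfg.seed)
    km.fit(x.reshape(-1, 1))
    return km


def _ss_ratio(x: np.ndarray, inertia: float) -> float:
    total = float(np.sum((x - x.mean()) ** 2))
    if total == 0:
        return 0.0
    return float(1.0 - inertia / total)


def cluster_betas(values: Mapping[str, float], labels: Mapping[str, str],
                  cfg: Optional[ClusterConfig] = None) -> ClusterModel:
    """Fit k = 3 clusters on β values and map clusters to classes.

    The best of ``n_init`` seeded k-means++ restarts (by within-SS, hence
    by between_SS/total_SS) is kept.  Each cluster takes the majority
    training label of its members; a tie or two clusters claiming the
    same class is a mapping error, not silently resolved.
    """
    cfg = cfg or ClusterConfig()
    ids = sorted(values.keys())
    x = np.array([values[i] for i in ids], dtype=float)
    km = _fit_kmeans(x, cfg)
    cluster_of = dict(zip(ids, km.labels_))

    mapping = {}
    for c in range(cfg.k):
        members = [i for i in ids if cluster_of[i] == c]
        if not members:
            raise ClusterError("empty cluster")
        tally = Counter(labels[i] for i in members)
        top = tally.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            raise ClusterError(f"ambiguous majority label in cluster {c}: {dict(tally)}")
        mapping[c] = top[0][0]
    if len(set(mapping.values())) != cfg.k:
        raise ClusterError(f"two clusters map to the same class: {mapping}")

    centroids = {}
    for c, cls in mapping.items():
        members = [values[i] for i in ids if cluster_of[i] == c]
        centroids[cls] = float(np.mean(members))
    assignments = {i: mapping[cluster_of[i]] for i in ids}
    return ClusterModel(centroids, assignments, _ss_ratio(x, km.inertia_))


def exclude_outliers(values: Mapping[str, float], labels: Mapping[str, str],
                     cfg: Optional[ClusterConfig] = None) -> tuple:
    """Identify outliers to drop before the final fit.

    ``manual`` mode returns the configured accession list (the default,
    mirroring curated exclusion); ``centroid_distance`` flags points more
    than ``outlier_sd`` within-cluster standard deviations from their
    centroid under a preliminary fit.
    """
    cfg = cfg or ClusterConfig()
    if cfg.outlier_method == "manual":
        return tuple(u for u in cfg.manual_exclude if u in values)
    model = cluster_betas(values, labels, cfg)
    flagged = []
    for cls in set(model.assignments.values()):
        members = [i for i, c in model.assignments.items() if c == cls]
        xs = np.array([values[i] for i in members], dtype=float)
        sd = float(xs.std())
        if sd == 0:
            continue
        for i in members:
            if abs(values[i] - model.centroids[cls]) > cfg.outlier_sd * sd:
                flagged.append(i)
    return tuple(sorted(flagged))


def fit_with_exclusion(values: Mapping[str, float], labels: Mapping[str, str],
                       cfg: Optional[ClusterConfig] = None) -> ClusterModel:
    """Outlier pass followed by a refit on the retained points."""
    cfg = cfg or ClusterConfig()
    excluded = exclude_outliers(values, labels, cfg)
    kept = {i: v for i, v in values.items() if i not in excluded}
    model = cluster_betas(kept, labels, cfg)
    model.excluded_uids = tuple(excluded)
    return model
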