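"""Per-individual task FC construction, 2-D embedding and cluster analysis.

Each individual's task functional connectivity (FC) is the Pearson matrix of
all of their trial windows concatenated in time.  FCs are embedded with UMAP
(correlation metric on the vectorized upper triangles), classified in the
2-D embedding with an RBF support-vector machine, and summarized by the
Euclidean distance of every individual to each task's cluster center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .evaluation import fc_matrix
from .separation import TrialWindowSet

logger = logging.getLogger(__name__)


def individual_task_fc(win: TrialWindowSet) -> np.ndarray:
    """FC of one individual's concatenated trial windows (order-invariant)."""
    if win.n_trials < 2:
        raise ValidationError("need at least 2 trials to form an individual FC")
    pooled = np.concatenate([win.signal[i] for i in range(win.n_trials)], axis=1)
    return fc_matrix(pooled)


def embed_fcs(
    fcs: np.ndarray,
    n_neighbors: int = 100,
    min_dist: float = 0.1,
    n_components: int = 2,
    metric: str = "correlation",
    seed: int = 0,
) -> np.ndarray:
    """UMAP embedding of vectorized FC upper triangles (n_individuals x 2)."""
    fcs = np.asarray(fcs, dtype=float)
    if fcs.shape[0] < 10:
        raise ValidationError("need at least 10 FC matrices to embed")
    iu = np.triu_indices(fcs.shape[1], k=1)
    features = fcs[:, iu[0], iu[1]]
    if n_neighbors >= len(features):
        logger.warning("n_neighbors=%d clamped to %d (n-1)", n_neighbors, len(features) - 1)
        n_neighbors = len(features) - 1
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_components=n_components,
            metric=metric,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(features), dtype=float)


def classify_embedding(
    coords: np.ndarray,
    labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """RBF-kernel SVM on the embedding coordinates; held-out accuracy."""
    from sklearn.metrics import confusion_matrix
    from sklearn.model_selection import train_test_split
    from sklearn.svm import SVC

    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    x_tr, x_te, y_tr, y_te = train_test_split(
        coords, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    return float(np.mean(pred == y_te)), confusion_matrix(y_te, pred, labels=classes)


@dataclass
class ClusterDistances:
    """Per-instance distances to every task cluster center, plus summaries."""

    classes: list[str]
    centers: np.ndarray            # (n_classes, 2)
    distances: np.ndarray          # (n_instances, n_classes)
    pair_means: np.ndarray         # (n_classes, n_classes): mean dist of class i members to center j
    within_mean: float
    between_mean: float

    @property
    def between_within_ratio(self) -> float:
        return self.between_mean / self.within_mean


def cluster_distances(coords: np.ndarray, labels: np.ndarray) -> ClusterDistances:
    """Euclidean distances of each instance to every class's mean coordinate."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    centers = np.stack([coords[labels == c].mean(axis=0) for c in classes])
    distances = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    pair_means = np.stack([distances[labels == c].mean(axis=0) for c in classes])
    own = np.array([classes.index(l) for l in labels])
    within = distances[np.arange(len(labels)), own]
    mask = np.ones_like(distances, dtype=bool)
    mask[np.arange(len(labels)), own] = False
    return ClusterDistances(
        classes=classes,
        centers=centers,
        distances=distances,
        pair_means=pair_means,
        within_mean=float(within.mean()),
        between_mean=float(distances[mask].mean()),
    )
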