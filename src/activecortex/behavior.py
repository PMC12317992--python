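"""Brain-to-behavior mapping: RT correlation maps and predictive models.

Two approximations of the brain-to-behavior function are provided: direct
spatiotemporal correlation of trial windows with reaction time, and an
Elastic Net aggregating the whole window (signal and derivative features)
into a single RT prediction.  Per-trial task classification and
per-individual outcome prediction round out the behavioral battery.

The reported R-squared is the *squared Pearson correlation* between
predicted and measured RT on held-out trials (explained variance, not the
coefficient of determination).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import ElasticNet
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import ShuffleSplit, train_test_split
from sklearn.preprocessing import StandardScaler

from .errors import StatisticalValidityError, ValidationError
from .separation import TrialWindowSet

logger = logging.getLogger(__name__)


def spatiotemporal_rt_correlation(win: TrialWindowSet | np.ndarray, rt: np.ndarray) -> np.ndarray:
    """Pearson r with RT across trials at every (region, time) point."""
    signal = win.signal if isinstance(win, TrialWindowSet) else np.asarray(win, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if signal.shape[0] != len(rt):
        raise ValidationError("rt vector not aligned with trials")
    if len(rt) < 10:
        raise StatisticalValidityError("need at least 10 trials for the correlation map")
    rt_c = rt - rt.mean()
    centered = signal - signal.mean(axis=0)
    denom = np.sqrt((centered ** 2).sum(axis=0) * (rt_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.einsum("ijk,i->jk", centered, rt_c) / denom
    n_missing = int(np.isnan(corr).sum())
    if n_missing:
        logger.warning("%d zero-variance spatiotemporal point(s) recorded as missing", n_missing)
    return corr


def max_abs_correlation(corr: np.ndarray) -> float:
    return float(np.nanmax(np.abs(corr)))


def top_correlation_set(corr: np.ndarray, fraction: float = 0.9) -> list[tuple[int, int]]:
    """(region, time) points with |r| at or above ``fraction`` of the maximum.

    The set is conventionally defined on the unseparated map and reused to
    index separated maps, so framework comparisons look at fixed locations.
    """
    corr = np.asarray(corr, dtype=float)
    if np.all(np.isnan(corr)):
        raise ValidationError("correlation map is entirely missing")
    cutoff = fraction * np.nanmax(np.abs(corr))
    rois, times = np.where(np.abs(corr) >= cutoff)
    return list(zip(rois.tolist(), times.tolist()))


def _window_features(win: TrialWindowSet) -> np.ndarray:
    """Concatenated flattened signal and derivative windows, one row per trial."""
    n = win.n_trials
    return np.concatenate([win.signal.reshape(n, -1), win.derivative.reshape(n, -1)], axis=1)


def _cv_r2(features: np.ndarray, target: np.ndarray, model_factory, n_splits: int,
           test_fraction: float, seed: int) -> np.ndarray:
    """Repeated shuffle-split R^2 (squared Pearson), standardizing in-fold."""
    r2s = []
    splitter = ShuffleSplit(n_splits=n_splits, test_size=test_fraction, random_state=seed)
    for train_idx, test_idx in splitter.split(features):
        y_test = target[test_idx]
        if np.std(target[train_idx]) < 1e-12 or np.std(y_test) < 1e-12:
            logger.warning("degenerate fold (constant target) skipped")
            continue
        scaler = StandardScaler().fit(features[train_idx])
        model = model_factory()
        model.fit(scaler.transform(features[train_idx]), target[train_idx])
        pred = model.predict(scaler.transform(features[test_idx]))
        if np.std(pred) < 1e-12:
            r2s.append(0.0)
        else:
            r2s.append(float(np.corrcoef(pred, y_test)[0, 1] ** 2))
    return np.asarray(r2s)


def elastic_net_rt(
    win: TrialWindowSet,
    rt: np.ndarray,
    alpha: float = 1.0,
    l1_ratio: float = 0.95,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    min_trials: int = 50,
) -> np.ndarray:
    """Cross-validated R^2 of an Elastic Net predicting per-trial RT.

    Features are the concatenated flattened signal and derivative windows;
    the model is trained on 10 repeats of a seeded 80/20 shuffle split with
    features standardized inside each training fold.
    """
    rt = np.asarray(rt, dtype=float)
    if win.n_trials != len(rt):
        raise ValidationError("rt vector not aligned with windows")
    if win.n_trials < min_trials:
        raise StatisticalValidityError(f"need at least {min_trials} trials, got {win.n_trials}")
    factory = lambda: ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)
    return _cv_r2(_window_features(win), rt, factory, n_splits, test_fraction, seed)


def classify_trials(
    windows_by_task: dict[str, TrialWindowSet],
    n_trees: int = 200,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Random-forest classification of trials into task categories."""
    if len(windows_by_task) < 2:
        raise ValidationError("need at least two task categories")
    feats, labels = [], []
    for name, win in windows_by_task.items():
        if win.n_trials < 5:
            raise ValidationError(f"task {name!r} has fewer than 5 trials")
        feats.append(_window_features(win))
        labels.extend([name] * win.n_trials)
    x = np.concatenate(feats, axis=0)
    y = np.asarray(labels)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    classes = sorted(windows_by_task)
    return float(np.mean(pred == y_te)), confusion_matrix(y_te, pred, labels=classes)


def predict_individual_outcomes(
    fcs: np.ndarray,
    outcome: np.ndarray,
    alpha: float = 5.0,
    l1_ratio: float = 0.01,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Elastic Net mapping per-individual FCs to a scalar outcome.

    ``fcs`` is (n_individuals, n_roi, n_roi); features are the vectorized
    upper triangle of each matrix.  Returns cross-validated R^2 per fold.
    """
    fcs = np.asarray(fcs, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if fcs.shape[0] != len(outcome):
        raise ValidationError("one outcome per individual required")
    if fcs.shape[0] < 20:
        raise StatisticalValidityError("need at least 20 individuals")
    iu = np.triu_indices(fcs.shape[1], k=1)
    features = fcs[:, iu[0], iu[1]]
    factory = lambda: ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000)
    return _cv_r2(features, outcome, factory, n_splits, test_fraction, seed)
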