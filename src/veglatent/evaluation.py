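"""Bootstrap-resampled Random-Forests evaluation of compressed features.

Labelled feature vectors are extracted at ground-truth points; a
Random-Forests importance ranking supplies the classical top-k baseline; and
classification accuracy is quantified with bootstrap resampling (sample n
rows with replacement, split the sample 75/25, fit on the training part,
score on the test part) summarised by a percentile confidence interval whose
bounds are order statistics of the accuracy list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from veglatent.raster import Raster

logger = logging.getLogger(__name__)


@dataclass
class LabelledFeatures:
    """An (n_points, d) feature matrix with one class label per row."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X):
            raise ValueError("one label per row is required")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


@dataclass
class BootstrapReport:
    """Per-iteration accuracies and importances with a percentile CI."""

    accuracies: np.ndarray
    ci_low: float
    ci_high: float
    importances: np.ndarray  # (n_boot, d)
    class_recall: dict[str, float]
    config: dict
    n_redraws: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "mean_accuracy": self.mean_accuracy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "accuracies": self.accuracies.tolist(),
            "importance_mean": self.importances.mean(axis=0).tolist(),
            "class_recall": self.class_recall,
            "n_redraws": self.n_redraws,
        }


def percentile_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Percentile interval with order-statistic bounds.

    The lower bound is the largest order statistic at or below the
    ``(1-confidence)/2`` quantile ('lower' interpolation); the upper bound
    the smallest at or above the matching upper quantile ('higher').  Both
    therefore always belong to ``values``, and widening the confidence can
    only widen the interval.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    values = np.asarray(values, dtype=np.float64)
    alpha = (1.0 - confidence) / 2.0
    lo = float(np.quantile(values, alpha, method="lower"))
    hi = float(np.quantile(values, 1.0 - alpha, method="higher"))
    return lo, hi


def extract_at_points(raster: Raster, points: pd.DataFrame) -> LabelledFeatures:
    """Sample raster values at 0-based integer pixel coordinates.

    ``points`` needs columns ``class``, ``x`` (column) and ``y`` (row).
    Out-of-bounds points and rows with any invalid cell are dropped with a
    warning; duplicated points yield duplicated rows.
    """
    required = {"class", "x", "y"}
    if not required.issubset(points.columns):
        raise ValueError(f"points table must have columns {sorted(required)}")
    h, w = raster.shape
    xs = points["x"].to_numpy(dtype=np.int64)
    ys = points["y"].to_numpy(dtype=np.int64)
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    n_out = int(np.count_nonzero(~inside))
    if n_out:
        logger.warning("extract_at_points: %d out-of-bounds point(s) skipped", n_out)
    xs, ys = xs[inside], ys[inside]
    labels = points["class"].to_numpy()[inside]

    X = raster.data[:, ys, xs].T.astype(np.float64)  # (n, bands)
    ok = raster.valid[:, ys, xs].T.all(axis=1)
    n_invalid = int(np.count_nonzero(~ok))
    if n_invalid:
        logger.warning("extract_at_points: %d point(s) dropped for invalid cells", n_invalid)
    return LabelledFeatures(X=X[ok], y=labels[ok], feature_names=list(raster.band_names))


def rf_top_features(
    data: LabelledFeatures,
    k: int,
    n_estimators: int = 500,
    seed: int = 0,
) -> tuple[LabelledFeatures, np.ndarray]:
    """Select the top-k columns by Random-Forests impurity importance.

    A forest is fitted on all d features; columns are ranked by mean
    impurity decrease (ties broken by column order) and the k best are
    returned together with their indices.
    """
    d = data.n_features
    if k > d:
        raise ValueError(f"cannot select {k} features from {d}")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(data.X, data.y)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    sel = order[:k]
    logger.info("rf_top_features: selected columns %s", sel.tolist())
    return (
        LabelledFeatures(
            X=data.X[:, sel],
            y=data.y.copy(),
            feature_names=[data.feature_names[i] for i in sel],
        ),
        sel,
    )


def _iteration_indices(
    rng: np.random.Generator,
    n: int,
    train_fraction: float,
    replacement: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if replacement:
        sample = rng.integers(0, n, size=n)
    else:
        sample = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return sample[:n_train], sample[n_train:]


def bootstrap_evaluate(
    data: LabelledFeatures,
    n_boot: int = 1000,
    train_fraction: float = 0.75,
    confidence: float = 0.95,
    seed: int = 0,
    replacement: bool = True,
    n_estimators: int = 500,
    accuracies: np.ndarray | None = None,
) -> BootstrapReport:
    """Bootstrap-resampled Random-Forests accuracy with a percentile CI.

    Each iteration resamples n rows with replacement (or permutes, with
    ``replacement=False``), splits the sample by ``train_fraction``, fits a
    forest on the training part and scores overall accuracy on the test
    part.  Iterations whose train or test part holds fewer than two classes
    are redrawn (logged; a warning is emitted past 10% redraws).

    ``accuracies`` injects a precomputed accuracy list, bypassing the
    classifier — the CI arithmetic is then applied verbatim to it.
    """
    if accuracies is not None:
        accs = np.asarray(accuracies, dtype=np.float64)
        lo, hi = percentile_ci(accs, confidence)
        return BootstrapReport(
            accuracies=accs,
            ci_low=lo,
            ci_high=hi,
            importances=np.zeros((0, data.n_features if data else 0)),
            class_recall={},
            config={"confidence": confidence, "injected": True},
        )

    n = len(data.X)
    if n < 8:
        raise ValueError("need at least 8 rows")
    if len(data.classes) < 2:
        raise ValueError("need at least 2 classes")

    rng = np.random.default_rng(seed)
    accs = np.empty(n_boot)
    importances = np.empty((n_boot, data.n_features))
    classes = data.classes
    recall_sum = {c: 0.0 for c in classes}
    recall_n = {c: 0 for c in classes}
    n_redraws = 0

    for it in range(n_boot):
        while True:
            tr, te = _iteration_indices(rng, n, train_fraction, replacement)
            if len(np.unique(data.y[tr])) >= 2 and len(np.unique(data.y[te])) >= 2:
                break
            n_redraws += 1
            logger.info("bootstrap iteration %d redrawn (degenerate split)", it)
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed + it, n_jobs=1
        )
        rf.fit(data.X[tr], data.y[tr])
        pred = rf.predict(data.X[te])
        truth = data.y[te]
        accs[it] = float(np.mean(pred == truth))
        imp = rf.feature_importances_
        total = imp.sum()
        importances[it] = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
        for c in np.unique(truth):
            mask = truth == c
            recall_sum[c] += float(np.mean(pred[mask] == c))
            recall_n[c] += 1

    if n_redraws > 0.1 * n_boot:
        logger.warning("bootstrap: %d redraws exceed 10%% of %d iterations", n_redraws, n_boot)

    lo, hi = percentile_ci(accs, confidence)
    class_recall = {
        str(c): (recall_sum[c] / recall_n[c] if recall_n[c] else float("nan")) for c in classes
    }
    return BootstrapReport(
        accuracies=accs,
        ci_low=lo,
        ci_high=hi,
        importances=importances,
        class_recall=class_recall,
        config={
            "n_boot": n_boot,
            "train_fraction": train_fraction,
            "confidence": confidence,
            "seed": seed,
            "replacement": replacement,
            "n_estimators": n_estimators,
        },
        n_redraws=n_redraws,
    )


def compare_methods(
    latents_by_method: dict[str, dict[int, LabelledFeatures]],
    raw: LabelledFeatures,
    ks: tuple[int, ...] = (3, 5, 10),
    n_boot: int = 1000,
    train_fraction: float = 0.75,
    confidence: float = 0.95,
    seed: int = 0,
    n_estimators: int = 500,
) -> pd.DataFrame:
    """Bootstrap CIs for each compression method at each latent size.

    ``latents_by_method`` maps a method name ("cae", "ae", ...) to
    ``{k: LabelledFeatures}``; an "rf" baseline of importance-selected raw
    columns is added automatically.  All feature sets must be row-aligned to
    the same points.  Returns a tidy frame (method, k, mean, ci_low, ci_high).
    """
    methods = dict(latents_by_method)
    methods["rf"] = {k: rf_top_features(raw, k, n_estimators=n_estimators, seed=seed)[0] for k in ks}

    rows = []
    for method, by_k in methods.items():
        for k in ks:
            feats = by_k[k]
            if len(feats.X) != len(raw.X) or not np.array_equal(feats.y, raw.y):
                raise ValueError(f"feature set {method}/k={k} is not row-aligned with raw features")
            rep = bootstrap_evaluate(
                feats,
                n_boot=n_boot,
                train_fraction=train_fraction,
                confidence=confidence,
                seed=seed,
                n_estimators=n_estimators,
            )
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "mean_accuracy": rep.mean_accuracy,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                }
            )
    return pd.DataFrame(rows)
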