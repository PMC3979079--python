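"""Supervised pathology discrimination of spectral-parameter vectors.

The classifier is deliberately simple and transparent: feature vectors
(A, b, HbT, %O2, %H2O) are whitened so Euclidean distance weights every
parameter equally, gross outliers are trimmed from the training set by
per-class interquartile fences (a fixed overall budget, 5% by default), and
each query is assigned the majority diagnosis of its k nearest training
neighbours found with a k-d tree. Performance is estimated by a
class-stratified three-fold cross-validation with equal per-class counts per
fold, averaging metrics over the three train/validation rotations.
Sensitivity and specificity carry continuity-corrected score (Wilson-Yates)
confidence intervals, and an ROC-style sweep over k exposes the
sensitivity/specificity trade-off for the benign-vs-malignant task.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .synthetic import BENIGN_CLASSES, MALIGNANT_CLASSES

__all__ = [
    "LabeledFeatureSet",
    "WhiteningTransform",
    "DiagnosticReport",
    "fit_whitening",
    "remove_outliers",
    "knn_predict",
    "crossvalidate",
    "compute_metrics",
    "yates_interval",
    "roc_over_k",
    "to_binary_task",
]

log = logging.getLogger(__name__)


@dataclass
class LabeledFeatureSet:
    """Feature matrix with pathology labels and source-ROI group ids."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) str
    group_ids: np.ndarray | None = None
    feature_names: tuple = ("A", "b", "HbT", "O2_percent", "water_percent")

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be (n, d) with one label per row")
        if np.isnan(self.features).any():
            raise ValueError("NaN features are not allowed")
        if self.group_ids is None:
            self.group_ids = np.zeros(len(self.labels), dtype=int)
        self.group_ids = np.asarray(self.group_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_names=None) -> "LabeledFeatureSet":
        names = tuple(feature_names or ("A", "b", "HbT", "O2_percent", "water_percent"))
        missing = [c for c in (*names, "label") if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        gid = df["group_id"].to_numpy() if "group_id" in df.columns else None
        return cls(df[list(names)].to_numpy(), df["label"].to_numpy(), gid, names)

    def subset(self, idx) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            self.features[idx], self.labels[idx], self.group_ids[idx], self.feature_names
        )

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class WhiteningTransform:
    """ZCA whitening: x -> W (x - center), with W the inverse matrix square root of cov."""

    center: np.ndarray
    matrix: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.center) @ self.matrix.T


def fit_whitening(train: LabeledFeatureSet, ridge: bool = True) -> WhiteningTransform:
    """Fit a symmetric (ZCA) whitening transform on the training features.

    Near-singular covariances are ridge-regularized (eps = 1e-10 * mean
    eigenvalue) and logged; with ``ridge=False`` a singular covariance raises.
    """
    x = train.features
    if len(x) < 6:
        raise ValueError("need at least 6 samples to fit a whitening transform")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    w, v = np.linalg.eigh(cov)
    tiny = w < 1e-12 * max(w.max(), 1e-300)
    if tiny.any():
        if not ridge:
            raise ValueError("singular sample covariance")
        eps = 1e-10 * max(w.mean(), 1e-30)
        log.warning("whitening: ridge-regularizing %d tiny eigenvalues", int(tiny.sum()))
        w = w + eps
    matrix = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
    return WhiteningTransform(center, matrix)


def remove_outliers(
    train: LabeledFeatureSet, target_fraction: float = 0.05
) -> LabeledFeatureSet:
    """Trim training outliers with per-class, per-feature Tukey fences.

    A sample is an outlier when any feature falls outside
    [Q1 - c*IQR, Q3 + c*IQR] of its class. The fence multiplier c is found by
    bisection so the overall removed fraction is the largest value not
    exceeding ``target_fraction``. Only ever applied to training folds.
    """
    if not 0.0 <= target_fraction <= 0.2:
        raise ValueError("target_fraction must be in [0, 0.2]")
    if target_fraction == 0.0 or len(train.labels) == 0:
        return train

    x = train.features
    labels = train.labels
    q1 = {}
    q3 = {}
    for c in np.unique(labels):
        sel = labels == c
        q1[c] = np.percentile(x[sel], 25, axis=0)
        q3[c] = np.percentile(x[sel], 75, axis=0)

    def removed_mask(c_mult: float) -> np.ndarray:
        out = np.zeros(len(labels), dtype=bool)
        for c in q1:
            sel = labels == c
            iqr = q3[c] - q1[c]
            lo = q1[c] - c_mult * iqr
            hi = q3[c] + c_mult * iqr
            out[sel] = np.any((x[sel] < lo) | (x[sel] > hi), axis=1)
        return out

    lo_c, hi_c = 0.0, 100.0
    best = np.zeros(len(labels), dtype=bool)  # c -> inf removes nothing
    for _ in range(60):
        mid = 0.5 * (lo_c + hi_c)
        rm = removed_mask(mid)
        if rm.mean() <= target_fraction:
            best = rm
            hi_c = mid
        else:
            lo_c = mid
    for c in np.unique(labels):
        if np.all(best[labels == c]):
            raise ValueError(f"outlier removal would empty class {c!r}")
    if best.any():
        log.info("outlier removal: dropped %d/%d training samples", int(best.sum()), len(best))
    return train.subset(~best)


def knn_predict(query: np.ndarray, train: LabeledFeatureSet, k: int) -> np.ndarray:
    """k-NN majority vote with a k-d tree; deterministic tie-breaking.

    Vote ties break to the class of the nearest neighbour among the tied
    classes. Assumes whitening has already been applied to both query and
    training features.
    """
    if len(train.labels) == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= len(train.labels):
        raise ValueError(f"k must be in [1, {len(train.labels)}]")
    q = np.atleast_2d(np.asarray(query, float))
    tree = cKDTree(train.features)
    dist, idx = tree.query(q, k=k)
    idx = idx.reshape(len(q), k)
    dist = dist.reshape(len(q), k)
    # sort neighbours by distance then index for full determinism
    order = np.lexsort((idx, dist), axis=1)
    idx = np.take_along_axis(idx, order, axis=1)
    neigh_labels = train.labels[idx]  # (nq, k)

    classes = np.unique(train.labels)
    counts = np.stack([(neigh_labels == c).sum(axis=1) for c in classes], axis=1)
    top = counts.max(axis=1)
    out = np.empty(len(q), dtype=train.labels.dtype)
    for i in range(len(q)):
        tied = set(classes[counts[i] == top[i]])
        if len(tied) == 1:
            out[i] = next(iter(tied))
        else:
            for lab in neigh_labels[i]:  # nearest first
                if lab in tied:
                    out[i] = lab
                    break
    return out if np.asarray(query).ndim > 1 else out[0]


def compute_metrics(confusion: np.ndarray, class_names) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, PPV, NPV per class, plus accuracy.

    Rows of ``confusion`` are true classes, columns predicted. Undefined
    ratios (zero denominators) are reported as NaN with a flag column.
    """
    m = np.asarray(confusion, dtype=float)
    if np.any(m < 0):
        raise ValueError("confusion counts must be non-negative")
    total = m.sum()
    rows = []
    for i, name in enumerate(class_names):
        tp = m[i, i]
        fn = m[i].sum() - tp
        fp = m[:, i].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return num / den if den > 0 else np.nan

        rows.append(
            {
                "class": name,
                "sensitivity": ratio(tp, tp + fn),
                "specificity": ratio(tn, tn + fp),
                "ppv": ratio(tp, tp + fp),
                "npv": ratio(tn, tn + fn),
                "undefined": (tp + fn == 0) or (tn + fp == 0) or (tp + fp == 0) or (tn + fn == 0),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["accuracy"] = float(np.trace(m) / total) if total > 0 else np.nan
    return df


def yates_interval(successes: int, n: int, alpha: float = 0.05):
    """Continuity-corrected score (Wilson-Yates) interval for a proportion.

    Endpoints are the exact roots of the continuity-corrected chi-square
    acceptance boundary |x - n p| - 1/2 = z sqrt(n p (1-p)), clipped to
    [0, 1]; lower = 0 when x = 0 and upper = 1 when x = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z2 = norm.ppf(1.0 - alpha / 2.0) ** 2

    def root(x_adj: float, upper: bool) -> float:
        # (x_adj - n p)^2 = z^2 n p (1 - p)
        a = n * (n + z2)
        b = -(2.0 * n * x_adj + z2 * n)
        c = x_adj**2
        disc = max(b * b - 4.0 * a * c, 0.0)
        if upper:
            return (-b + np.sqrt(disc)) / (2.0 * a)
        return (-b - np.sqrt(disc)) / (2.0 * a)

    lower = 0.0 if successes == 0 else max(0.0, root(successes - 0.5, upper=False))
    upper = 1.0 if successes == n else min(1.0, root(successes + 0.5, upper=True))
    return lower, upper


@dataclass
class DiagnosticReport:
    """Cross-validated diagnostic performance summary."""

    confusion: np.ndarray  # pooled counts over the 3 rotations (true x predicted)
    class_names: tuple
    metrics: pd.DataFrame  # per-class metrics averaged over rotations
    accuracy: float
    sensitivity_ci: dict  # class -> (lo, hi), Wilson-Yates on pooled counts
    specificity_ci: dict
    k: int
    fold_sizes: dict  # class -> per-fold count
    dropped: int  # samples dropped to equalize fold counts

    @property
    def confusion_percent(self) -> np.ndarray:
        """Confusion as percentage of all diagnosed samples (sums to 100)."""
        total = self.confusion.sum()
        return 100.0 * self.confusion / total if total else self.confusion * 0.0

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion_counts": self.confusion.tolist(),
            "confusion_percent": np.round(self.confusion_percent, 4).tolist(),
            "accuracy": self.accuracy,
            "metrics": self.metrics.to_dict(orient="records"),
            "sensitivity_ci": {c: list(v) for c, v in self.sensitivity_ci.items()},
            "specificity_ci": {c: list(v) for c, v in self.specificity_ci.items()},
            "k": self.k,
            "fold_sizes": self.fold_sizes,
            "dropped_for_stratification": self.dropped,
        }


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Equal per-class counts per fold; per-class remainders mod n_folds dropped."""
    fold_of = np.full(len(labels), -1, dtype=int)
    fold_sizes = {}
    dropped = 0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        per = len(idx) // n_folds
        if per < 1:
            raise ValueError(f"class {c!r} has fewer than {n_folds} samples")
        dropped += len(idx) - per * n_folds
        fold_sizes[str(c)] = per
        for f in range(n_folds):
            fold_of[idx[f * per : (f + 1) * per]] = f
    if dropped:
        log.info("stratification: dropped %d remainder samples", dropped)
    return fold_of, fold_sizes, dropped


def crossvalidate(
    data: LabeledFeatureSet,
    k: int = 9,
    seed: int = 0,
    outlier_fraction: float = 0.05,
    global_whiten: bool = False,
    n_folds: int = 3,
) -> DiagnosticReport:
    """Stratified n-fold cross-validation of the whiten + trim + k-NN classifier.

    For each rotation, whitening is fitted on the training folds only
    (leakage-free default; ``global_whiten=True`` fits it once on all data),
    outliers are trimmed from the training folds, and the held-out fold is
    classified. The confusion matrix pools the three rotations; per-class
    metrics are computed per rotation and averaged.
    """
    rng = np.random.default_rng(seed)
    fold_of, fold_sizes, dropped = _stratified_folds(data.labels, n_folds, rng)
    class_names = tuple(np.unique(data.labels))
    n_cls = len(class_names)
    pooled = np.zeros((n_cls, n_cls), dtype=int)
    per_rotation_metrics = []
    per_rotation_acc = []

    global_wt = fit_whitening(data) if global_whiten else None

    for fold in range(n_folds):
        train_idx = np.nonzero((fold_of >= 0) & (fold_of != fold))[0]
        val_idx = np.nonzero(fold_of == fold)[0]
        train = data.subset(train_idx)
        wt = global_wt if global_whiten else fit_whitening(train)
        train_w = LabeledFeatureSet(
            wt.apply(train.features), train.labels, train.group_ids, train.feature_names
        )
        train_w = remove_outliers(train_w, outlier_fraction)
        pred = knn_predict(wt.apply(data.features[val_idx]), train_w, k)
        true = data.labels[val_idx]
        conf = np.zeros((n_cls, n_cls), dtype=int)
        for i, ci in enumerate(class_names):
            for j, cj in enumerate(class_names):
                conf[i, j] = int(np.sum((true == ci) & (pred == cj)))
        pooled += conf
        mdf = compute_metrics(conf, class_names)
        per_rotation_metrics.append(mdf)
        per_rotation_acc.append(mdf.attrs["accuracy"])

    avg = per_rotation_metrics[0].copy()
    for col in ("sensitivity", "specificity", "ppv", "npv"):
        avg[col] = np.nanmean(
            np.stack([m[col].to_numpy(dtype=float) for m in per_rotation_metrics]), axis=0
        )
    avg["undefined"] = np.any(
        [m["undefined"].to_numpy() for m in per_rotation_metrics], axis=0
    )
    accuracy = float(np.mean(per_rotation_acc))

    sens_ci = {}
    spec_ci = {}
    total = pooled.sum()
    for i, c in enumerate(class_names):
        tp = int(pooled[i, i])
        pos = int(pooled[i].sum())
        tn = int(total - pooled[i].sum() - pooled[:, i].sum() + pooled[i, i])
        neg = int(total - pos)
        sens_ci[c] = yates_interval(tp, pos) if pos else (np.nan, np.nan)
        spec_ci[c] = yates_interval(tn, neg) if neg else (np.nan, np.nan)

    return DiagnosticReport(
        pooled, class_names, avg, accuracy, sens_ci, spec_ci, k, fold_sizes, dropped
    )


def to_binary_task(data: LabeledFeatureSet) -> LabeledFeatureSet:
    """Collapse pathology subtypes into the benign-vs-malignant task."""
    known = BENIGN_CLASSES | MALIGNANT_CLASSES
    unknown = set(np.unique(data.labels)) - known
    if unknown:
        raise ValueError(f"labels outside the pathology class set: {sorted(unknown)}")
    binary = np.where(np.isin(data.labels, sorted(MALIGNANT_CLASSES)), "malignant", "benign")
    return LabeledFeatureSet(data.features, binary, data.group_ids, data.feature_names)


def roc_over_k(
    data: LabeledFeatureSet,
    k_values=None,
    seed: int = 0,
    outlier_fraction: float = 0.05,
) -> pd.DataFrame:
    """Cross-validated (sensitivity, specificity) per k for benign vs malignant.

    Malignant is the positive class. The returned frame carries the k
    maximizing Youden's index (sens + spec - 1) in ``attrs['optimal_k']``,
    ties broken toward smaller k. Refuses single-class data.
    """
    k_values = tuple(k_values) if k_values is not None else tuple(range(1, 32, 2))
    if any(k < 1 or k % 2 == 0 for k in k_values):
        raise ValueError("k values must be odd positive integers")
    binary = to_binary_task(data) if set(np.unique(data.labels)) != {"benign", "malignant"} else data
    if len(np.unique(binary.labels)) < 2:
        raise ValueError("ROC analysis needs both a positive and a negative class")

    rows = []
    for k in k_values:
        rep = crossvalidate(binary, k=k, seed=seed, outlier_fraction=outlier_fraction)
        i_pos = rep.class_names.index("malignant")
        sens = float(rep.metrics.loc[rep.metrics["class"] == "malignant", "sensitivity"].iloc[0])
        spec = float(rep.metrics.loc[rep.metrics["class"] == "malignant", "specificity"].iloc[0])
        rows.append({"k": k, "sensitivity": sens, "specificity": spec, "youden": sens + spec - 1.0})
    df = pd.DataFrame(rows)
    best = df.loc[df["youden"].idxmax()]  # idxmax returns the first max -> smaller k
    df.attrs["optimal_k"] = int(best["k"])
    return df
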