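"""Diagnostic separability ranking of spectral parameters and IHC correlates.

Class separability is scored by the Gaussian Bhattacharyya distance between
two classes i, j summarized by sample means and covariances over a feature
subset,

    J_ij = 1/8 (mu_i - mu_j)^T [(S_i + S_j)/2]^-1 (mu_i - mu_j)
         + 1/2 ln( det((S_i + S_j)/2) / sqrt(det S_i det S_j) )

generalized across all classes by prior weighting J = sum_i sum_j P_i P_j
J_ij, with P_i the fraction of training samples in class i. Sequential
floating forward selection (SFFS) greedily adds the feature maximizing J and
conditionally removes features whose exclusion improves on the best subset
previously recorded at that size, ranking the five spectral parameters by
their contribution to tissue-type discrimination. Pearson correlation
against region-level immunohistochemistry links the optical parameters to
tissue composition and vascularity.

By default ranking operates on region-averaged features (one vector per
ROI); a pixelwise mode is a caller choice (pass pixel-level rows instead).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .classify import LabeledFeatureSet

__all__ = [
    "ClassSummary",
    "FeatureRanking",
    "bhattacharyya_pair",
    "generalized_separability",
    "sffs_rank",
    "pearson_correlates",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassSummary:
    """Sample mean and covariance of one class over a feature subset."""

    mean: np.ndarray
    cov: np.ndarray


def _ridge(cov: np.ndarray) -> np.ndarray:
    """Ridge near-singular covariances: eps = 1e-8 tr(S)/d, logged."""
    d = cov.shape[0]
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 1e-12 * max(abs(w).max(), 1e-300):
        eps = 1e-8 * max(np.trace(cov) / d, 1e-30)
        log.info("ridging near-singular covariance (eps=%.3g)", eps)
        return cov + eps * np.eye(d)
    return cov


def bhattacharyya_pair(stats_i: ClassSummary, stats_j: ClassSummary) -> float:
    """Gaussian Bhattacharyya distance between two class summaries."""
    mu_i = np.atleast_1d(np.asarray(stats_i.mean, float))
    mu_j = np.atleast_1d(np.asarray(stats_j.mean, float))
    cov_i = np.atleast_2d(np.asarray(stats_i.cov, float))
    cov_j = np.atleast_2d(np.asarray(stats_j.cov, float))
    cov_i = _ridge(cov_i)
    cov_j = _ridge(cov_j)
    pooled = 0.5 * (cov_i + cov_j)
    diff = mu_i - mu_j
    sol = np.linalg.solve(pooled, diff)
    term_mean = 0.125 * float(diff @ sol)
    sign_p, logdet_p = np.linalg.slogdet(pooled)
    sign_i, logdet_i = np.linalg.slogdet(cov_i)
    sign_j, logdet_j = np.linalg.slogdet(cov_j)
    if sign_p <= 0 or sign_i <= 0 or sign_j <= 0:
        raise ValueError("covariances must be positive definite")
    term_cov = 0.5 * (logdet_p - 0.5 * (logdet_i + logdet_j))
    return term_mean + term_cov


def _class_summaries(data: LabeledFeatureSet, cols: tuple) -> dict:
    out = {}
    for c in data.classes:
        x = data.features[data.labels == c][:, list(cols)]
        out[c] = ClassSummary(x.mean(axis=0), np.atleast_2d(np.cov(x, rowvar=False)))
    return out


def generalized_separability(data: LabeledFeatureSet, subset=None) -> float:
    """Prior-weighted separability J = sum_ij P_i P_j J_ij over a feature subset."""
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("separability needs at least two classes")
    cols = tuple(subset) if subset is not None else tuple(range(data.features.shape[1]))
    if len(cols) == 0:
        return 0.0
    summaries = _class_summaries(data, cols)
    priors = {c: np.mean(data.labels == c) for c in classes}
    j = 0.0
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            ca, cb = classes[a], classes[b]
            j += 2.0 * priors[ca] * priors[cb] * bhattacharyya_pair(summaries[ca], summaries[cb])
    return float(j)


@dataclass
class FeatureRanking:
    """Ordered features with the J trace of the best nested subsets."""

    order: tuple  # feature names, most discriminative first
    j_trace: tuple  # J of the ranked prefix of each size
    history: tuple  # (action, feature, J) steps of the SFFS search


def sffs_rank(data: LabeledFeatureSet) -> FeatureRanking:
    """Rank features by sequential floating forward selection on J.

    Classical SFFS: repeatedly add the feature maximizing J, then
    conditionally exclude any already-selected feature whose removal beats
    the best recorded subset of the smaller size. The final ranking is the
    order in which features enter the best nested chain; ties break
    lexicographically by feature name. Zero-variance features are excluded
    with a warning.
    """
    names = list(data.feature_names)
    d = data.features.shape[1]
    variances = data.features.var(axis=0)
    active = [i for i in range(d) if variances[i] > 0]
    for i in range(d):
        if variances[i] == 0:
            warnings.warn(f"feature {names[i]!r} is constant; excluded from ranking")
    if len(active) < 2:
        raise ValueError("need at least 2 non-constant features")
    if len(data.classes) < 2:
        raise ValueError("need at least 2 classes")

    def score(cols) -> float:
        return generalized_separability(data, tuple(sorted(cols)))

    # tie-break: larger J first, then lexicographic feature name
    def better(cand_j, cand_name, best_j, best_name):
        if cand_j > best_j + 1e-15:
            return True
        if abs(cand_j - best_j) <= 1e-15 and (best_name is None or cand_name < best_name):
            return True
        return False

    best_at_size: dict[int, tuple[float, frozenset]] = {0: (0.0, frozenset())}
    current: set[int] = set()
    history = []
    while len(current) < len(active):
        # forward: add the best feature
        best_j, best_f, best_name = -np.inf, None, None
        for f in active:
            if f in current:
                continue
            jv = score(current | {f})
            if better(jv, names[f], best_j, best_name):
                best_j, best_f, best_name = jv, f, names[f]
        current.add(best_f)
        history.append(("add", names[best_f], best_j))
        k = len(current)
        if k not in best_at_size or best_j > best_at_size[k][0]:
            best_at_size[k] = (best_j, frozenset(current))
        # backward: conditional exclusion
        while len(current) > 2:
            best_j_rm, best_rm, best_rm_name = -np.inf, None, None
            for f in current:
                jv = score(current - {f})
                if better(jv, names[f], best_j_rm, best_rm_name):
                    best_j_rm, best_rm, best_rm_name = jv, f, names[f]
            size = len(current) - 1
            if best_j_rm > best_at_size.get(size, (-np.inf,))[0] + 1e-15:
                current.remove(best_rm)
                history.append(("remove", names[best_rm], best_j_rm))
                best_at_size[size] = (best_j_rm, frozenset(current))
            else:
                break

    # ranking = order of first appearance along the best nested chain
    order: list[str] = []
    ranked: set[int] = set()
    j_trace = []
    for size in range(1, len(active) + 1):
        jv, subset = best_at_size.get(size, (None, None))
        if subset is None:
            subset = frozenset(ranked)  # degenerate; should not happen
        new = sorted(subset - ranked, key=lambda f: names[f])
        if not new:
            # best subset at this size not a superset; extend by best marginal gain
            rest = sorted(set(active) - ranked, key=lambda f: (-score(ranked | {f}), names[f]))
            new = rest[:1]
        for f in new[: size - len(ranked)]:
            ranked.add(f)
            order.append(names[f])
        j_trace.append(score(frozenset(ranked)))
    return FeatureRanking(tuple(order), tuple(j_trace), tuple(history))


SPECTRAL_COLUMNS = ("A", "b", "HbT", "O2_percent", "water_percent")
IHC_MEASURES = (
    "percent_epithelium",
    "percent_stroma",
    "percent_fat",
    "mvd_cd31",
    "mvd_cd105",
    "mva_cd31",
    "mva_cd105",
)


def pearson_correlates(region_means: pd.DataFrame, ihc: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between ROI-mean spectral parameters and IHC measures.

    Rows are paired by ``roi_id``. Returns a tidy frame (spectral, ihc, r, n);
    zero-variance columns yield NaN with ``undefined=True``.
    """
    merged = region_means.merge(ihc, on="roi_id", suffixes=("", "_ihc"))
    if len(merged) < 3:
        raise ValueError("need at least 3 paired ROIs")
    rows = []
    for s in SPECTRAL_COLUMNS:
        for m in IHC_MEASURES:
            x = merged[s].to_numpy(float)
            y = merged[m].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"spectral": s, "ihc": m, "r": np.nan, "n": len(x), "undefined": True})
            else:
                r, _ = pearsonr(x, y)
                rows.append({"spectral": s, "ihc": m, "r": float(r), "n": len(x), "undefined": False})
    return pd.DataFrame(rows)
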