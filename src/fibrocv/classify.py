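"""Binary IC/NIC clustering of heart-failure subjects and its scoring.

Subjects are clustered into two groups by restarted k-means on one or more
fibrosis features (typically the tile heterogeneity sigma_intra).  The
cluster whose centroid is lower (summed over features) is labeled NIC and
the higher one IC, reflecting that ischemic cardiomyopathy carries the
larger and more heterogeneous fibrotic burden.  For a single feature the
midpoint of the two centroids is the scalar discrimination threshold.
Classification quality is scored with IC as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClusteringResult",
    "ClassificationMetrics",
    "kmeans_binary",
    "score_classification",
    "feature_comparison",
]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # array of "IC"/"NIC" strings, one per subject
    centroids: np.ndarray  # (2, n_features); row 0 = NIC (lower centroid)
    inertia: float
    threshold: float | None  # centroid midpoint, 1D features only
    degenerate: bool = False


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix summary with IC as the positive class.

    Accuracy, sensitivity and specificity are percentages; the predictive
    values are proportions.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fn: int
    tn: int
    fp: int


def _lloyd(x: np.ndarray, init_idx, squared: bool):
    """One Lloyd run from two seed points; returns (centroids, assign, inertia)."""
    c = x[np.asarray(init_idx)].astype(float)
    for _ in range(300):
        d = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d, axis=1)
        new_c = c.copy()
        for k in range(2):
            if np.any(assign == k):
                new_c[k] = x[assign == k].mean(axis=0)
            else:  # empty cluster: reseed at the point farthest from the other
                new_c[k] = x[np.argmax(d[:, 1 - k])]
        if np.allclose(new_c, c):
            c = new_c
            break
        c = new_c
    d = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d, axis=1)
    dist = d[np.arange(len(x)), assign]
    inertia = float(dist.sum()) if squared else float(np.sqrt(dist).sum())
    return c, assign, inertia


def kmeans_binary(
    features,
    restarts: int = 50,
    seed: int | None = 0,
    squared: bool = True,
) -> ClusteringResult:
    """Best-of-``restarts`` binary k-means with lower-centroid -> NIC labeling.

    Each restart initializes Lloyd's algorithm from a uniformly drawn pair
    of distinct subjects; the run with the lowest sum of (squared by
    default; plain Euclidean with ``squared=False``) point-to-centroid
    distances wins, ties broken by first occurrence.  Deterministic for a
    fixed seed.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to cluster")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")

    if np.allclose(x, x[0]):
        # all points identical: degenerate clustering
        c = np.vstack([x[0], x[0]])
        labels = np.array(["NIC"] * n)
        thr = float(x[0, 0]) if x.shape[1] == 1 else None
        return ClusteringResult(labels, c, 0.0, thr, degenerate=True)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        while True:
            i, j = rng.integers(0, n, size=2)
            if not np.array_equal(x[i], x[j]):
                break
        c, assign, inertia = _lloyd(x, (i, j), squared)
        if best is None or inertia < best[2] - 1e-12 * max(1.0, abs(best[2])):
            best = (c, assign, inertia)
    c, assign, inertia = best
    order = np.argsort(c.sum(axis=1))  # lower centroid first -> NIC
    c = c[order]
    remap = np.empty(2, dtype=int)
    remap[order] = np.arange(2)
    labels = np.where(remap[assign] == 0, "NIC", "IC")
    threshold = float(c.mean()) if x.shape[1] == 1 else None
    return ClusteringResult(labels, c, inertia, threshold)


def score_classification(predicted, truth, positive: str = "IC") -> ClassificationMetrics:
    """Confusion-matrix metrics for predicted vs true binary labels."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("labels must be non-empty and of equal length")
    p = pred == positive
    t = true == positive
    tp = int(np.sum(p & t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    total = tp + fn + tn + fp

    def _safe(num, den):
        return float(num) / den if den else float("nan")

    return ClassificationMetrics(
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=100.0 * _safe(tp, tp + fn),
        specificity=100.0 * _safe(tn, tn + fp),
        ppv=_safe(tp, tp + fp),
        npv=_safe(tn, tn + fn),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


DEFAULT_FEATURE_SETS = (
    ("sigma_intra",),
    ("v_nm",),
    ("largest_patch_area_um2",),
    ("sigma_intra", "v_nm"),
    ("sigma_intra", "v_nm", "largest_patch_area_um2"),
)


def feature_comparison(
    table: pd.DataFrame,
    truth_column: str = "group",
    feature_sets=DEFAULT_FEATURE_SETS,
    restarts: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score k-means clustering for several feature sets, one row per set.

    ``table`` holds one row per HF subject with feature columns and the
    true etiology in ``truth_column``.  Constant features are flagged and
    skipped.  Multi-feature sets are clustered on raw (unstandardized)
    values, so features with large numeric ranges dominate the distance.
    """
    truth = table[truth_column].to_numpy()
    rows = []
    for fs in feature_sets:
        x = table.loc[:, list(fs)].to_numpy(dtype=float)
        name = " + ".join(fs)
        if np.allclose(x, x[0]):
            rows.append({"features": name, "skipped": "constant feature"})
            continue
        res = kmeans_binary(x, restarts=restarts, seed=seed)
        m = score_classification(res.labels, truth)
        rows.append(
            {
                "features": name,
                "accuracy_pct": m.accuracy,
                "sensitivity_pct": m.sensitivity,
                "specificity_pct": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "threshold": res.threshold,
            }
        )
    return pd.DataFrame(rows)
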