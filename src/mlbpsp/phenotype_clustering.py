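"""Step two: PCA compression, k-means, elbow selection, label ordering.

The participant-level random-effect matrix is z-scored and compressed to the
smallest number of principal components reaching a cumulative explained
variance threshold (default 0.85).  k-means (50 restarts) is run on the
component scores for k = 1..k_max; the cluster count is chosen at the point
of maximum perpendicular distance from the within-cluster sum-of-squares
curve to the chord joining its endpoints.  Cluster labels are then reordered
by baseline severity so that label 1 is always the healthiest group, and
agreement between two labelings is quantified by optimal label matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from mlbpsp.synthetic_cohort import CohortPanel


@dataclass
class PCACompression:
    """Standardization constants and retained principal components."""

    means: pd.Series
    scales: pd.Series
    components: np.ndarray  # (n_components, n_kept_columns) loading vectors
    explained_variance_ratio: np.ndarray
    n_retained: int
    cumulative_variance: float
    dropped_columns: list[str]


@dataclass
class ClusterSolution:
    """A severity-ordered k-means solution with its model-selection curve."""

    k: int
    labels: pd.Series  # index = pid, values in 1..k, 1 = lowest severity
    centers: np.ndarray
    wss_curve: pd.Series  # index = k, values = within-cluster sum of squares
    selection: str  # "elbow" | "forced"
    seed: int
    severity: pd.Series | None = None  # per original cluster


def standardize_and_reduce(
    matrix: pd.DataFrame, variance_threshold: float = 0.85
) -> tuple[PCACompression, pd.DataFrame]:
    """Z-score columns, run PCA, retain the smallest m reaching the threshold.

    Zero-variance columns are dropped with a warning.  Returns the
    compression summary and the participant scores on the m retained
    components (index preserved).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 participants for PCA")
    if matrix.isna().any().any():
        raise ValueError("matrix has missing cells")

    means = matrix.mean()
    scales = matrix.std(ddof=1)
    zero_var = scales.index[scales == 0.0].tolist()
    if zero_var:
        warnings.warn(f"dropping zero-variance columns: {zero_var}", stacklevel=2)
    kept = matrix.drop(columns=zero_var)
    z = (kept - means[kept.columns]) / scales[kept.columns]

    pca = PCA(n_components=None, svd_solver="full")
    all_scores = pca.fit_transform(z.to_numpy())
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    m = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    m = min(m, len(evr))

    compression = PCACompression(
        means=means,
        scales=scales,
        components=pca.components_,
        explained_variance_ratio=evr,
        n_retained=m,
        cumulative_variance=float(cum[m - 1]),
        dropped_columns=zero_var,
    )
    scores = pd.DataFrame(
        all_scores[:, :m], index=matrix.index, columns=[f"PC{i+1}" for i in range(m)]
    )
    return compression, scores


def kmeans_fit(
    scores: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> tuple[pd.Series, np.ndarray, float]:
    """Best-of-``n_restarts`` k-means++; returns (labels, centers, WSS)."""
    n = scores.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds number of observations n = {n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(scores.to_numpy())
    labels = pd.Series(raw + 1, index=scores.index, name="cluster")
    return labels, km.cluster_centers_, float(km.inertia_)


def wss_curve(
    scores: pd.DataFrame, k_max: int = 9, seed: int = 0, n_restarts: int = 50
) -> pd.Series:
    """Within-cluster sum of squares for k = 1..k_max."""
    values = {}
    for k in range(1, k_max + 1):
        _, _, wss = kmeans_fit(scores, k, seed=seed, n_restarts=n_restarts)
        values[k] = wss
    return pd.Series(values, name="wss").rename_axis("k")


def elbow_select_k(curve: pd.Series) -> int:
    """Pick k at maximum perpendicular distance to the endpoint chord.

    The curve is first made non-increasing by a running minimum.  Ties are
    broken toward smaller k, so a linear or flat curve yields k = 1.
    """
    ks = np.asarray(curve.index, dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow selection needs a WSS curve with k_max >= 3")
    wss = np.minimum.accumulate(np.asarray(curve.to_numpy(), dtype=float))

    p0 = np.array([ks[0], wss[0]])
    p1 = np.array([ks[-1], wss[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0.0:
        return int(ks[0])
    # distance of each point from the chord (cross-product magnitude)
    vx, vy = ks - p0[0], wss - p0[1]
    dist = np.abs(chord[0] * vy - chord[1] * vx) / norm
    return int(ks[int(np.argmax(dist))])


def order_clusters(
    labels: pd.Series,
    panel: CohortPanel,
    ordering_features: list[str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Relabel clusters 1..k ascending by baseline severity.

    Severity of a cluster is the mean over its members of the mean z-scored
    baseline ordering features (default: all feature columns present at
    baseline).  Ties are broken by cluster size descending, then original
    label.  Returns (ordered labels, per-original-cluster severity).
    """
    base = panel.baseline()
    features = ordering_features or [c for c in panel.feature_names if c in base.columns]
    missing = [f for f in features if f not in base.columns]
    if missing:
        raise KeyError(f"ordering features absent at baseline: {missing}")

    sub = base.loc[base.index.intersection(labels.index), features]
    z = (sub - sub.mean()) / sub.std(ddof=1).replace(0.0, 1.0)
    person_severity = z.mean(axis=1)

    severity = {}
    sizes = labels.value_counts()
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        members = members.intersection(person_severity.index)
        if len(members) == 0:
            raise ValueError(f"cluster {cluster} has no members with baseline data")
        severity[cluster] = float(person_severity.loc[members].mean())
    severity = pd.Series(severity, name="severity")

    order = sorted(
        severity.index, key=lambda c: (severity[c], -int(sizes.get(c, 0)), c)
    )
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(mapping).rename(labels.name), severity


def cluster_agreement(
    labels_a: pd.Series, labels_b: pd.Series, common_ids=None
) -> tuple[float, pd.DataFrame, float]:
    """Agreement under optimal one-to-one label matching, plus ARI.

    The confusion matrix between the two labelings is matched with the
    assignment problem (maximizing total overlap); agreement is the matched
    overlap divided by the number of common ids.
    """
    if common_ids is None:
        common_ids = labels_a.index.intersection(labels_b.index)
    common_ids = pd.Index(common_ids)
    if len(common_ids) == 0:
        raise ValueError("labelings share no ids")
    a = labels_a.loc[common_ids]
    b = labels_b.loc[common_ids]
    confusion = pd.crosstab(a, b)
    # pad to square so the assignment is one-to-one
    mat = confusion.to_numpy()
    n_rows, n_cols = mat.shape
    size = max(n_rows, n_cols)
    padded = np.zeros((size, size))
    padded[:n_rows, :n_cols] = mat
    rows, cols = linear_sum_assignment(padded, maximize=True)
    agreement = float(padded[rows, cols].sum() / len(common_ids))
    ari = float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
    return agreement, confusion, ari


def cluster_pipeline(
    matrix: pd.DataFrame,
    panel: CohortPanel,
    variance_threshold: float = 0.85,
    k_max: int = 9,
    forced_k: int | None = None,
    seed: int = 0,
    ordering_features: list[str] | None = None,
    n_restarts: int = 50,
) -> tuple[PCACompression, ClusterSolution]:
    """Standardize + reduce, scan k, select (or force) k, order labels."""
    compression, scores = standardize_and_reduce(matrix, variance_threshold)
    curve = wss_curve(scores, k_max=k_max, seed=seed, n_restarts=n_restarts)
    if forced_k is not None:
        k, selection = forced_k, "forced"
    else:
        k, selection = elbow_select_k(curve), "elbow"
    labels, centers, _ = kmeans_fit(scores, k, seed=seed, n_restarts=n_restarts)
    ordered, severity = order_clusters(labels, panel, ordering_features)
    solution = ClusterSolution(
        k=k,
        labels=ordered.rename("phenotype"),
        centers=centers,
        wss_curve=curve,
        selection=selection,
        seed=seed,
        severity=severity,
    )
    return compression, solution
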