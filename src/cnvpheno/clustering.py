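"""k-means phenotype clustering with Calinski-Harabasz selection of K.

Subjects are clustered on the binary fine-phenotype matrix, treated as
0/1 real vectors under Euclidean distance (no scaling, weighting, or
dimensionality reduction).  Lloyd's algorithm is restarted from many
random row initializations and the best run (lowest within-cluster sum
of squares) is kept; K is scanned over a range and chosen by the
Calinski-Harabasz index CH = (B/(K-1)) / (W/(n-K)), the between- over
within-cluster variance ratio.

Lloyd's algorithm and the index are implemented here because their
exact behaviour (row-sampling initialization, farthest-point
empty-cluster repair, per-iteration monotonicity, the W = 0 sentinel)
is part of the pipeline's contract; scikit-learn serves only as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import bh_adjust, fisher_exact_2x2
from .characterize import RankSumResult, rank_sum_test
from .phenotypes import PhenotypeMatrix, abnormality_counts

__all__ = [
    "kmeans",
    "calinski_index",
    "select_k",
    "ClusterResult",
    "ClusterCharacterization",
    "characterize_clusters",
    "adjusted_rand_index",
]

_MAX_ITER = 300
_WSS_RTOL = 1e-9


def _as_array(matrix: PhenotypeMatrix | np.ndarray | pd.DataFrame) -> tuple[np.ndarray, list]:
    if isinstance(matrix, PhenotypeMatrix):
        return matrix.data.to_numpy(dtype=float), matrix.subjects
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index)
    arr = np.asarray(matrix, dtype=float)
    return arr, list(range(arr.shape[0]))


def _sq_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = (
        (x * x).sum(axis=1)[:, None]
        + (centroids * centroids).sum(axis=1)[None, :]
        - 2.0 * x @ centroids.T
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=int)
    prev_wss = math.inf
    for _ in range(max_iter):
        d2 = _sq_distances(x, centroids)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: re-seed at the point farthest from its
        # centroid; looped because one repair can empty another cluster
        for _repair in range(k):
            empty = np.setdiff1d(np.arange(k), new_labels)
            if empty.size == 0:
                break
            point_d2 = d2[np.arange(n), new_labels]
            far = int(point_d2.argmax())
            if point_d2[far] <= 0.0:  # every point sits on a centroid already
                break
            centroids[empty[0]] = x[far]
            d2 = _sq_distances(x, centroids)
            new_labels = d2.argmin(axis=1)
        wss = float(d2[np.arange(n), new_labels].sum())
        assert wss <= prev_wss * (1 + _WSS_RTOL) + 1e-12, "wss increased across iterations"
        if (new_labels == labels).all():
            break
        labels, prev_wss = new_labels, wss
        for j in range(k):
            members = labels == j
            if members.any():
                centroids[j] = x[members].mean(axis=0)
    d2 = _sq_distances(x, centroids)
    wss = float(d2[np.arange(n), labels].sum())
    return labels, centroids, wss


def kmeans(
    matrix: PhenotypeMatrix | np.ndarray,
    k: int,
    restarts: int = 100,
    seed: int = 1,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``restarts`` Lloyd k-means on rows of the matrix.

    Each restart initializes centroids at ``k`` distinct data rows drawn
    uniformly; the run with the lowest within-cluster sum of squares
    wins (first winner on ties, so the result is deterministic given
    ``seed``).  Returns 1-based labels, centroids, and the wss.
    """
    x, _ = _as_array(matrix)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"require 2 <= k <= n_subjects, got k={k}, n={n}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct rows")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        labels, centroids, wss = _lloyd(x, k, rng, max_iter)
        if best is None or wss < best[2]:
            best = (labels, centroids, wss)
    labels, centroids, wss = best
    return labels + 1, centroids, wss


def calinski_index(
    matrix: PhenotypeMatrix | np.ndarray, assignments: Sequence[int] | np.ndarray
) -> float:
    """Calinski-Harabasz index (B/(K-1)) / (W/(n-K)).

    Returns ``inf`` when the within-cluster sum of squares is zero
    (perfectly collapsed clusters).
    """
    x, _ = _as_array(matrix)
    labels = np.asarray(assignments)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("assignments length must match the number of rows")
    uniq = np.unique(labels)
    k, n = uniq.size, x.shape[0]
    if k < 2:
        raise ValueError("need >= 2 non-empty clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = x.mean(axis=0)
    b = w = 0.0
    for lab in uniq:
        pts = x[labels == lab]
        centroid = pts.mean(axis=0)
        b += pts.shape[0] * float(((centroid - grand) ** 2).sum())
        w += float(((pts - centroid) ** 2).sum())
    if w <= 0.0:
        return math.inf
    return (b / (k - 1)) / (w / (n - k))


@dataclass
class ClusterResult:
    """k-means solution at the Calinski-selected K, with the full K trace."""

    assignments: pd.Series  # subject id -> 1-based cluster label
    centroids: np.ndarray
    wss: float
    per_k_ch: dict[int, float]
    chosen_k: int
    seed: int
    restarts: int


def select_k(
    matrix: PhenotypeMatrix | np.ndarray,
    k_range: Sequence[int] | None = None,
    restarts: int = 100,
    seed: int = 1,
) -> ClusterResult:
    """Scan K, cluster at each, and keep the K maximizing the Calinski index.

    The default scan is 2..min(10, n-1); ties (including multiple
    infinite indexes) resolve to the smallest K.
    """
    x, subjects = _as_array(matrix)
    n = x.shape[0]
    ks = list(k_range) if k_range is not None else list(range(2, min(10, n - 1) + 1))
    if not ks or min(ks) < 2 or max(ks) >= n:
        raise ValueError(f"k_range must lie within [2, n-1], got {ks}")
    per_k_ch: dict[int, float] = {}
    best = None
    for k in sorted(ks):
        labels, centroids, wss = kmeans(x, k, restarts=restarts, seed=seed)
        ch = calinski_index(x, labels)
        per_k_ch[k] = ch
        if best is None or ch > best[0]:
            best = (ch, k, labels, centroids, wss)
    _, chosen_k, labels, centroids, wss = best
    return ClusterResult(
        assignments=pd.Series(labels, index=pd.Index(subjects, name="subject_id")),
        centroids=centroids,
        wss=wss,
        per_k_ch=per_k_ch,
        chosen_k=chosen_k,
        seed=seed,
        restarts=restarts,
    )


@dataclass
class ClusterCharacterization:
    counts: pd.Series  # per-subject abnormality counts
    mean_counts: pd.Series  # per-cluster mean abnormality count
    count_tests: pd.DataFrame  # pairwise rank-sum tests on the counts
    feature_table: pd.DataFrame | None  # per-feature Fisher + BH (K = 2 only)


def characterize_clusters(
    matrix: PhenotypeMatrix, result: ClusterResult
) -> ClusterCharacterization:
    """Abnormality burden and per-feature prevalence differences by cluster.

    Per-subject abnormal-feature counts are compared between clusters
    with the Wilcoxon rank-sum test (all pairs).  When K = 2, each
    feature's prevalence is additionally compared with a Fisher exact
    test, BH-adjusted across the features.
    """
    labels = result.assignments.reindex(matrix.subjects)
    if labels.isna().any():
        raise ValueError("cluster result does not cover every matrix subject")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters to characterize")
    counts, _ = abnormality_counts(matrix)
    mean_counts = counts.groupby(labels).mean()
    mean_counts.index = [f"cluster_{int(c)}" for c in mean_counts.index]

    tests = []
    for i, a in enumerate(uniq):
        for b_lab in uniq[i + 1 :]:
            res: RankSumResult = rank_sum_test(
                counts[labels == a].to_numpy(), counts[labels == b_lab].to_numpy()
            )
            tests.append(
                {
                    "cluster_a": int(a),
                    "cluster_b": int(b_lab),
                    "statistic": res.statistic,
                    "p_value": res.pvalue,
                    "method": res.method,
                }
            )
    count_tests = pd.DataFrame(tests)

    feature_table = None
    if len(uniq) == 2:
        a_lab, b_lab = uniq
        subj_a = labels.index[labels == a_lab]
        subj_b = labels.index[labels == b_lab]
        n_a, n_b = len(subj_a), len(subj_b)
        rows = []
        for feature in matrix.features:
            k_a = int(matrix.data.loc[subj_a, feature].sum())
            k_b = int(matrix.data.loc[subj_b, feature].sum())
            rows.append(
                {
                    "feature": feature,
                    "n_a": n_a,
                    "abnormal_a": k_a,
                    "prevalence_a": k_a / n_a,
                    "n_b": n_b,
                    "abnormal_b": k_b,
                    "prevalence_b": k_b / n_b,
                    "p_value": fisher_exact_2x2(
                        [[k_a, k_b], [n_a - k_a, n_b - k_b]]
                    ),
                }
            )
        feature_table = pd.DataFrame(rows).set_index("feature")
        feature_table["q_value"] = bh_adjust(feature_table["p_value"].to_numpy())

    return ClusterCharacterization(
        counts=counts,
        mean_counts=mean_counts,
        count_tests=count_tests,
        feature_table=feature_table,
    )


def adjusted_rand_index(
    labels_a: Sequence[int] | np.ndarray, labels_b: Sequence[int] | np.ndarray
) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def _comb2(v: np.ndarray) -> float:
        return float((v * (v - 1) // 2).sum())

    sum_ij = _comb2(contingency.ravel())
    sum_a = _comb2(contingency.sum(axis=1))
    sum_b = _comb2(contingency.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
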