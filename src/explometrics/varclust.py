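"""Hierarchical clustering of variables with PCA homogeneity.

Variables (here: exploration measures across a cohort) are merged
agglomeratively.  The homogeneity of a cluster is the leading
eigenvalue of the correlation matrix of its variables — equivalently
the sum of squared correlations of the variables with the cluster's
first principal component — and each merge joins the pair of clusters
whose union loses the least homogeneity.  Because similarity is a
squared correlation, the tree is invariant to sign flips and affine
rescaling of any variable.  A kneedle-style elbow detector suggests the
number of clusters from the aggregation heights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariableMatrix",
    "ClusterTree",
    "ClusterSolution",
    "orient_measures",
    "standardize",
    "similarity_matrix",
    "cluster_variables",
    "cut_tree",
    "kneedle_elbow",
]


@dataclass
class VariableMatrix:
    """A subjects x variables numeric table with no missing values."""

    values: np.ndarray
    variable_names: List[str]
    subject_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x variables)")
        if self.values.shape != (len(self.subject_ids), len(self.variable_names)):
            raise ValueError("values shape does not match names/ids")
        if len(self.subject_ids) < 3:
            raise ValueError("need at least 3 subjects")
        if np.isnan(self.values).any():
            raise ValueError("missing values present; apply a completeness policy first")
        variances = self.values.var(axis=0, ddof=1)
        zero = [n for n, v in zip(self.variable_names, variances) if v == 0.0]
        if zero:
            raise ValueError(f"constant variable(s): {zero}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_column: str = "subject_id",
                   dropna: bool = True) -> "VariableMatrix":
        df = df.copy()
        if id_column in df.columns:
            ids = df[id_column].astype(str).tolist()
            df = df.drop(columns=[id_column])
        else:
            ids = [str(i) for i in df.index]
        if dropna:
            complete = ~df.isna().any(axis=1)
            dropped = int((~complete).sum())
            if dropped:
                logger.info("dropping %d subject(s) with missing values", dropped)
            ids = [i for i, ok in zip(ids, complete) if ok]
            df = df.loc[complete.values]
        return cls(df.to_numpy(dtype=float), list(df.columns), ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.variable_names)

    def copy(self) -> "VariableMatrix":
        return VariableMatrix(self.values.copy(), list(self.variable_names),
                              list(self.subject_ids))


@dataclass
class ClusterTree:
    """Merge history: ordered (members_a, members_b, height) triples.

    Heights are homogeneity losses (non-negative up to rounding); with
    p variables there are p - 1 merges.  ``leaf_order`` is a
    deterministic dendrogram ordering of the variables.
    """

    merges: List[Tuple[frozenset, frozenset, float]]
    leaf_order: List[str]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    @property
    def n_variables(self) -> int:
        return len(self.leaf_order)


@dataclass
class ClusterSolution:
    """A cut of the tree at k clusters.

    ``synthetic_scores`` holds one synthetic cluster variable per
    cluster: the first principal component of the cluster's
    standardized variables, scaled to unit variance and oriented so the
    mean correlation with the cluster's members is positive.
    ``loadings`` are Pearson correlations of every variable with every
    synthetic score.
    """

    k: int
    assignment: Dict[str, int]
    synthetic_scores: pd.DataFrame
    loadings: pd.DataFrame


def orient_measures(matrix: VariableMatrix, invert: Sequence[str]) -> VariableMatrix:
    """Multiply the named variables by -1 (display convention only).

    The clustering itself is invariant to this (similarity is r^2), but
    loadings and similarity displays change sign, which is used to give
    all efficiency-type measures a "higher = better" reading.
    """
    out = matrix.copy()
    for name in invert:
        if name not in out.variable_names:
            raise KeyError(f"unknown variable {name!r}")
        out.values[:, out.variable_names.index(name)] *= -1.0
    return out


def standardize(matrix: VariableMatrix) -> VariableMatrix:
    """Scale each variable to mean 0 and standard deviation 1 (ddof=1)."""
    out = matrix.copy()
    mean = out.values.mean(axis=0)
    sd = out.values.std(axis=0, ddof=1)
    zero = [n for n, s in zip(out.variable_names, sd) if s == 0.0]
    if zero:
        raise ValueError(f"constant variable(s): {zero}")
    out.values = (out.values - mean) / sd
    return out


def similarity_matrix(matrix: VariableMatrix) -> pd.DataFrame:
    """Squared Pearson correlations between variables (direction-blind)."""
    corr = np.corrcoef(matrix.values, rowvar=False)
    sim = corr**2
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=matrix.variable_names,
                        columns=matrix.variable_names)


def _homogeneity(corr: pd.DataFrame, members: frozenset) -> float:
    """Leading eigenvalue of the correlation matrix of the members."""
    idx = sorted(members)
    if len(idx) == 1:
        return 1.0
    sub = corr.loc[idx, idx].to_numpy()
    return float(np.linalg.eigvalsh(sub)[-1])


def cluster_variables(matrix: VariableMatrix) -> ClusterTree:
    """Agglomerative clustering of variables by homogeneity loss.

    Merge criterion: ``d(A, B) = H(A) + H(B) - H(A u B)`` where ``H``
    is the cluster homogeneity; the pair with minimal loss merges and
    ``d`` is recorded as the aggregation height.  Ties are broken by
    the lexicographically smallest member name for reproducibility.
    """
    names = matrix.variable_names
    if len(names) < 2:
        raise ValueError("need at least 2 variables to cluster")
    corr = pd.DataFrame(
        np.corrcoef(matrix.values, rowvar=False), index=names, columns=names
    )
    clusters: List[frozenset] = [frozenset([n]) for n in names]
    orders: Dict[frozenset, List[str]] = {c: [next(iter(c))] for c in clusters}
    h_cache: Dict[frozenset, float] = {c: 1.0 for c in clusters}
    merges: List[Tuple[frozenset, frozenset, float]] = []

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                union = a | b
                if union not in h_cache:
                    h_cache[union] = _homogeneity(corr, union)
                d = h_cache[a] + h_cache[b] - h_cache[union]
                key = (d, min(min(a), min(b)), max(min(a), min(b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        union = a | b
        first, second = (a, b) if min(a) <= min(b) else (b, a)
        merges.append((first, second, float(d)))
        orders[union] = orders[first] + orders[second]
        clusters = [c for c in clusters if c not in (a, b)] + [union]

    return ClusterTree(merges=merges, leaf_order=orders[frozenset(names)])


def cut_tree(tree: ClusterTree, k: int, matrix: VariableMatrix) -> ClusterSolution:
    """Undo the last ``n - k`` merges and build synthetic cluster scores."""
    n = tree.n_variables
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    std = standardize(matrix)
    clusters: List[frozenset] = [frozenset([v]) for v in tree.leaf_order]
    for a, b, _ in tree.merges[: n - k]:
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    # stable labels: order clusters by their first variable in leaf order
    position = {v: i for i, v in enumerate(tree.leaf_order)}
    clusters.sort(key=lambda c: min(position[v] for v in c))
    assignment = {v: ci for ci, c in enumerate(clusters) for v in sorted(c)}

    frame = std.to_frame()
    n_subj = len(frame)
    scores = {}
    for ci, members in enumerate(clusters):
        cols = sorted(members)
        x = frame[cols].to_numpy()
        if len(cols) == 1:
            s = x[:, 0]
        else:
            corr = x.T @ x / (n_subj - 1)
            vals, vecs = np.linalg.eigh(corr)
            v = vecs[:, -1]
            s = x @ v
            s = s / s.std(ddof=1)
        member_corr = np.array(
            [np.corrcoef(frame[c], s)[0, 1] for c in cols]
        )
        if member_corr.mean() < 0:
            s = -s
        scores[f"cluster_{ci + 1}"] = s
    score_df = pd.DataFrame(scores, index=frame.index)
    loadings = pd.DataFrame(
        {
            sc: [np.corrcoef(frame[v], score_df[sc])[0, 1] for v in std.variable_names]
            for sc in score_df.columns
        },
        index=std.variable_names,
    )
    return ClusterSolution(
        k=k, assignment=assignment, synthetic_scores=score_df, loadings=loadings
    )


def kneedle_elbow(
    heights: Sequence[float], sensitivity: float = 1.0
) -> Optional[int]:
    """Knee of the aggregation-height curve (offline kneedle).

    ``heights[i]`` is the aggregation height plotted at ``x = i + 1``
    clusters, so the sequence must be non-increasing (the merge down to
    one cluster is the most expensive).  The curve is min-max
    normalized, flipped to an increasing-concave shape, and the knee is
    the first local maximum of the difference curve ``y - x`` whose
    prominence survives the sensitivity-scaled threshold.  Returns the
    suggested number of clusters, or ``None`` when no knee passes.
    """
    y = np.asarray(heights, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 heights")
    if np.any(np.diff(y) > 1e-12):
        raise ValueError("heights must be non-increasing (sorted as plotted)")
    x = np.arange(1, len(y) + 1, dtype=float)
    span = y.max() - y.min()
    if span == 0:
        return None
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / span
    yt = yn.max() - yn  # decreasing-convex -> increasing-concave
    diff = yt - xn
    maxima = [
        i
        for i in range(1, len(diff) - 1)
        if diff[i] >= diff[i - 1] and diff[i] >= diff[i + 1] and diff[i] > 0
    ]
    if not maxima:
        return None
    step_thresh = sensitivity * np.mean(np.diff(xn))
    maxima_set = set(maxima)
    for lm in maxima:
        threshold = diff[lm] - step_thresh
        for j in range(lm + 1, len(diff)):
            if j in maxima_set:
                break  # superseded by the next candidate knee
            if diff[j] < threshold:
                return int(x[lm])
    return None
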