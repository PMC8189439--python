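"""Fuzzy c-means clustering of z-scored temporal profiles and attribution of
clusters to lineages by the proportion of modulated genes.

Soft clustering gives each gene graded memberships across cluster centers,
controlled by the fuzzifier exponent m > 1; hard labels (argmax membership)
are used for the integer cluster sizes and the lineage-ratio table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

from .matrix import ExpressionMatrix, GeneSet

logger = logging.getLogger("embryostage")


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, population (1/N) sd 1.

    Rows with zero standard deviation carry no temporal shape and are
    dropped with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 columns to z-score")
    vals = m.values.to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} constant gene rows", stacklevel=2)
    z = (vals[~flat] - mu[~flat]) / sd[~flat]
    out = pd.DataFrame(z, index=m.values.index[~flat], columns=m.values.columns)
    return ExpressionMatrix(out, m.scale)


def estimate_fuzzifier(n_genes: int, n_features: int) -> float:
    """Data-size heuristic for the fuzzifier exponent m, clipped to [1.05, 3].

    m = 1 + (1418/N + 22.05)·D^(−2)
          + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134)

    with N genes and D features. Falls back to 1.25 if the formula
    misbehaves (non-finite or out of any plausible range before clipping).
    """
    if n_genes < 10:
        raise ValueError("fuzzifier heuristic needs at least 10 genes")
    N, D = float(n_genes), float(n_features)
    m = 1.0 + (1418.0 / N + 22.05) * D ** (-2.0) + (12.33 / N + 0.243) * D ** (
        -0.0406 * np.log(N) - 0.1134
    )
    if not np.isfinite(m) or m <= 1.0 or m > 10.0:
        warnings.warn("fuzzifier heuristic misbehaved; using default 1.25", stacklevel=2)
        m = 1.25
    return float(np.clip(m, 1.05, 3.0))


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means with the standard alternating updates.

    Memberships: u_ij ∝ ||x_i − c_j||^(−2/(m−1)), normalized per point;
    centers: c_j = Σ_i u_ij^m x_i / Σ_i u_ij^m. Iteration stops when the
    maximum center shift falls below `tol` or after `max_iter` rounds. A
    point coinciding exactly with a center receives full membership there.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_features)
    membership_ : ndarray (n_samples, n_clusters), rows sum to 1.
    labels_ : ndarray, argmax membership (ties to the lower cluster index).
    objective_path_ : list of the objective Σ u^m d² per iteration
        (non-increasing).
    rowsum_max_err_ : float, worst |row sum − 1| seen across all iterations.
    """

    def __init__(self, n_clusters: int = 6, m: float = 1.25, tol: float = 1e-6,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        c = self.n_clusters
        if c < 1:
            raise ValueError("n_clusters must be >= 1")
        if n < c:
            raise ValueError(f"{n} points cannot form {c} clusters")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        rng = check_random_state(self.random_state)

        if c == 1:
            self.cluster_centers_ = X.mean(axis=0, keepdims=True)
            self.membership_ = np.ones((n, 1))
            self.labels_ = np.zeros(n, dtype=int)
            self.objective_path_ = [
                float((((X - self.cluster_centers_) ** 2).sum()))
            ]
            self.rowsum_max_err_ = 0.0
            self.n_iter_ = 1
            return self

        u = rng.random_sample((n, c))
        u /= u.sum(axis=1, keepdims=True)
        exponent = 2.0 / (self.m - 1.0)
        centers = np.empty((c, d))
        prev_centers = None
        self.objective_path_ = []
        self.rowsum_max_err_ = 0.0
        for it in range(self.max_iter):
            um = u ** self.m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            d2 = cdist(X, centers, metric="sqeuclidean")
            self.objective_path_.append(float((um * d2).sum()))
            zero_rows = (d2 == 0).any(axis=1)
            with np.errstate(divide="ignore"):
                inv = d2 ** (-1.0 / (self.m - 1.0) * 1.0)  # d^(-2/(m-1)) since d2 = d²
            u = inv / inv.sum(axis=1, keepdims=True)
            if zero_rows.any():
                # exact coincidence with a center: full membership there
                u[zero_rows] = 0.0
                hits = np.argmin(d2[zero_rows], axis=1)
                u[np.flatnonzero(zero_rows), hits] = 1.0
            self.rowsum_max_err_ = max(
                self.rowsum_max_err_, float(np.abs(u.sum(axis=1) - 1.0).max())
            )
            if prev_centers is not None:
                if np.abs(centers - prev_centers).max() < self.tol:
                    break
            prev_centers = centers.copy()
        # final objective with converged memberships
        um = u ** self.m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = cdist(X, centers, metric="sqeuclidean")
        self.objective_path_.append(float((um * d2).sum()))
        self.n_iter_ = it + 1

        # stable cluster identity: relabel in order of the center's argmax position
        order = np.lexsort((np.arange(c), centers.argmax(axis=1)))
        centers = centers[order]
        u = u[:, order]
        self.cluster_centers_ = centers
        self.membership_ = u
        self.labels_ = u.argmax(axis=1)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: np.ndarray) -> np.ndarray:
        d2 = cdist(np.asarray(X, float), self.cluster_centers_, metric="sqeuclidean")
        return d2.argmin(axis=1)


@dataclass
class ClusterModel:
    """Fitted temporal clustering with centers, memberships and hard labels."""

    centers: pd.DataFrame       # cluster x timepoint
    memberships: pd.DataFrame   # gene x cluster, rows sum to 1
    fuzzifier_m: float
    n_clusters: int
    hard_labels: pd.Series      # per-gene argmax cluster id
    objective_path: list[float]

    def cluster_sizes(self) -> pd.Series:
        return self.hard_labels.value_counts().sort_index()


def fuzzy_cmeans(
    m: ExpressionMatrix,
    c: int = 6,
    fuzzifier_m: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusterModel:
    """Cluster z-scored gene rows into `c` temporal shapes.

    `fuzzifier_m=None` invokes the data-size heuristic. Cluster identities
    are relabeled in order of the time of each center's maximum so reports
    are stable across runs.
    """
    X = m.values.to_numpy()
    if fuzzifier_m is None:
        fuzzifier_m = estimate_fuzzifier(*X.shape)
    est = FuzzyCMeans(
        n_clusters=c, m=fuzzifier_m, tol=tol, max_iter=max_iter, random_state=seed
    ).fit(X)
    names = [f"cluster{i + 1}" for i in range(c)]
    return ClusterModel(
        centers=pd.DataFrame(est.cluster_centers_, index=names, columns=m.sample_ids),
        memberships=pd.DataFrame(est.membership_, index=m.gene_ids, columns=names),
        fuzzifier_m=fuzzifier_m,
        n_clusters=c,
        hard_labels=pd.Series(
            [names[i] for i in est.labels_], index=m.gene_ids, name="cluster"
        ),
        objective_path=est.objective_path_,
    )


def cluster_lineage_ratio(
    model: ClusterModel,
    contrasts: dict[str, tuple[GeneSet, GeneSet]],
) -> pd.DataFrame:
    """Per-cluster counts and within-contrast ratios of modulated genes.

    `contrasts` maps a contrast name (e.g. "eTE_vs_ICM") to its two opposed
    gene sets; the two sets of a contrast must be disjoint. Genes outside
    every set are ignored; a cluster with no genes from a contrast has both
    ratios undefined (NaN).
    """
    rows = []
    for cname, (set_a, set_b) in contrasts.items():
        overlap = set(set_a.genes) & set(set_b.genes)
        if overlap:
            raise ValueError(
                f"sets of contrast {cname!r} share genes: {sorted(overlap)[:5]}"
            )
    labels = model.hard_labels
    for cluster in model.centers.index:
        members = set(labels.index[labels == cluster])
        row: dict[str, object] = {"cluster": cluster, "n_genes": len(members)}
        for cname, (set_a, set_b) in contrasts.items():
            na = len(members & set(set_a.genes))
            nb = len(members & set(set_b.genes))
            row[f"{cname}:{set_a.name}_count"] = na
            row[f"{cname}:{set_b.name}_count"] = nb
            denom = na + nb
            row[f"{cname}:{set_a.name}_ratio"] = na / denom if denom else np.nan
            row[f"{cname}:{set_b.name}_ratio"] = nb / denom if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
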