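"""PCA of expression matrices, gene-loading density overlays, and
average-linkage ordering for heatmaps.

The "contribution" of a gene to the sample PCA is its coordinate pair in
loading space; a 2D Gaussian product-kernel density over the loadings of a
gene set yields the contour overlay that localizes a lineage program in the
component plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, GeneSet, StageReference

logger = logging.getLogger("embryostage")


@dataclass
class Embedding:
    """PCA result: sample scores, gene loadings, and bookkeeping.

    Loadings columns are orthonormal; the sign convention makes the
    largest-magnitude loading of every component positive, so results are
    reproducible across linear-algebra backends.
    """

    sample_scores: pd.DataFrame   # samples x components
    gene_loadings: pd.DataFrame   # genes x components
    explained_variance: np.ndarray
    centering: pd.Series          # per-gene means removed before decomposition
    n_components: int
    sample_labels: pd.Series | None = None  # provenance (e.g. query vs reference)


@dataclass
class DensityGrid:
    """Evaluated 2D kernel density with its grid, bandwidths, and contour levels."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray           # shape (len(x), len(y))
    bandwidth: tuple[float, float]
    levels: np.ndarray

    def mass(self) -> float:
        """Numeric integral of the density over the grid (trapezoid rule)."""
        inner = np.trapezoid(self.density, self.y, axis=1)
        return float(np.trapezoid(inner, self.x))


class LoadingPCA(BaseEstimator):
    """PCA over samples with gene loadings retained for density overlays.

    Genes are centered but not scaled before decomposition; the variance
    structure of log-scale expression is the signal.

    Attributes
    ----------
    embedding_ : Embedding
        Scores, loadings, explained-variance fractions and centering means.
    """

    def __init__(self, n_components: int = 10, gene_filter: GeneSet | None = None):
        self.n_components = n_components
        self.gene_filter = gene_filter

    def fit(self, X: ExpressionMatrix, y=None) -> "LoadingPCA":
        self.embedding_ = run_pca(X, self.n_components, self.gene_filter)
        return self

    def transform(self, X: ExpressionMatrix) -> pd.DataFrame:
        """Project new samples onto the fitted component basis."""
        emb = self.embedding_
        genes = emb.gene_loadings.index
        centered = X.values.loc[genes].sub(emb.centering, axis=0)
        scores = centered.T.to_numpy() @ emb.gene_loadings.to_numpy()
        return pd.DataFrame(scores, index=X.sample_ids, columns=emb.sample_scores.columns)


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """In place: flip components whose largest-magnitude loading is negative."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def run_pca(
    m: ExpressionMatrix, n_components: int = 10, gene_filter: GeneSet | None = None
) -> Embedding:
    """Principal-component analysis of samples, genes centered (not scaled).

    Scores and loadings satisfy scores = centered_dataᵀ · loadings. When a
    `gene_filter` is given the decomposition uses only those genes (the
    intersection with the matrix must be at least `n_components`).
    """
    if gene_filter is not None:
        present = [g for g in gene_filter.genes if g in set(m.gene_ids)]
        if len(present) < n_components:
            raise ValueError(
                f"gene filter leaves {len(present)} genes; need >= {n_components}"
            )
        m = m.subset_genes(present)
    n_genes, n_samples = m.shape
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(n_genes, n_samples):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(n_genes, n_samples)}"
        )
    X = m.values.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    _fix_signs(loadings, scores)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return Embedding(
        sample_scores=pd.DataFrame(scores, index=m.sample_ids, columns=comp_names),
        gene_loadings=pd.DataFrame(loadings, index=m.gene_ids, columns=comp_names),
        explained_variance=pca.explained_variance_ratio_.copy(),
        centering=pd.Series(pca.mean_, index=m.gene_ids),
        n_components=n_components,
    )


def joint_pca(
    query: ExpressionMatrix,
    reference: StageReference,
    gene_filter: GeneSet | None = None,
    n_components: int = 10,
) -> Embedding:
    """One PCA over query samples and reference stages together.

    Columns are concatenated on the shared gene space before centering and
    decomposition (no projection of one set onto the other's basis); the
    returned embedding carries a "query"/"reference" label per column.
    """
    shared = [g for g in query.gene_ids if g in set(reference.gene_ids)]
    if gene_filter is not None:
        in_filter = set(gene_filter.genes)
        shared = [g for g in shared if g in in_filter]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared between query and reference")
    overlap = set(query.sample_ids) & set(reference.stages)
    if overlap:
        raise ValueError(f"query and reference share column names: {sorted(overlap)[:3]}")
    combined = pd.concat(
        [query.values.loc[shared], reference.values.loc[shared]], axis=1
    )
    emb = run_pca(ExpressionMatrix(combined, query.scale), n_components)
    labels = pd.Series(
        ["query"] * len(query.sample_ids) + ["reference"] * len(reference.stages),
        index=emb.sample_scores.index,
    )
    emb.sample_labels = labels
    return emb


def normal_reference_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Per-axis normal-reference (Scott) bandwidth for a 2D point cloud:
    h_i = sigma_i * n^(-1/6)."""
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-6)
    h = sd * n ** (-1.0 / 6.0)
    return float(h[0]), float(h[1])


def loading_density(
    e: Embedding,
    gene_set: GeneSet,
    components: tuple[int, int] = (1, 2),
    bandwidth: tuple[float, float] | None = None,
    gridsize: tuple[int, int] = (128, 128),
    level_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> DensityGrid:
    """2D Gaussian product-kernel density of a gene set's loadings.

    `components` are 1-based (PC1, PC2). The grid extends 4 bandwidths past
    the extreme points so the numeric mass is ~1; contour levels are the
    stated quantiles of the density evaluated at the set's own points.
    """
    cols = [f"PC{components[0]}", f"PC{components[1]}"]
    present = [g for g in gene_set.genes if g in e.gene_loadings.index]
    if len(present) < 2:
        raise ValueError(
            f"need >= 2 genes of set {gene_set.name!r} in the loadings; have {len(present)}"
        )
    pts = e.gene_loadings.loc[present, cols].to_numpy()
    if bandwidth is None:
        bandwidth = normal_reference_bandwidth(pts)
    hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    gx = np.linspace(pts[:, 0].min() - 4 * hx, pts[:, 0].max() + 4 * hx, gridsize[0])
    gy = np.linspace(pts[:, 1].min() - 4 * hy, pts[:, 1].max() + 4 * hy, gridsize[1])
    density = _product_kde(pts, gx, gy, hx, hy)
    at_points = _kde_at(pts, pts, hx, hy)
    levels = np.quantile(at_points, level_quantiles)
    return DensityGrid(gx, gy, density, (hx, hy), levels)


def _product_kde(pts: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                 hx: float, hy: float) -> np.ndarray:
    n = pts.shape[0]
    ax = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2)
    ay = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2)
    norm = 1.0 / (n * 2.0 * np.pi * hx * hy)
    return norm * (ax @ ay.T)


def _kde_at(pts: np.ndarray, where: np.ndarray, hx: float, hy: float) -> np.ndarray:
    n = pts.shape[0]
    dx = (where[:, None, 0] - pts[None, :, 0]) / hx
    dy = (where[:, None, 1] - pts[None, :, 1]) / hy
    k = np.exp(-0.5 * (dx ** 2 + dy ** 2))
    return k.sum(axis=1) / (n * 2.0 * np.pi * hx * hy)


def kde_evaluate(grid_or_points: np.ndarray, pts: np.ndarray,
                 bandwidth: tuple[float, float]) -> np.ndarray:
    """Evaluate the product-kernel KDE of `pts` at arbitrary 2D locations."""
    return _kde_at(pts, np.atleast_2d(grid_or_points), *bandwidth)


def average_linkage_order(m: ExpressionMatrix, axis: str = "genes") -> np.ndarray:
    """Leaf order of an average-linkage (UPGMA) dendrogram on Euclidean distances.

    axis="genes" orders rows, axis="samples" orders columns. Deterministic
    given input order; scipy breaks distance ties by the smaller cluster
    index.
    """
    if axis == "genes":
        X = m.values.to_numpy()
    elif axis == "samples":
        X = m.values.to_numpy().T
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to order")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    return hierarchy.leaves_list(Z)
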