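"""Transcriptome staging by bootstrap Spearman correlation.

Each query transcriptome is correlated with every embryo reference stage
over repeated random subsets of the usable genes (genes shared with the
reference and expressed above a cutoff in at least one query sample). The
median correlation across iterations is robust to the particular genes
drawn; the per-query argmax stage ("trace") follows a trajectory across
stages as a time course progresses.

Subsets are drawn without replacement by default — "number of genes = k"
reads most naturally as a subsample — with a classical with-replacement
bootstrap and an exhaustive all-subsets mode also available. One subset per
iteration is shared across every query x stage pair, so each iteration
yields a coherent correlation profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix, StageReference

logger = logging.getLogger("embryostage")


@dataclass
class StagingParams:
    """Parameters of the bootstrap staging statistic.

    n_iterations : number of gene subsets drawn (ignored in exhaustive mode).
    genes_per_iteration : subset size k.
    expr_cutoff : log2 expression a gene must exceed in >= 1 query sample.
    sampling : "without_replacement" (default), "with_replacement", or
        "exhaustive" (all C(n, k) subsets; only sensible for tiny n).
    """

    n_iterations: int = 100
    genes_per_iteration: int = 50
    expr_cutoff: float = 1.0
    seed: int = 0
    sampling: str = "without_replacement"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.genes_per_iteration < 2:
            raise ValueError("genes_per_iteration must be >= 2")
        if self.sampling not in ("without_replacement", "with_replacement", "exhaustive"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass
class StagingResult:
    """Median bootstrap Spearman correlations and the per-query traced stage."""

    median_rho: pd.DataFrame              # query x stage, values in [-1, 1]
    trace: pd.Series                      # per-query argmax stage label
    usable_genes: list[str]
    iteration_rhos: np.ndarray | None = field(default=None, repr=False)
    # shape (n_query, n_stage, n_iterations) when retained


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. A constant vector has no rank ordering; the
    correlation is defined as 0 with a warning in that case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant input; Spearman correlation defined as 0", stacklevel=2)
        return 0.0
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


def _rank_corr_matrix(Q: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Spearman correlations between columns of Q (k x nq) and R (k x ns)."""
    k = Q.shape[0]
    rq = rankdata(Q, axis=0)
    rr = rankdata(R, axis=0)
    rq = rq - rq.mean(axis=0)
    rr = rr - rr.mean(axis=0)
    sq = rq.std(axis=0)
    sr = rr.std(axis=0)
    # constant columns: define rho = 0 by zeroing the standardized ranks
    rq = np.where(sq > 0, rq / np.where(sq > 0, sq, 1.0), 0.0)
    rr = np.where(sr > 0, rr / np.where(sr > 0, sr, 1.0), 0.0)
    return np.clip(rq.T @ rr / k, -1.0, 1.0)


def usable_gene_list(
    query: ExpressionMatrix, reference: StageReference, expr_cutoff: float
) -> list[str]:
    """Genes shared with the reference and above `expr_cutoff` in >= 1 query sample.

    The cutoff is applied on the query side only; query gene order is kept
    for determinism.
    """
    ref_genes = set(reference.gene_ids)
    expressed = (query.values.to_numpy() > expr_cutoff).any(axis=1)
    return [
        g for g, ok in zip(query.gene_ids, expressed) if ok and g in ref_genes
    ]


def bootstrap_stage_correlation(
    query: ExpressionMatrix,
    reference: StageReference,
    params: StagingParams | None = None,
    keep_iterations: bool = False,
) -> StagingResult:
    """Median-of-bootstrap Spearman correlation between queries and stages.

    For every iteration one gene subset of size `genes_per_iteration` is
    drawn and applied to all query x stage pairs; per-pair correlations are
    median-aggregated over iterations. The trace is the per-query argmax
    stage, ties broken toward the earlier stage in the reference order.
    Fully reproducible given `params.seed`.
    """
    if params is None:
        params = StagingParams()
    usable = usable_gene_list(query, reference, params.expr_cutoff)
    k = params.genes_per_iteration
    if len(usable) < k:
        raise ValueError(
            f"{len(usable)} usable genes < genes_per_iteration={k} "
            f"(shared with reference and log2 expression > {params.expr_cutoff})"
        )
    Q = query.values.loc[usable].to_numpy()
    R = reference.values.loc[usable].to_numpy()
    n = len(usable)

    if params.sampling == "exhaustive":
        total = comb(n, k)
        if total > 200_000:
            raise ValueError(
                f"exhaustive mode would enumerate C({n},{k})={total} subsets"
            )
        subsets = (np.array(c) for c in combinations(range(n), k))
        n_iter = total
    else:
        rng = np.random.default_rng(params.seed)
        replace = params.sampling == "with_replacement"
        subsets = (
            rng.choice(n, size=k, replace=replace) for _ in range(params.n_iterations)
        )
        n_iter = params.n_iterations

    rhos = np.empty((query.shape[1], reference.values.shape[1], n_iter))
    for it, idx in enumerate(subsets):
        rhos[:, :, it] = _rank_corr_matrix(Q[idx], R[idx])

    median = np.median(rhos, axis=2)
    median_rho = pd.DataFrame(
        median, index=query.sample_ids, columns=reference.stages
    )
    # np.argmax takes the first maximum -> earlier stage in reference order
    trace = pd.Series(
        [reference.stages[int(i)] for i in np.argmax(median, axis=1)],
        index=query.sample_ids,
        name="trace",
    )
    return StagingResult(
        median_rho=median_rho,
        trace=trace,
        usable_genes=usable,
        iteration_rhos=rhos if keep_iterations else None,
    )


def trace_heatmap(result: StagingResult, query_order: list[str]) -> pd.DataFrame:
    """The median-correlation matrix ordered for plotting, with the trace flagged.

    Returns a table with one row per (query, stage) cell: columns ``query``,
    ``stage``, ``median_rho`` and ``is_trace`` (the per-row argmax cell).
    """
    unknown = [q for q in query_order if q not in result.median_rho.index]
    if unknown:
        raise KeyError(f"unknown queries: {unknown[:5]}")
    rows = []
    for q in query_order:
        for s in result.median_rho.columns:
            rows.append(
                {
                    "query": q,
                    "stage": s,
                    "median_rho": float(result.median_rho.at[q, s]),
                    "is_trace": bool(result.trace[q] == s),
                }
            )
    return pd.DataFrame(rows)


class BootstrapStager(BaseEstimator):
    """Estimator facade over the bootstrap staging statistic.

    fit() stores the stage reference; transform() returns the query x stage
    median-correlation matrix; predict() returns the traced stage labels.
    """

    def __init__(self, n_iterations: int = 100, genes_per_iteration: int = 50,
                 expr_cutoff: float = 1.0, seed: int = 0,
                 sampling: str = "without_replacement"):
        self.n_iterations = n_iterations
        self.genes_per_iteration = genes_per_iteration
        self.expr_cutoff = expr_cutoff
        self.seed = seed
        self.sampling = sampling

    def _params(self) -> StagingParams:
        return StagingParams(
            n_iterations=self.n_iterations,
            genes_per_iteration=self.genes_per_iteration,
            expr_cutoff=self.expr_cutoff,
            seed=self.seed,
            sampling=self.sampling,
        )

    def fit(self, X: StageReference, y=None) -> "BootstrapStager":
        self.reference_ = X
        return self

    def stage(self, query: ExpressionMatrix, keep_iterations: bool = False) -> StagingResult:
        self.result_ = bootstrap_stage_correlation(
            query, self.reference_, self._params(), keep_iterations
        )
        return self.result_

    def transform(self, query: ExpressionMatrix) -> pd.DataFrame:
        return self.stage(query).median_rho

    def predict(self, query: ExpressionMatrix) -> pd.Series:
        return self.stage(query).trace
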