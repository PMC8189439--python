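"""Variable-gene selection.

Two routes are provided: the CV²-versus-mean trend (a non-linear fit of
squared coefficient of variation against mean expression, with axis
thresholds picking genes that are both expressed and overdispersed), and a
simple top-N ranking by log-scale variance with an expression floor.

Means on the log2 axis are computed on the stored log-scale values; CV² is
computed on de-logged (linear) values, where CV² = variance / mean².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix, GeneSet, LOG_SCALES, ScaleWarning

logger = logging.getLogger("embryostage")


@dataclass
class Cv2TrendFit:
    """Fitted CV²-vs-mean trend with per-gene statistics.

    `stats` has one row per fitted gene: ``mean_log2`` (mean of stored
    log-scale values), ``cv2`` and ``log_cv2`` (on de-logged values),
    ``fitted_cv2`` (trend value at the gene's linear mean), and
    ``excess_ratio`` = cv2 / fitted_cv2.
    """

    model: str
    coefficients: np.ndarray
    stats: pd.DataFrame
    source_genes: tuple[str, ...]


def _per_gene_stats(m: ExpressionMatrix) -> pd.DataFrame:
    linear = m.delogged()
    mean_lin = linear.mean(axis=1)
    var_lin = linear.var(axis=1, ddof=1)
    mean_log = m.values.to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mean_lin > 0, var_lin / np.maximum(mean_lin, 1e-300) ** 2, np.nan)
    return pd.DataFrame(
        {"mean_log2": mean_log, "mean_linear": mean_lin, "cv2": cv2},
        index=m.values.index,
    )


def fit_cv2_trend(m: ExpressionMatrix, model: str = "inverse_mean") -> Cv2TrendFit:
    """Fit the CV²-vs-mean trend across genes.

    model="inverse_mean" fits CV² = a0 + a1/mean by least squares on the
    de-logged per-gene means (the standard technical-noise form, in which a
    Poisson-limited gene has a1 ≈ 1, a0 ≈ 0). model="loess_like" fits a
    lowess curve of log10 CV² against mean log2 expression. Genes with zero
    linear mean cannot carry a CV² and are excluded with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 columns to estimate CV²")
    if m.scale not in LOG_SCALES:
        warnings.warn(
            f"CV² trend expects log-scale input, got {m.scale!r}", ScaleWarning, stacklevel=2
        )
    stats = _per_gene_stats(m)
    bad = ~np.isfinite(stats["cv2"]) | (stats["mean_linear"] <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} genes with zero mean excluded from CV² fit", stacklevel=2
        )
    fit_stats = stats.loc[~bad].copy()
    mean_lin = fit_stats["mean_linear"].to_numpy()
    cv2 = fit_stats["cv2"].to_numpy()

    if model == "inverse_mean":
        X = np.column_stack([np.ones_like(mean_lin), 1.0 / mean_lin])
        coef, *_ = np.linalg.lstsq(X, cv2, rcond=None)
        fitted = X @ coef
    elif model == "loess_like":
        order = np.argsort(fit_stats["mean_log2"].to_numpy(), kind="stable")
        x = fit_stats["mean_log2"].to_numpy()
        with np.errstate(divide="ignore"):
            y = np.log10(np.maximum(cv2, 1e-300))
        sm = lowess(y[order], x[order], frac=0.3, return_sorted=False)
        fitted = np.empty_like(sm)
        fitted[order] = 10.0 ** sm
        coef = np.array([])
    else:
        raise ValueError(f"unknown trend model {model!r}")

    fitted = np.maximum(fitted, 1e-300)
    fit_stats["fitted_cv2"] = fitted
    fit_stats["excess_ratio"] = fit_stats["cv2"] / fitted
    with np.errstate(divide="ignore"):
        fit_stats["log_cv2"] = np.log10(np.maximum(fit_stats["cv2"].to_numpy(), 1e-300))
    return Cv2TrendFit(model, np.asarray(coef), fit_stats, tuple(m.gene_ids))


def select_hvg(fit: Cv2TrendFit, x_threshold: float, y_threshold: float,
               name: str = "hvg_cv2") -> GeneSet:
    """Select genes above both axis thresholds and above the fitted trend.

    x axis: mean log2 expression; y axis: log10 CV². Returns an (unsigned)
    GeneSet; an empty selection raises no error but warns.
    """
    s = fit.stats
    keep = (
        (s["mean_log2"] > x_threshold)
        & (s["log_cv2"] > y_threshold)
        & (s["cv2"] > s["fitted_cv2"])
    )
    genes = tuple(sorted(s.index[keep]))
    if not genes:
        warnings.warn("HVG thresholds excluded all genes", stacklevel=2)
    return GeneSet(
        name, genes, "unsigned",
        f"cv2 trend ({fit.model}); x>{x_threshold}, y>{y_threshold}",
    )


def select_top_variable(m: ExpressionMatrix, n: int, min_expr: float = 1.0,
                        name: str = "hvg_topn") -> GeneSet:
    """Top-`n` genes by log-scale variance, after an expression floor.

    The floor keeps genes with value >= `min_expr` in at least one column.
    Ranking is by variance (descending) with a deterministic lexicographic
    tie-break on gene identifier; if fewer than `n` genes survive the floor,
    all survivors are returned with a warning.
    """
    vals = m.values
    floor_keep = (vals.to_numpy() >= min_expr).any(axis=1)
    sub = vals.loc[floor_keep]
    if sub.shape[0] == 0:
        raise ValueError("expression floor removed every gene")
    var = sub.var(axis=1, ddof=1)
    # deterministic tie-break: pre-sort by gene id, then stable-sort by variance
    ranked = var.loc[sorted(var.index)].sort_values(ascending=False, kind="stable")
    if n > len(ranked):
        warnings.warn(
            f"requested {n} variable genes but only {len(ranked)} pass the floor",
            stacklevel=2,
        )
        n = len(ranked)
    genes = tuple(ranked.index[:n])
    return GeneSet(name, genes, "unsigned", f"top {n} by log-scale variance, floor {min_expr}")


class Cv2TrendHVG(BaseEstimator):
    """Highly-variable-gene selector based on the CV²-vs-mean trend.

    Parameters
    ----------
    model : {"inverse_mean", "loess_like"}
        Trend family fitted across genes.
    x_threshold, y_threshold : float
        Axis thresholds on mean log2 expression and log10 CV². The defaults
        are explicit configuration values, not derived quantities.

    Attributes
    ----------
    stats_ : pandas.DataFrame
        Per-gene mean, CV², fitted trend and excess ratio.
    coefficients_ : numpy.ndarray
        Trend coefficients (a0, a1) for the inverse-mean model.
    gene_set_ : GeneSet
        Selected highly variable genes.
    """

    def __init__(self, model: str = "inverse_mean", x_threshold: float = 0.5,
                 y_threshold: float = 0.3):
        self.model = model
        self.x_threshold = x_threshold
        self.y_threshold = y_threshold

    def fit(self, X: ExpressionMatrix, y=None) -> "Cv2TrendHVG":
        fit = fit_cv2_trend(X, self.model)
        self.trend_ = fit
        self.stats_ = fit.stats
        self.coefficients_ = fit.coefficients
        self.gene_set_ = select_hvg(fit, self.x_threshold, self.y_threshold)
        return self

    def transform(self, X: ExpressionMatrix) -> ExpressionMatrix:
        """Subset a matrix to the selected genes."""
        present = [g for g in self.gene_set_.genes if g in set(X.gene_ids)]
        return X.subset_genes(present)
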