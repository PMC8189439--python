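"""Lineage gene signatures from differential-expression tables, and
signature scoring of cells against expression-matched control genes.

A DE table is a DataFrame with columns ``gene_id``, ``log2fc`` (positive =
up in group A), ``padj`` in (0, 1], and ``base_mean``. The pipeline accepts
externally produced tables in this schema; :func:`simple_de` is a clearly
labelled built-in stand-in (Welch t-test + Benjamini-Hochberg on log-scale
values), not a negative-binomial model.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, GeneSet

logger = logging.getLogger("embryostage")

#: padj floor applied before log10 to avoid infinities.
PADJ_FLOOR = 1e-300


def threshold_signature(
    de: pd.DataFrame, log2fc_min: float, direction: str = "up", name: str | None = None
) -> GeneSet:
    """Genes beyond a fold-change threshold in one direction.

    direction="up" keeps log2fc strictly greater than `log2fc_min`;
    direction="down" keeps log2fc strictly less than −`log2fc_min`.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if direction == "up":
        keep = de["log2fc"] > log2fc_min
    else:
        keep = de["log2fc"] < -log2fc_min
    genes = tuple(de.loc[keep, "gene_id"])
    if name is None:
        name = f"log2fc_{direction}"
    return GeneSet(
        name, genes, direction,
        f"threshold signature: |log2fc| > {log2fc_min}, direction {direction}",
    )


def rank_score(de: pd.DataFrame, fc_scale: str = "log2") -> pd.Series:
    """Per-gene ranking score: (−log10 padj) × fold-change.

    The fold-change factor is the signed log2FC by default ("log2"); with
    fc_scale="linear" the signed linear ratio 2**log2fc × sign is used.
    """
    padj = np.maximum(de["padj"].to_numpy(float), PADJ_FLOOR)
    fc = de["log2fc"].to_numpy(float)
    if fc_scale == "linear":
        fc = np.sign(fc) * np.exp2(np.abs(fc))
    elif fc_scale != "log2":
        raise ValueError("fc_scale must be 'log2' or 'linear'")
    return pd.Series(-np.log10(padj) * fc, index=pd.Index(de["gene_id"], name="gene_id"))


def rank_genes(
    de: pd.DataFrame, n_top: int = 200, fc_scale: str = "log2"
) -> tuple[GeneSet, GeneSet]:
    """Top up- and down-ranked gene sets by the −log10(padj) × FC product.

    The up set is the `n_top` largest positive scores, the down set the
    `n_top` most negative; ties break lexicographically on gene id. If fewer
    than `n_top` genes qualify on a side, the shorter set is returned with a
    warning.
    """
    scores = rank_score(de, fc_scale)
    # deterministic: order by id first, then stable-sort by score
    scores = scores.loc[sorted(scores.index)]
    up_pool = scores[scores > 0].sort_values(ascending=False, kind="stable")
    down_pool = scores[scores < 0].sort_values(ascending=True, kind="stable")
    if len(up_pool) < n_top or len(down_pool) < n_top:
        warnings.warn(
            f"only {len(up_pool)} up / {len(down_pool)} down genes qualify "
            f"for n_top={n_top}", stacklevel=2,
        )
    up = GeneSet("rank_up", tuple(up_pool.index[:n_top]), "up",
                 f"top {n_top} by -log10(padj) x FC ({fc_scale})")
    down = GeneSet("rank_down", tuple(down_pool.index[:n_top]), "down",
                   f"top {n_top} most negative -log10(padj) x FC ({fc_scale})")
    return up, down


def simple_de(
    m: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Built-in two-group differential test (stand-in for an external DE tool).

    Per gene: Welch's unequal-variance t-test on log-scale values, BH
    adjustment across genes; log2fc = mean(A) − mean(B) on the stored log
    scale. Genes with zero variance in both groups get padj = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    A = m.values.loc[:, group_a].to_numpy()
    B = m.values.loc[:, group_b].to_numpy()
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(A, B, axis=1, equal_var=False)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    pvals = np.where(np.isnan(pvals) | degenerate, 1.0, pvals)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    padj = np.clip(padj, PADJ_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "log2fc": log2fc,
            "padj": padj,
            "base_mean": m.values.to_numpy().mean(axis=1),
        }
    )


class ModuleScorer(BaseEstimator):
    """Signature module score with expression-binned control genes.

    Genes are binned into `n_bins` equal-frequency bins of average
    expression across cells; each signature gene contributes
    `n_ctrl_per_gene` control genes drawn with replacement (seeded) from its
    bin. A cell's score is the mean expression of the signature genes minus
    the mean over the sampled control multiset, so a set with no coherent
    enrichment scores near zero regardless of its average expression level.

    Attributes
    ----------
    bins_ : pandas.Series
        Bin index per gene (fitted on average expression).
    mean_expression_ : pandas.Series
        Per-gene average expression used for binning.
    """

    def __init__(self, n_bins: int = 25, n_ctrl_per_gene: int = 100, seed: int = 0):
        self.n_bins = n_bins
        self.n_ctrl_per_gene = n_ctrl_per_gene
        self.seed = seed

    def fit(self, X: ExpressionMatrix, y=None) -> "ModuleScorer":
        if self.n_bins < 1 or self.n_ctrl_per_gene < 1:
            raise ValueError("n_bins and n_ctrl_per_gene must be >= 1")
        if X.shape[0] < self.n_bins:
            raise ValueError(
                f"matrix has {X.shape[0]} genes; need at least n_bins={self.n_bins}"
            )
        avg = X.values.mean(axis=1)
        # rank with deterministic tie resolution, then equal-frequency bins
        ranks = avg.rank(method="first")
        self.bins_ = pd.qcut(ranks, self.n_bins, labels=False)
        self.mean_expression_ = avg
        self._matrix = X
        self._vals = X.values.to_numpy()
        self._pos = {g: i for i, g in enumerate(X.gene_ids)}
        bins_np = self.bins_.to_numpy()
        self._bin_members = {
            b: np.flatnonzero(bins_np == b) for b in np.unique(bins_np)
        }
        return self

    def score_set(self, gene_set: GeneSet) -> pd.Series:
        """Per-cell module score for one gene set (missing genes dropped with warning)."""
        X = self._matrix
        universe = set(X.gene_ids)
        present = [g for g in gene_set.genes if g in universe]
        dropped = len(gene_set.genes) - len(present)
        if dropped:
            warnings.warn(
                f"{dropped} signature genes absent from the matrix were dropped",
                stacklevel=2,
            )
        if not present:
            raise ValueError(f"no genes of set {gene_set.name!r} are in the matrix")
        rng = np.random.default_rng(self.seed)
        vals = self._vals
        sig_pos = np.array([self._pos[g] for g in present])
        sig_mean = vals[sig_pos].mean(axis=0)

        ctrl_sum = np.zeros(vals.shape[1])
        n_ctrl = 0
        for g in present:
            pool = self._bin_members[int(self.bins_[g])]
            draw = rng.choice(pool, size=self.n_ctrl_per_gene, replace=True)
            ctrl_sum += vals[draw].sum(axis=0)
            n_ctrl += self.n_ctrl_per_gene
        ctrl_mean = ctrl_sum / n_ctrl
        return pd.Series(sig_mean - ctrl_mean, index=self._matrix.sample_ids,
                         name=gene_set.name)

    def transform(self, gene_sets: list[GeneSet]) -> pd.DataFrame:
        """Cell x set score table for several signatures (one seeded stream each)."""
        return pd.DataFrame({s.name: self.score_set(s) for s in gene_sets})


def module_score(
    cells: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 25,
    n_ctrl_per_gene: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Functional wrapper over :class:`ModuleScorer` for a single gene set."""
    scorer = ModuleScorer(n_bins=n_bins, n_ctrl_per_gene=n_ctrl_per_gene, seed=seed)
    return scorer.fit(cells).score_set(gene_set)
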