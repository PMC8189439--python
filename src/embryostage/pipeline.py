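"""End-to-end pipelines chaining the analysis stages, with a synthetic demo.

Two headline analyses are wired:

* bulk: expressed-gene filter → PCA with gene-set loading densities →
  bootstrap Spearman staging against the stage reference → temporal fuzzy
  c-means clustering of the trophectoderm branch → lineage-ratio table;
* cells: droplet QC → log-normalization → variable genes → signature module
  scores → per-cell argmax assignment.

Stages communicate via files in the output directory; every artifact is
declared in a manifest with a content hash, so a re-run with an unchanged
configuration reproduces the hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as esio
from .clustering import cluster_lineage_ratio, fuzzy_cmeans, zscore_rows
from .embedding import loading_density, run_pca
from .hvg import select_top_variable
from .matrix import ExpressionMatrix, GeneSet
from .qc import QcThresholds, average_by_group, filter_cells, filter_expressed_genes, normalize_lognorm
from .signatures import ModuleScorer
from .simulate import (
    BRANCH_TERMINI,
    NAIVE_STAGE,
    SimParams,
    TE_STAGES,
    make_cell_counts,
    make_reference,
    make_timecourse,
)
from .staging import StagingParams, bootstrap_stage_correlation, trace_heatmap

logger = logging.getLogger("embryostage")


@dataclass
class RunConfig:
    """Run configuration: input paths (or synthetic generation), parameters, seed.

    Leave `expression_path`/`reference_path` (bulk) or `counts_dir` (cells)
    unset to generate synthetic inputs from `sim`. One global seed is
    propagated with fixed per-module offsets.
    """

    outdir: str = "results"
    seed: int = 0
    expression_path: str | None = None
    metadata_path: str | None = None
    reference_path: str | None = None
    gene_sets_path: str | None = None
    counts_dir: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    staging: StagingParams = field(default_factory=StagingParams)
    sim: SimParams = field(default_factory=SimParams)
    n_clusters: int = 4
    fuzzifier_m: float | None = 1.25
    n_hvg: int = 500
    score_bins: int = 25
    score_ctrl: int = 100
    assign_margin: float = 0.0
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = esio.load_config(path)
        kwargs = dict(raw)
        for key, factory in (("qc", QcThresholds), ("staging", StagingParams),
                             ("sim", SimParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = factory(**kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("expression_path", "metadata_path", "reference_path",
                     "gene_sets_path", "counts_dir"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: dict[str, str] = {}

    def add(self, path: Path) -> None:
        self.entries[str(path.relative_to(self.outdir))] = _sha256(path)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(dict(sorted(self.entries.items())), indent=2) + "\n")
        return path


def _write_tsv(df: pd.DataFrame, path: Path, manifest: _Manifest, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
    manifest.add(path)


def run_bulk_pipeline(config: RunConfig) -> dict:
    """Bulk time-course analysis: filter → PCA+density → staging → clustering.

    Returns a summary report dict; all artifacts are written under
    `config.outdir` and listed in manifest.json.
    """
    t0 = time.time()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)

    sim = SimParams(**{**asdict(config.sim), "seed": config.seed})
    if config.expression_path is None:
        logger.info("bulk: generating synthetic reference and time course")
        ref, truth = make_reference(sim)
        tc, meta, truth = make_timecourse(ref, truth, sim)
        gene_sets = [truth.marker_genes[s] for s in ref.stages]
        esio.write_stage_reference(ref, outdir / "reference.tsv")
        manifest.add(outdir / "reference.tsv")
        esio.write_expression_table(tc, outdir / "timecourse.tsv")
        manifest.add(outdir / "timecourse.tsv")
        _write_tsv(meta, outdir / "metadata.tsv", manifest, index=False)
    else:
        tc = esio.read_expression_table(config.expression_path)
        meta = pd.read_csv(config.metadata_path, sep="\t")
        ref = esio.read_stage_reference(config.reference_path)
        gene_sets = esio.read_gene_sets(config.gene_sets_path)
        truth = None

    # 1. expressed-gene filter (log2 expression > 0 in at least one sample)
    expressed = filter_expressed_genes(tc, cutoff=0.0, min_samples=1)

    # 2. PCA with loading densities for each gene set
    emb = run_pca(expressed, n_components=min(10, expressed.shape[1] - 1))
    _write_tsv(emb.sample_scores, outdir / "pca_scores.tsv", manifest)
    _write_tsv(emb.gene_loadings.iloc[:, :2], outdir / "pca_loadings.tsv", manifest)
    density_peaks = {}
    for gs in gene_sets:
        try:
            grid = loading_density(emb, gs, gridsize=(96, 96))
        except ValueError:
            continue
        peak = np.unravel_index(np.argmax(grid.density), grid.density.shape)
        density_peaks[gs.name] = {
            "x": float(grid.x[peak[0]]), "y": float(grid.y[peak[1]]),
            "mass": grid.mass(),
        }
        _write_tsv(
            pd.DataFrame(grid.density, index=grid.x, columns=grid.y),
            outdir / f"density_{gs.name}.tsv", manifest,
        )

    # 3. bootstrap Spearman staging
    staging = StagingParams(**{**asdict(config.staging), "seed": config.seed + 10})
    result = bootstrap_stage_correlation(tc, ref, staging)
    order = list(meta.sort_values(["condition", "day", "sample_id"])["sample_id"])
    trace_tbl = trace_heatmap(result, order)
    _write_tsv(result.median_rho, outdir / "staging_median_rho.tsv", manifest)
    _write_tsv(trace_tbl, outdir / "staging_trace.tsv", manifest, index=False)

    # 4. temporal clustering of the TE branch (replicate-averaged, z-scored)
    te_samples = meta.loc[meta["condition"] == "TE"].sort_values(["day", "sample_id"])
    te_matrix = ExpressionMatrix(tc.values[list(te_samples["sample_id"])], tc.scale)
    by_day = average_by_group(
        te_matrix,
        dict(zip(te_samples["sample_id"], "d" + te_samples["day"].astype(str))),
        order=sorted(set("d" + te_samples["day"].astype(str)), key=lambda s: int(s[1:])),
    )
    dynamic = select_top_variable(
        ExpressionMatrix(by_day.values, by_day.scale), n=config.n_hvg, min_expr=0.0
    )
    z = zscore_rows(ExpressionMatrix(by_day.values.loc[list(dynamic.genes)], by_day.scale))
    model = fuzzy_cmeans(z, c=config.n_clusters, fuzzifier_m=config.fuzzifier_m,
                         seed=config.seed + 20)
    _write_tsv(model.memberships, outdir / "cluster_memberships.tsv", manifest)
    _write_tsv(model.centers, outdir / "cluster_centers.tsv", manifest)
    _write_tsv(model.hard_labels.to_frame(), outdir / "cluster_labels.tsv", manifest)

    # 5. lineage attribution by ratio of modulated genes
    report: dict = {}
    if truth is not None:
        contrasts = {
            "eTE_vs_ICM": (truth.marker_genes["eTE"], truth.marker_genes["ICM"]),
            "lTE_vs_EPI": (truth.marker_genes["lTE"], truth.marker_genes[NAIVE_STAGE]),
        }
        ratios = cluster_lineage_ratio(model, contrasts)
        _write_tsv(ratios, outdir / "lineage_ratios.tsv", manifest)

        final_day = max(sim.days)
        te_final = [s for s in tc.sample_ids if s.startswith(f"TE_d{final_day}_")]
        report["te_final_traces"] = {s: result.trace[s] for s in te_final}
        report["te_final_trace_in_te"] = all(
            result.trace[s] in TE_STAGES for s in te_final
        )

    if config.make_figures:
        _staging_figure(result, order, outdir / "staging_heatmap.png", manifest)

    report.update(
        {
            "n_genes_expressed": expressed.shape[0],
            "n_samples": tc.shape[1],
            "explained_variance_pc1": float(emb.explained_variance[0]),
            "density_peaks": density_peaks,
            "cluster_sizes": {k: int(v) for k, v in model.cluster_sizes().items()},
        }
    )
    (outdir / "bulk_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest.add(outdir / "bulk_report.json")
    manifest.write()
    report["runtime_s"] = round(time.time() - t0, 2)
    return report


def _staging_figure(result, order, path: Path, manifest: _Manifest) -> None:
    mat = result.median_rho.loc[order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(order))))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
    for i, q in enumerate(mat.index):
        j = list(mat.columns).index(result.trace[q])
        ax.plot(j, i, "r.", markersize=8)
    fig.colorbar(im, ax=ax, label="median bootstrap Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    manifest.add(path)


def run_cell_pipeline(config: RunConfig) -> dict:
    """Single-cell analysis: QC → normalize → HVG → module scores → assignment."""
    t0 = time.time()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)

    if config.counts_dir is None:
        logger.info("cells: generating synthetic droplet counts")
        # droplet simulation needs a gene universe above the detection threshold
        cell_sim = SimParams(
            **{**asdict(config.sim), "seed": config.seed,
               "n_genes": max(config.sim.n_genes, 8000), "markers_per_stage": 100}
        )
        ref, truth = make_reference(cell_sim)
        type_stages = [NAIVE_STAGE, *BRANCH_TERMINI.values()]
        profiles = ExpressionMatrix(ref.values[type_stages], ref.scale)
        counts, cell_truth = make_cell_counts(
            profiles, cell_sim,
            n_fail_low=max(2, cell_sim.n_cells // 10),
            n_fail_mito=max(2, cell_sim.n_cells // 10),
            thresholds=config.qc,
        )
        signature_sets = [truth.marker_genes[s] for s in type_stages]
    else:
        counts = esio.read_sparse_counts(config.counts_dir)
        signature_sets = esio.read_gene_sets(config.gene_sets_path)
        cell_truth = None

    kept, qc_report = filter_cells(counts, config.qc)
    _write_tsv(qc_report, outdir / "cell_qc_report.tsv", manifest)
    report: dict = {
        "n_cells_in": counts.shape[1],
        "n_cells_pass_qc": kept.shape[1],
    }
    if kept.shape[1] == 0:
        logger.warning("no cells passed QC; writing empty score table")
        _write_tsv(pd.DataFrame(), outdir / "cell_scores.tsv", manifest)
        manifest.write()
        report["runtime_s"] = round(time.time() - t0, 2)
        return report

    norm = normalize_lognorm(kept, config.qc.scale_factor)
    hvg = select_top_variable(norm, n=min(2000, norm.shape[0]), min_expr=0.0)
    esio.write_gene_sets([hvg], outdir / "cell_hvg.gmt")
    manifest.add(outdir / "cell_hvg.gmt")

    scorer = ModuleScorer(
        n_bins=config.score_bins, n_ctrl_per_gene=config.score_ctrl,
        seed=config.seed + 30,
    ).fit(norm)
    scores = scorer.transform([s.intersect(norm.gene_ids) for s in signature_sets])
    assign = scores.idxmax(axis=1)
    margin = scores.max(axis=1) - scores.apply(
        lambda r: r.nlargest(2).iloc[-1] if len(r) > 1 else 0.0, axis=1
    )
    assign = assign.where(margin >= config.assign_margin, "unassigned")
    table = scores.assign(assigned=assign)
    _write_tsv(table, outdir / "cell_scores.tsv", manifest)

    if cell_truth is not None:
        truth_types = cell_truth.cell_type_of_barcode.loc[table.index]
        # signature sets are named "<stage>_markers"
        correct = (table["assigned"].str.replace("_markers", "", regex=False)
                   == truth_types)
        report["assignment_accuracy"] = float(correct.mean())
    (outdir / "cell_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest.add(outdir / "cell_report.json")
    manifest.write()
    report["runtime_s"] = round(time.time() - t0, 2)
    return report


def run_demo(outdir: str | Path, seed: int = 7) -> dict:
    """Full synthetic demo: bulk and cell pipelines into one directory tree."""
    outdir = Path(outdir)
    bulk = run_bulk_pipeline(RunConfig(outdir=str(outdir / "bulk"), seed=seed))
    cells = run_cell_pipeline(
        RunConfig(outdir=str(outdir / "cells"), seed=seed,
                  sim=SimParams(n_cells=60, seed=seed))
    )
    summary = {"bulk": bulk, "cells": cells}
    stable = {
        side: {k: v for k, v in rep.items() if k != "runtime_s"}
        for side, rep in summary.items()
    }
    (outdir / "demo_summary.json").write_text(
        json.dumps(stable, indent=2, sort_keys=True) + "\n"
    )
    return summary
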