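"""Synthetic embryo references, differentiation time courses, and droplet
count matrices with known ground truth.

The generator emulates the statistical structure the analyses assume:

* a stage reference with disjoint marker blocks elevated per stage on a
  shared baseline (log2 scale, right-skewed baseline law);
* two-branch bulk time courses that linearly mix the naive profile toward a
  branch terminus (trophectoderm or formative epiblast) with additive
  log-scale Gaussian noise;
* sparse droplet counts with library-size variation, Poisson sampling,
  independent dropout, a mitochondrial fraction, and planted QC-failure
  cells (low complexity or high mitochondrial content).

Planted QC labels are guaranteed: failure modes are constructed to fail
(low-complexity cells draw from fewer features than the detection
threshold; high-mito cells carry a 35% mitochondrial share), and any cell
whose realized statistics nevertheless cross its planted label is redrawn
(bounded rejection), so truth flags match the QC filter exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .matrix import CellCountMatrix, ExpressionMatrix, GeneSet, StageReference
from .qc import QcThresholds, cell_qc_stats

logger = logging.getLogger("embryostage")

#: Default developmental order of the synthetic reference stages.
DEFAULT_STAGES = ("ICM", "eTE", "lTE", "preEPI", "postEPI")
#: Stages counted as trophectoderm for recovery checks.
TE_STAGES = ("eTE", "lTE")
#: Branch termini: each branch mixes the naive profile toward one stage.
BRANCH_TERMINI = {"TE": "lTE", "formative": "postEPI"}
#: The naive starting state corresponds to pre-implantation epiblast.
NAIVE_STAGE = "preEPI"

#: GRCh38 mitochondrial gene symbols used for the synthetic mito block.
MITO_SYMBOLS = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)


@dataclass
class SimParams:
    """Generator configuration (defaults define the packaged study conditions).

    Bulk defaults: 2000 genes, 5 stages x 50 markers elevated by 3 log2
    units over a right-skewed baseline, log-scale noise sd 0.4 — marker
    effects well clear of noise, as stage-specific programs are in embryo
    references. Time course: days 0-5 with linearly increasing branch
    weight and biological duplicates.

    Droplet defaults: mean depth 30,000 with mild lognormal spread, 5%
    dropout, 3% mitochondrial share. The droplet simulator requires a gene
    universe comfortably above the 3000-detected-genes QC threshold; use a
    reference with `n_genes` >= ~8000 for cells.
    """

    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    markers_per_stage: int = 50
    marker_effect: float = 3.0
    noise_sd: float = 0.4
    baseline_shape: float = 3.0
    baseline_scale: float = 1.0
    days: tuple[int, ...] = (0, 1, 2, 3, 5)
    branch_mixing: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    replicates: int = 2
    n_cells: int = 100
    cell_depth_mean: float = 30_000.0
    cell_depth_sd_log: float = 0.15
    dropout_rate: float = 0.05
    mito_mean_fraction: float = 0.03
    fail_mito_fraction: float = 0.35
    fail_low_n_features: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_stage * len(self.stages) > self.n_genes:
            raise ValueError("marker blocks exceed the gene universe")
        if len(self.branch_mixing) != len(self.days):
            raise ValueError("branch_mixing must give one weight per day")
        if any(not 0 <= w <= 1 for w in self.branch_mixing):
            raise ValueError("branch weights must lie in [0, 1]")
        if list(self.branch_mixing) != sorted(self.branch_mixing):
            raise ValueError("branch weights must be monotone along days")


@dataclass
class SimTruth:
    """Ground-truth labels attached to generated entities."""

    stage_of_sample: pd.Series | None = None
    branch_of_sample: pd.Series | None = None
    day_of_sample: pd.Series | None = None
    marker_genes: dict[str, GeneSet] = field(default_factory=dict)
    hvg_genes: GeneSet | None = None
    cluster_shape_of_gene: pd.Series | None = None
    cell_type_of_barcode: pd.Series | None = None
    qc_fail_flags: pd.Series | None = None
    qc_fail_mode: pd.Series | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_reference(p: SimParams | None = None) -> tuple[StageReference, SimTruth]:
    """Stage-averaged reference profiles with disjoint per-stage marker blocks.

    Baseline log2 expression per gene is Gamma-distributed (right-skewed,
    lognormal-like); each stage's markers are elevated by `marker_effect`
    and every gene x stage value receives independent N(0, noise_sd) noise.
    """
    if p is None:
        p = SimParams()
    rng = np.random.default_rng(p.seed)
    genes = _gene_ids(p.n_genes)
    baseline = rng.gamma(p.baseline_shape, p.baseline_scale, size=p.n_genes)
    values = np.tile(baseline[:, None], (1, len(p.stages)))
    truth = SimTruth()
    k = p.markers_per_stage
    for si, stage in enumerate(p.stages):
        idx = np.arange(si * k, (si + 1) * k)
        values[idx, si] += p.marker_effect
        truth.marker_genes[stage] = GeneSet(
            f"{stage}_markers", tuple(genes[i] for i in idx), "up",
            "synthetic planted stage markers",
        )
    values += rng.normal(0.0, p.noise_sd, size=values.shape)
    ref = StageReference(
        pd.DataFrame(values, index=genes, columns=list(p.stages)), "log2fpkm"
    )
    # genes that move along either branch of a time course built on this
    # reference: naive-stage markers (fall) and branch-terminus markers (rise)
    dyn = []
    for stage in (NAIVE_STAGE, *BRANCH_TERMINI.values()):
        if stage in truth.marker_genes:
            dyn.extend(truth.marker_genes[stage].genes)
    truth.hvg_genes = GeneSet("dynamic_markers", tuple(dict.fromkeys(dyn)), "unsigned",
                              "synthetic: markers of naive state and branch termini")
    return ref, truth


def make_timecourse(
    ref: StageReference, truth: SimTruth, p: SimParams | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Two-branch differentiation time course mixed from the reference.

    sample(day d, branch b) = (1−w_d)·naive + w_d·terminus_b + N(0, noise_sd)
    per gene, with `replicates` independent noise draws per (day, branch).
    Returns the matrix, a tidy metadata table, and truth labels.
    """
    if p is None:
        p = SimParams()
    rng = np.random.default_rng(p.seed + 1)
    naive = ref.values[NAIVE_STAGE].to_numpy()
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for branch, terminus in BRANCH_TERMINI.items():
        term = ref.values[terminus].to_numpy()
        for day, w in zip(p.days, p.branch_mixing):
            for rep in range(1, p.replicates + 1):
                name = f"{branch}_d{day}_r{rep}"
                profile = (1 - w) * naive + w * term
                if p.noise_sd > 0:
                    profile = profile + rng.normal(0, p.noise_sd, size=len(naive))
                cols[name] = profile
                meta_rows.append(
                    {"sample_id": name, "condition": branch, "day": day,
                     "stage": "", "replicate": f"r{rep}"}
                )
    values = pd.DataFrame(cols, index=ref.gene_ids)
    meta = pd.DataFrame(meta_rows)
    out_truth = replace(
        truth,
        branch_of_sample=pd.Series(meta["condition"].to_numpy(), index=meta["sample_id"]),
        day_of_sample=pd.Series(meta["day"].to_numpy(), index=meta["sample_id"]),
    )
    return ExpressionMatrix(values, ref.scale), meta, out_truth


def _draw_cell(
    rng: np.random.Generator,
    props: np.ndarray,
    depth_mean: float,
    depth_sd_log: float,
    dropout: float,
) -> np.ndarray:
    depth = rng.lognormal(np.log(depth_mean), depth_sd_log)
    lam = props * depth
    counts = rng.poisson(lam)
    if dropout > 0:
        counts = counts * (rng.random(len(counts)) >= dropout)
    return counts


def make_cell_counts(
    profiles: ExpressionMatrix,
    p: SimParams | None = None,
    n_fail_low: int = 0,
    n_fail_mito: int = 0,
    n_boundary: int = 0,
    thresholds: QcThresholds | None = None,
    max_redraws: int = 50,
) -> tuple[CellCountMatrix, SimTruth]:
    """Droplet-style counts for cells drawn from the given type profiles.

    `profiles` columns are cell types (log2 scale); cell types are assigned
    round-robin. `n_fail_low` and `n_fail_mito` cells are planted to fail
    the QC thresholds (low complexity / high mitochondrial fraction);
    `n_boundary` cells sit exactly on both thresholds (detected genes ==
    min_genes_per_cell and mito fraction == max_mito_fraction) and must be
    kept. Planted pass/fail labels are exact with respect to `thresholds`.
    """
    if p is None:
        p = SimParams()
    if thresholds is None:
        thresholds = QcThresholds()
    rng = np.random.default_rng(p.seed + 2)
    n_types = profiles.shape[1]
    gene_ids = list(profiles.gene_ids) + list(MITO_SYMBOLS)
    n_main = profiles.shape[0]
    n_genes = len(gene_ids)
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[n_main:] = True

    lin = np.exp2(profiles.values.to_numpy())  # linear expression per type
    type_props = lin / lin.sum(axis=0, keepdims=True)

    def props_for(type_idx: int, mito_share: float, restrict: int | None = None) -> np.ndarray:
        base = type_props[:, type_idx].copy()
        if restrict is not None:
            order = np.argsort(base)[::-1]
            keep = np.zeros(n_main, dtype=bool)
            keep[order[:restrict]] = True
            base = np.where(keep, base, 0.0)
            base /= base.sum()
        props = np.empty(n_genes)
        props[:n_main] = base * (1.0 - mito_share)
        props[n_main:] = mito_share * rng.dirichlet(np.ones(len(MITO_SYMBOLS)))
        return props

    n_pass = p.n_cells - n_fail_low - n_fail_mito - n_boundary
    if n_pass < 0:
        raise ValueError("planted failure/boundary cells exceed n_cells")
    plan = (
        [("pass", None)] * n_pass
        + [("fail_low", None)] * n_fail_low
        + [("fail_mito", None)] * n_fail_mito
        + [("boundary", None)] * n_boundary
    )

    columns: list[np.ndarray] = []
    barcodes: list[str] = []
    types: list[str] = []
    fail_flags: list[bool] = []
    modes: list[str] = []
    for ci, (mode, _) in enumerate(plan):
        t = ci % n_types
        tname = profiles.sample_ids[t]
        if mode == "boundary":
            counts = _boundary_cell(thresholds, n_main, n_genes, rng)
        else:
            for attempt in range(max_redraws):
                if mode == "pass":
                    counts = _draw_cell(
                        rng, props_for(t, p.mito_mean_fraction),
                        p.cell_depth_mean, p.cell_depth_sd_log, p.dropout_rate,
                    )
                elif mode == "fail_low":
                    counts = _draw_cell(
                        rng,
                        props_for(t, p.mito_mean_fraction,
                                  restrict=min(p.fail_low_n_features,
                                               thresholds.min_genes_per_cell - 1)),
                        p.cell_depth_mean * 0.5, p.cell_depth_sd_log, p.dropout_rate,
                    )
                else:  # fail_mito
                    counts = _draw_cell(
                        rng, props_for(t, p.fail_mito_fraction),
                        p.cell_depth_mean, p.cell_depth_sd_log, p.dropout_rate,
                    )
                if counts.sum() == 0:
                    continue
                detected = int((counts > 0).sum())
                mito_frac = counts[mito_mask].sum() / counts.sum()
                ok = (detected >= thresholds.min_genes_per_cell
                      and mito_frac <= thresholds.max_mito_fraction)
                if (mode == "pass") == ok:
                    break
            else:
                raise RuntimeError(
                    f"could not realize planted QC label {mode!r} in {max_redraws} draws; "
                    "generator parameters are inconsistent with the thresholds"
                )
        columns.append(counts)
        barcodes.append(f"CELL{ci:04d}")
        types.append(tname)
        fail_flags.append(mode in ("fail_low", "fail_mito"))
        modes.append(mode)

    counts_mat = sparse.csc_matrix(np.column_stack(columns))
    ccm = CellCountMatrix(counts_mat, barcodes, gene_ids, mito_mask)
    bidx = pd.Index(barcodes, name="barcode")
    truth = SimTruth(
        cell_type_of_barcode=pd.Series(types, index=bidx),
        qc_fail_flags=pd.Series(fail_flags, index=bidx),
        qc_fail_mode=pd.Series(modes, index=bidx),
    )
    # construction guarantee: realized QC status must match planted labels
    stats = cell_qc_stats(ccm)
    realized_fail = (
        (stats["n_genes"] < thresholds.min_genes_per_cell)
        | (stats["mito_fraction"] > thresholds.max_mito_fraction)
    )
    if not realized_fail.equals(truth.qc_fail_flags.astype(bool)):
        raise RuntimeError("planted QC labels failed to realize (internal error)")
    return ccm, truth


def _boundary_cell(
    thresholds: QcThresholds, n_main: int, n_genes: int, rng: np.random.Generator
) -> np.ndarray:
    """A cell with exactly `min_genes_per_cell` detected genes and exactly
    `max_mito_fraction` of counts on mitochondrial genes (kept by QC)."""
    n_mito = n_genes - n_main
    g = thresholds.min_genes_per_cell
    n_nonmito_detected = g - n_mito
    if n_nonmito_detected > n_main:
        raise ValueError("gene universe too small for a boundary cell")
    frac = thresholds.max_mito_fraction
    # choose integer totals S (non-mito) and M (mito) with M/(S+M) == frac exactly
    num = int(round(frac * 1_000_000))
    den = 1_000_000
    from math import gcd

    gdiv = gcd(num, den)
    num //= gdiv
    den //= gdiv
    # M = num*t, total = den*t, S = (den-num)*t; need S >= detected non-mito genes
    t = 1
    while (den - num) * t < n_nonmito_detected or num * t < n_mito:
        t += 1
    M = num * t
    S = (den - num) * t
    counts = np.zeros(n_genes, dtype=int)
    chosen = rng.choice(n_main, size=n_nonmito_detected, replace=False)
    counts[chosen] = 1
    extra = S - n_nonmito_detected
    counts[chosen[0]] += extra  # pile remainder on one detected gene
    base, rem = divmod(M, n_mito)
    counts[n_main:] = base
    counts[n_main : n_main + rem] += 1
    realized = counts[n_main:].sum() / counts.sum()
    assert (counts > 0).sum() == g and realized <= frac and frac - realized < 1e-6
    return counts
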