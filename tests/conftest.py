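import numpy as np
import pandas as pd
import pytest

from embryostage.matrix import CellCountMatrix, ExpressionMatrix, StageReference
from embryostage.simulate import SimParams, make_cell_counts, make_reference, make_timecourse


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, log2 scale, handy for arithmetic checks."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0], [2.0, 2.0, 2.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values, "log2fpkm")


@pytest.fixture(scope="session")
def sim_bundle():
    """Default synthetic reference + two-branch time course (seed 0)."""
    p = SimParams(seed=0)
    ref, truth = make_reference(p)
    tc, meta, truth = make_timecourse(ref, truth, p)
    return p, ref, tc, meta, truth


@pytest.fixture(scope="session")
def cell_bundle():
    """Synthetic droplet counts: 100 cells, 40 planted QC failures, 2 boundary cells."""
    p = SimParams(seed=11, n_genes=8000, markers_per_stage=100, n_cells=100)
    ref, truth = make_reference(p)
    profiles = ExpressionMatrix(ref.values[["preEPI", "lTE", "postEPI"]], ref.scale)
    counts, cell_truth = make_cell_counts(
        profiles, p, n_fail_low=20, n_fail_mito=18, n_boundary=2
    )
    return p, ref, truth, counts, cell_truth


def toy_reference(n_genes: int = 40, seed: int = 5) -> StageReference:
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(
        rng.normal(3, 1, size=(n_genes, 3)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=["stageA", "stageB", "stageC"],
    )
    return StageReference(vals, "log2fpkm")
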