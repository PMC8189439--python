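import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from embryostage.matrix import ExpressionMatrix, StageReference
from embryostage.staging import (
    BootstrapStager,
    StagingParams,
    bootstrap_stage_correlation,
    spearman_rho,
    trace_heatmap,
    usable_gene_list,
)
from tests.conftest import toy_reference


class TestSpearmanRho:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == 1.0

    def test_anti_monotone_is_minus_one(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == -1.0

    def test_tie_case_matches_hand_mid_rank_value(self):
        # ranks x: [1, 2.5, 2.5, 4], y: [1, 3, 2, 4] -> rho = 4.5/sqrt(4.5*5)
        rho = spearman_rho([1, 2, 2, 3], [1, 3, 2, 4])
        assert rho == pytest.approx(np.sqrt(0.9), abs=1e-12)

    def test_agrees_with_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 5, 20).astype(float)  # ties likely
            y = rng.normal(0, 1, 20)
            assert spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, abs=1e-12
            )

    def test_constant_input_defined_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert spearman_rho([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            spearman_rho([1, 2], [1, 2, 3])


def _query_from_reference(ref, columns, names, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vals = ref.values[columns].to_numpy().astype(float)
    if noise:
        vals = vals + rng.normal(0, noise, vals.shape)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=ref.gene_ids, columns=names), "log2fpkm"
    )


class TestBootstrapStageCorrelation:
    def test_degenerate_full_subset_equals_single_spearman(self):
        ref = toy_reference(20)
        query = _query_from_reference(ref, ["stageB"], ["q"], noise=0.5, seed=1)
        usable = usable_gene_list(query, ref, 1.0)
        params = StagingParams(
            n_iterations=5, genes_per_iteration=len(usable), expr_cutoff=1.0
        )
        res = bootstrap_stage_correlation(query, ref, params, keep_iterations=True)
        full = spearman_rho(
            query.values.loc[usable, "q"], ref.values.loc[usable, "stageA"]
        )
        assert res.median_rho.at["q", "stageA"] == pytest.approx(full, abs=1e-12)
        # every iteration identical
        assert np.ptp(res.iteration_rhos, axis=2).max() == pytest.approx(0.0)

    def test_duplicated_stage_traces_to_itself(self):
        ref = toy_reference(60)
        query = _query_from_reference(ref, ["stageC"], ["dup"])
        params = StagingParams(n_iterations=20, genes_per_iteration=10, seed=3)
        res = bootstrap_stage_correlation(query, ref, params)
        assert res.median_rho.at["dup", "stageC"] == pytest.approx(1.0)
        assert res.trace["dup"] == "stageC"

    def test_exhaustive_matches_brute_force_oracle(self):
        """6 usable genes, k=3: the module's exhaustive mode equals an
        independent enumeration over all C(6,3)=20 subsets with scipy."""
        from itertools import combinations

        ref = toy_reference(6, seed=8)
        query = _query_from_reference(ref, ["stageA", "stageB"], ["q1", "q2"],
                                      noise=1.0, seed=9)
        params = StagingParams(n_iterations=1, genes_per_iteration=3,
                               expr_cutoff=-np.inf, sampling="exhaustive")
        res = bootstrap_stage_correlation(query, ref, params)
        for q in ["q1", "q2"]:
            for s in ref.stages:
                rhos = [
                    sps.spearmanr(
                        query.values.iloc[list(c)][q],
                        ref.values.iloc[list(c)][s],
                    ).statistic
                    for c in combinations(range(6), 3)
                ]
                assert res.median_rho.at[q, s] == pytest.approx(
                    np.median(rhos), abs=1e-12
                )

    def test_sampled_mode_close_to_exhaustive(self):
        # query rank-similar to stageA so each pair's subset-rho distribution
        # has a clear majority atom and the sample median is stable
        ref = toy_reference(6, seed=0)
        query = _query_from_reference(ref, ["stageA"], ["q"], noise=0.5, seed=0)
        exh = bootstrap_stage_correlation(
            query, ref,
            StagingParams(genes_per_iteration=3, expr_cutoff=-np.inf,
                          sampling="exhaustive"),
        )
        sam = bootstrap_stage_correlation(
            query, ref,
            StagingParams(n_iterations=2000, genes_per_iteration=3,
                          expr_cutoff=-np.inf, seed=17),
        )
        assert np.abs(
            sam.median_rho.to_numpy() - exh.median_rho.to_numpy()
        ).max() <= 0.02

    def test_monotone_transform_invariance(self):
        """Rank statistic: applying exp (monotone) to both sides changes nothing."""
        ref = toy_reference(40)
        query = _query_from_reference(ref, ["stageB"], ["q"], noise=0.7, seed=4)
        params = StagingParams(n_iterations=30, genes_per_iteration=15, seed=5,
                               expr_cutoff=1.0)
        a = bootstrap_stage_correlation(query, ref, params)
        # transform values monotonically but keep the same usable-gene filter
        usable = usable_gene_list(query, ref, params.expr_cutoff)
        q2 = ExpressionMatrix(np.exp(query.values.loc[usable] / 4), "log2fpkm")
        r2 = StageReference(np.exp(ref.values.loc[usable] / 4), "log2fpkm")
        params2 = StagingParams(n_iterations=30, genes_per_iteration=15, seed=5,
                                expr_cutoff=-np.inf)
        b = bootstrap_stage_correlation(q2, r2, params2)
        np.testing.assert_allclose(
            a.median_rho.to_numpy(), b.median_rho.to_numpy(), atol=1e-12
        )

    def test_reproducible_given_seed(self):
        ref = toy_reference(50)
        query = _query_from_reference(ref, ["stageA"], ["q"], noise=0.5, seed=6)
        p = StagingParams(n_iterations=50, genes_per_iteration=10, seed=21)
        a = bootstrap_stage_correlation(query, ref, p)
        b = bootstrap_stage_correlation(query, ref, p)
        pd.testing.assert_frame_equal(a.median_rho, b.median_rho)

    def test_more_iterations_stabilize_median(self):
        """sd of the median across seeds shrinks as iterations grow."""
        ref = toy_reference(80, seed=2)
        query = _query_from_reference(ref, ["stageB"], ["q"], noise=1.0, seed=7)

        def sd_at(B):
            vals = [
                bootstrap_stage_correlation(
                    query, ref,
                    StagingParams(n_iterations=B, genes_per_iteration=10, seed=s),
                ).median_rho.at["q", "stageB"]
                for s in range(20)
            ]
            return np.std(vals)

        assert sd_at(100) > sd_at(1000)

    def test_too_few_usable_genes_reports_count(self):
        ref = toy_reference(10)
        query = _query_from_reference(ref, ["stageA"], ["q"])
        with pytest.raises(ValueError, match="usable genes"):
            bootstrap_stage_correlation(
                query, ref, StagingParams(genes_per_iteration=50)
            )

    def test_cutoff_applied_on_query_side_only(self):
        ref = toy_reference(30, seed=3)
        query = _query_from_reference(ref, ["stageA"], ["q"])
        # push one gene below the cutoff in the query only
        vals = query.values.copy()
        vals.iloc[0] = 0.5
        low = ExpressionMatrix(vals, "log2fpkm")
        usable = usable_gene_list(low, ref, expr_cutoff=1.0)
        assert low.gene_ids[0] not in usable


class TestTraceHeatmap:
    def test_single_cell_is_trace(self):
        ref = toy_reference(30)
        query = _query_from_reference(ref, ["stageA"], ["q"])
        res = bootstrap_stage_correlation(
            query, ref, StagingParams(n_iterations=10, genes_per_iteration=5, seed=1)
        )
        tbl = trace_heatmap(res, ["q"])
        assert tbl.loc[tbl["is_trace"], "stage"].tolist() == [res.trace["q"]]

    def test_tie_breaks_to_earlier_stage(self):
        # duplicated stage columns produce an exact tie in median rho
        ref = toy_reference(40, seed=13)
        vals = ref.values.copy()
        vals["stageB"] = vals["stageA"]  # two identical stages
        tied_ref = StageReference(vals, "log2fpkm")
        query = _query_from_reference(tied_ref, ["stageA"], ["q"])
        res = bootstrap_stage_correlation(
            query, tied_ref,
            StagingParams(n_iterations=10, genes_per_iteration=8, seed=2),
        )
        assert res.trace["q"] == "stageA"  # earlier column wins the tie

    def test_unknown_query_rejected(self):
        ref = toy_reference(30)
        query = _query_from_reference(ref, ["stageA"], ["q"])
        res = bootstrap_stage_correlation(
            query, ref, StagingParams(n_iterations=5, genes_per_iteration=5)
        )
        with pytest.raises(KeyError, match="ghost"):
            trace_heatmap(res, ["ghost"])

    def test_te_branch_trace_moves_toward_te(self, sim_bundle):
        _, ref, tc, meta, _ = sim_bundle
        res = bootstrap_stage_correlation(tc, ref, StagingParams(seed=5))
        for s in tc.sample_ids:
            if s.startswith("TE_d0_"):
                assert res.trace[s] == "preEPI"
            if s.startswith("TE_d5_"):
                assert res.trace[s] in ("eTE", "lTE")


class TestBootstrapStagerEstimator:
    def test_fit_transform_predict(self, sim_bundle):
        _, ref, tc, _, _ = sim_bundle
        stager = BootstrapStager(n_iterations=20, seed=1).fit(ref)
        rho = stager.transform(tc)
        assert rho.shape == (tc.shape[1], len(ref.stages))
        trace = stager.predict(tc)
        assert (trace == rho.idxmax(axis=1)).all()
        assert stager.get_params()["n_iterations"] == 20
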