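import numpy as np
import pandas as pd
import pytest
from scipy import stats

from argenrich.enrichment import (
    EnrichmentRecord,
    call_enrichment,
    count_wt_detected,
    fold_change_vs_input,
    impute_missing,
    log_transform_normalize,
    paired_t_test,
    qc_filter,
    run_enrichment,
)
from argenrich.io_formats import KO, WT

from conftest import make_table


class TestQcFilter:
    @pytest.mark.parametrize(
        "wt,ko,kept",
        [
            (1, 1, False),  # ">1": a count of 1 fails in both genotypes
            (0, 5, True),  # OR semantics: KO alone qualifies
            (2, 0, True),
            (2, 2, True),
            (0, 0, False),
        ],
    )
    def test_threshold_or_semantics(self, design3, wt, ko, kept):
        razor = pd.DataFrame({"WT": [wt], "KO": [ko]}, index=["P0"])
        table = make_table(np.full((1, 8), 10.0), design3, razor=razor)
        out = qc_filter(table)
        assert (out.n_proteins == 1) is kept

    def test_empty_result_allowed(self, design3):
        razor = pd.DataFrame({"WT": [1, 0], "KO": [1, 1]}, index=["P0", "P1"])
        table = make_table(np.full((2, 8), 10.0), design3, razor=razor)
        assert qc_filter(table).n_proteins == 0


class TestNormalize:
    def test_two_value_example(self, design3):
        # intensities (2, 8) in one sample: log2 -> (1, 3), centered (-1, +1)
        values = np.full((2, 8), 4.0)
        values[:, 0] = [2.0, 8.0]
        nt = log_transform_normalize(make_table(values, design3))
        np.testing.assert_allclose(nt.values[:, 0], [-1.0, 1.0])

    def test_all_equal_gives_zeros(self, design3):
        nt = log_transform_normalize(make_table(np.full((3, 8), 7.0), design3))
        np.testing.assert_allclose(nt.values, 0.0)

    def test_missing_excluded_from_mean(self, tiny_design):
        # 3x2-protein fixture, hand-computed column means over present cells
        values = np.full((3, 6), 8.0)
        values[:, 0] = [2.0, 8.0, np.nan]
        values[:, 1] = [4.0, 4.0, 4.0]
        nt = log_transform_normalize(make_table(values, tiny_design))
        # column 0: log2 -> (1, 3, nan), mean over present = 2
        np.testing.assert_allclose(nt.values[:2, 0], [-1.0, 1.0])
        assert np.isnan(nt.values[2, 0])
        # column 1: log2 -> (2, 2, 2), mean 2 -> zeros
        np.testing.assert_allclose(nt.values[:, 1], 0.0)

    def test_column_means_zero(self, design3, sim_small):
        _, (table, _, _, _) = sim_small
        nt = log_transform_normalize(table)
        means = np.nanmean(nt.values, axis=0)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)

    def test_centering_idempotent(self, sim_small):
        _, (table, _, _, _) = sim_small
        nt = log_transform_normalize(table)
        recentered = nt.values - np.nanmean(nt.values, axis=0)
        np.testing.assert_allclose(
            np.where(np.isnan(nt.values), 0, recentered),
            np.where(np.isnan(nt.values), 0, nt.values),
            atol=1e-12,
        )

    def test_nonpositive_rejected(self, design3):
        table = make_table(np.full((2, 8), 5.0), design3)
        table.values[0, 0] = -1.0  # bypass constructor check deliberately
        with pytest.raises(ValueError, match="nonpositive"):
            log_transform_normalize(table)


class TestImpute:
    def test_bounds_from_formula(self, tiny_design):
        # present values {-1, 0, 1} after centering: sd (n-1) = 1,
        # so imputed values land in [-2.5, -2.2]
        values = np.full((4, 6), 4.0)
        values[:3, 0] = [2.0, 4.0, 8.0]  # log2 -> (1, 2, 3), centered (-1, 0, 1)
        values[3, 0] = np.nan
        nt = impute_missing(log_transform_normalize(make_table(values, tiny_design)), seed=0)
        v = nt.values[3, 0]
        assert -2.5 <= v <= -2.2
        assert nt.imputed_mask[3, 0]

    def test_no_missing_identity(self, sim_small):
        from argenrich.synthetic_data import SimConfig, simulate_experiment

        table, *_ = simulate_experiment(SimConfig(n_proteins=30, censor_quantile=0.0, seed=1))
        nt = log_transform_normalize(table)
        for seed in (0, 1, 99):
            out = impute_missing(nt, seed=seed)
            np.testing.assert_array_equal(out.values, nt.values)
            assert not out.imputed_mask.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_every_seed(self, sim_small, seed):
        _, (table, _, _, _) = sim_small
        nt = log_transform_normalize(table)
        out = impute_missing(nt, seed=seed)
        for j in range(out.values.shape[1]):
            present = nt.values[:, j][~np.isnan(nt.values[:, j])]
            sigma = np.std(present, ddof=1)
            imputed = out.values[out.imputed_mask[:, j], j]
            assert np.all(imputed >= -2.5 * sigma - 1e-12)
            assert np.all(imputed <= 0.3 - 2.5 * sigma + 1e-12)

    def test_reproducible(self, sim_small):
        _, (table, _, _, _) = sim_small
        nt = log_transform_normalize(table)
        a = impute_missing(nt, seed=7)
        b = impute_missing(nt, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_too_few_present_named(self, tiny_design):
        values = np.full((2, 6), 4.0)
        values[0, 0] = np.nan
        with pytest.raises(ValueError, match="WT_input"):
            impute_missing(log_transform_normalize(make_table(values, tiny_design)))


class TestFoldChange:
    def _normalized_with_deltas(self, design3, deltas):
        # build the NormalizedTable directly: inputs and KO eluates at 0,
        # WT eluate column c at delta_c, so the per-column lfc IS delta_c
        from argenrich.enrichment import NormalizedTable

        values = np.zeros((1, 8))
        names = design3.sample_names
        for c, d in zip(("c1", "c2", "c3"), deltas):
            values[0, names.index(f"WT_eluate_{c}")] = d
        razor = pd.DataFrame({"WT": [5], "KO": [5]}, index=["P0"])
        return NormalizedTable(
            ["P0"], ["g0"], razor, design3, values, np.zeros_like(values, dtype=bool)
        )

    def test_identical_genotypes_unity(self, design3):
        nt = log_transform_normalize(make_table(np.full((2, 8), 9.0), design3))
        delta, avg_fc, _ = fold_change_vs_input(nt)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)
        np.testing.assert_allclose(avg_fc, 1.0)

    def test_uniform_delta(self, design3):
        nt = self._normalized_with_deltas(design3, (1, 1, 1))
        delta, avg_fc, _ = fold_change_vs_input(nt)
        np.testing.assert_allclose(delta[0], [1, 1, 1], atol=1e-12)
        assert avg_fc[0] == pytest.approx(2.0)

    def test_mixed_delta_arithmetic_mean(self, design3):
        # delta (1, 2, 3): (2 + 4 + 8) / 3 = 14/3
        nt = self._normalized_with_deltas(design3, (1, 2, 3))
        _, avg_fc, _ = fold_change_vs_input(nt)
        assert avg_fc[0] == pytest.approx(14.0 / 3.0)

    def test_geometric_switch(self, design3):
        nt = self._normalized_with_deltas(design3, (1, 2, 3))
        _, avg_fc, _ = fold_change_vs_input(nt, fc_average="geometric")
        assert avg_fc[0] == pytest.approx(4.0)  # 2**mean(1,2,3)


class TestPairedT:
    def test_symmetric_differences(self):
        t, p = paired_t_test([1.0, -1.0, 0.0], [0.0, 0.0, 0.0])
        assert t == 0.0 and p == 1.0

    def test_known_value_against_t_cdf(self):
        # d = (1, 2, 3): t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        t, p = paired_t_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0))
        assert p == pytest.approx(2.0 * (1.0 - stats.t.cdf(2.0 * np.sqrt(3.0), df=2)))

    def test_degenerate_equal(self):
        _, p = paired_t_test([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_degenerate_constant_shift(self):
        _, p = paired_t_test([2.0, 3.0], [1.0, 2.0])
        assert p == 0.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 8))
            wt = rng.normal(size=n)
            ko = rng.normal(size=n)
            t, p = paired_t_test(wt, ko)
            ref = stats.ttest_rel(wt, ko)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])


class TestCallEnrichment:
    def _records(self, design3, avg_fc, p, n_det):
        nt = log_transform_normalize(make_table(np.full((1, 8), 3.0), design3))
        return call_enrichment(
            nt,
            delta=np.zeros((1, 3)),
            avg_fc=np.array([avg_fc]),
            p_values=np.array([p]),
            n_wt_detected=np.array([n_det]),
            column_ids=["c1", "c2", "c3"],
        )

    def test_table1_top_row_passes(self, design3):
        (rec,) = self._records(design3, 2206.8, 2.4e-4, 3)
        assert rec.enriched

    def test_fc_boundary_fails(self, design3):
        (rec,) = self._records(design3, 1.4, 0.001, 3)
        assert not rec.enriched

    def test_detection_criterion_fails(self, design3):
        (rec,) = self._records(design3, 10.0, 0.001, 1)
        assert not rec.enriched

    def test_flag_matches_invariant(self, sim_small):
        _, (table, _, _, _) = sim_small
        records, _ = run_enrichment(table, seed=11)
        for r in records:
            assert r.enriched == (
                r.avg_fold_change > 1.5
                and r.p_value <= 0.05
                and r.n_wt_detected >= 2
                and r.passes_qc
            )

    def test_sorted_by_fold_change(self, sim_small):
        _, (table, _, _, _) = sim_small
        records, _ = run_enrichment(table, seed=11)
        fcs = [r.avg_fold_change for r in records]
        assert fcs == sorted(fcs, reverse=True)


class TestInvariants:
    def test_scale_invariance(self, sim_small):
        # multiplying all raw intensities of one sample by a constant
        # leaves fold changes, p values and calls unchanged
        _, (table, _, _, _) = sim_small
        scaled = make_table(
            table.values.copy(), table.design, list(table.protein_ids),
            list(table.gene_names), table.razor_unique,
        )
        scaled.values[:, 2] = scaled.values[:, 2] * 37.5
        a, _ = run_enrichment(table, seed=3)
        b, _ = run_enrichment(scaled, seed=3)
        for ra, rb in zip(a, b):
            assert ra.protein_id == rb.protein_id
            assert ra.per_column_log2fc == pytest.approx(rb.per_column_log2fc, abs=1e-9)
            assert ra.p_value == pytest.approx(rb.p_value, abs=1e-9)
            assert ra.enriched == rb.enriched

    def test_detection_counts_use_non_imputed_cells(self, sim_small):
        _, (table, _, _, _) = sim_small
        nt = impute_missing(log_transform_normalize(table), seed=0)
        counts = count_wt_detected(nt)
        wt_cols = [nt.sample_index(s) for _, s in nt.design.eluate_samples(WT)]
        expected = (~nt.imputed_mask[:, wt_cols]).sum(axis=1)
        np.testing.assert_array_equal(counts, expected)
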