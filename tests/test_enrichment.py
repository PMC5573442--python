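"""The three compartment-enrichment calling methods."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmir.config import AnalysisConfig
from nucmir.enrichment import (call_method2, call_method3, enrichment_table,
                               filter_low_signal, moderated_t,
                               nuclear_percentage, quantile_normalize,
                               rank_scores)
from nucmir.errors import ConfigError
from nucmir.simulate import gen_expression, triplicate_meta


class TestLowSignalFilter:
    def test_probe_low_in_all_samples_is_removed(self, make_matrix):
        m = make_matrix(np.full((1, 6), 29.0))
        assert len(filter_low_signal(m, 30.0).signals) == 0

    def test_one_detected_sample_retains_the_probe(self, make_matrix):
        m = make_matrix([[31, 0, 0, 0, 0, 0]])
        assert len(filter_low_signal(m, 30.0).signals) == 1

    def test_empty_matrix_passes_through(self, make_matrix):
        m = make_matrix(np.empty((0, 6)))
        assert len(filter_low_signal(m, 30.0).signals) == 0

    def test_order_preserved(self, make_matrix):
        m = make_matrix([[40] * 6, [1] * 6, [50] * 6], probe_ids=["a", "b", "c"])
        assert filter_low_signal(m, 30.0).probe_ids == ["a", "c"]


class TestNuclearPercentage:
    def test_ninety_ten_split(self, make_matrix):
        m = make_matrix([[90, 90, 90, 10, 10, 10]])
        assert nuclear_percentage(m).iloc[0] == 90.0

    def test_equal_compartments_give_fifty(self, make_matrix):
        m = make_matrix([[7, 7, 7, 7, 7, 7]])
        assert nuclear_percentage(m).iloc[0] == 50.0

    def test_global_rescaling_invariance(self, make_matrix):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, size=(20, 6))
        p1 = nuclear_percentage(make_matrix(x))
        p2 = nuclear_percentage(make_matrix(3.0 * x))
        np.testing.assert_allclose(p1.values, p2.values)

    def test_replicate_means_are_taken_first(self, make_matrix):
        # nuclear reps (10, 20, 30) -> mean 20; cytoplasmic all 20 -> 50%
        m = make_matrix([[10, 20, 30, 20, 20, 20]])
        assert nuclear_percentage(m).iloc[0] == 50.0

    def test_both_zero_is_undefined(self, make_matrix):
        m = make_matrix([[0, 0, 0, 0, 0, 0]])
        assert np.isnan(nuclear_percentage(m).iloc[0])

    def test_single_compartment_only_probe_is_100_or_0(self, make_matrix):
        m = make_matrix([[5, 5, 5, 0, 0, 0], [0, 0, 0, 5, 5, 5]])
        assert list(nuclear_percentage(m)) == [100.0, 0.0]

    def test_single_compartment_matrix_errors(self, make_matrix):
        meta = triplicate_meta(3)[:3]
        m = make_matrix(np.ones((2, 3)), meta=meta)
        with pytest.raises(ConfigError):
            nuclear_percentage(m)

    def test_implied_cytoplasmic_percent_completes_to_100(self, make_matrix):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.uniform(1, 50, size=(10, 6)))
        pct = nuclear_percentage(m)
        m_swapped = make_matrix(m.signals[["C1", "C2", "C3", "N1", "N2", "N3"]].values)
        np.testing.assert_allclose(pct.values + nuclear_percentage(m_swapped).values,
                                   100.0)


class TestMethod3Call:
    def test_table_style_percentage_is_enriched(self):
        pcts = pd.Series([71.94])
        assert call_method3(pcts, 70.0).iloc[0]

    def test_exactly_at_threshold_is_not_enriched(self):
        assert not call_method3(pd.Series([70.0]), 70.0).iloc[0]

    def test_zero_and_nan_are_not_enriched(self):
        calls = call_method3(pd.Series([0.0, np.nan]), 70.0)
        assert not calls.any()


class TestRankScores:
    def test_three_point_sample(self, make_matrix):
        m = make_matrix(np.array([[10.0], [20.0], [30.0]]) @ np.ones((1, 6)))
        s = rank_scores(m)
        assert list(s["N1"]) == [-1.0, 0.0, 1.0]

    def test_all_equal_scores_zero(self, make_matrix):
        m = make_matrix(np.full((5, 6), 3.0))
        assert (rank_scores(m).values == 0).all()

    def test_monotone_in_signal_within_sample(self, make_matrix):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, size=(50, 6))
        s = rank_scores(make_matrix(x))
        for j in range(6):
            order = np.argsort(x[:, j])
            assert (np.diff(s.values[order, j]) >= 0).all()

    def test_agrees_with_brute_force_oracle(self, make_matrix):
        rng = np.random.default_rng(3)
        x = np.round(rng.uniform(0, 20, size=(50, 6)))  # rounding makes ties
        s = rank_scores(make_matrix(x))
        n = 50
        for j in range(6):
            col = x[:, j]
            for i in range(n):
                larger = (col > col[i]).sum()
                equal = (col == col[i]).sum()
                position = 1 + larger + (equal - 1) / 2.0
                assert s.values[i, j] == pytest.approx((n + 1) / 2.0 - position)


class TestMethod2Call:
    def make_scores(self, row, meta):
        return pd.DataFrame([row], index=["p"],
                            columns=[m.sample_id for m in meta])

    def test_full_separation_is_enriched(self, meta6):
        s = self.make_scores([5, 4, 6, 1, 2, 3], meta6)
        assert call_method2(s, meta6).iloc[0]

    def test_one_overlap_breaks_the_call(self, meta6):
        s = self.make_scores([5, 2, 6, 1, 3, 4], meta6)
        assert not call_method2(s, meta6).iloc[0]

    def test_tie_is_not_enriched(self, meta6):
        s = self.make_scores([5, 4, 3, 1, 2, 3], meta6)
        assert not call_method2(s, meta6).iloc[0]

    def test_invariant_under_monotone_within_sample_transform(self, make_matrix):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 100, size=(30, 6))
        m1 = make_matrix(x)
        m2 = make_matrix(np.exp(x / 25.0))  # strictly monotone transform
        c1 = call_method2(rank_scores(m1), m1.meta)
        c2 = call_method2(rank_scores(m2), m2.meta)
        assert (c1 == c2).all()


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self, make_matrix):
        col = np.array([5.0, 1.0, 9.0, 3.0])
        m = make_matrix(np.tile(col[:, None], (1, 6)))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.signals.values, m.signals.values)

    def test_columns_share_sorted_values_afterwards(self, make_matrix):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.uniform(0, 100, size=(20, 6)))
        out = quantile_normalize(m).signals.values
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_matches_brute_force_reference(self, make_matrix):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 50, size=(20, 4))
        meta = triplicate_meta(2)
        m = make_matrix(x, meta=meta)
        got = quantile_normalize(m).signals.values
        # independent reference: mean of order statistics assigned by rank,
        # tie groups averaged
        ref = np.sort(x, axis=0).mean(axis=1)
        expected = np.empty_like(x)
        for j in range(4):
            order = np.argsort(x[:, j], kind="stable")
            tmp = np.empty(20)
            tmp[order] = ref
            for v in np.unique(x[:, j]):
                mask = x[:, j] == v
                tmp[mask] = tmp[mask].mean()
            expected[:, j] = tmp
        np.testing.assert_allclose(got, expected)

    def test_preserves_within_sample_order(self, make_matrix):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 50, size=(30, 6))
        out = quantile_normalize(make_matrix(x)).signals.values
        for j in range(6):
            order = np.argsort(x[:, j])
            assert (np.diff(out[order, j]) >= 0).all()


class TestModeratedT:
    def test_identical_group_means_give_t0_p1(self, make_matrix):
        rng = np.random.default_rng(8)
        x = rng.lognormal(5, 0.5, size=(30, 6))
        x[0] = [4, 5, 6, 6, 5, 4]  # same mean, same spread
        res = moderated_t(make_matrix(x))
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_zero_prior_df_recovers_ordinary_t(self, make_matrix):
        rng = np.random.default_rng(9)
        x = rng.lognormal(6, 1, size=(200, 6)) * rng.lognormal(0, 0.2, size=(200, 6))
        m = make_matrix(x)
        res = moderated_t(m, prior_df=0)
        y = np.log2(x + 1.0)
        t_ref, p_ref = stats.ttest_ind(y[:, :3], y[:, 3:], axis=1)
        np.testing.assert_allclose(res["t"].values, t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"].values, p_ref, rtol=1e-10)

    def test_null_type_i_error_is_calibrated(self, make_matrix):
        rng = np.random.default_rng(10)
        x = rng.lognormal(6, 1, size=(1000, 1)) * rng.lognormal(0, 0.15, size=(1000, 6))
        res = moderated_t(make_matrix(x))
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_single_replicate_errors(self, make_matrix):
        meta = (triplicate_meta(1))
        m = make_matrix(np.ones((5, 2)), meta=meta)
        with pytest.raises(ConfigError, match="replicates"):
            moderated_t(m)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_bioconductor_limma(self, make_matrix, tmp_path):
        """Independent oracle: limma lmFit + eBayes on the same log2 matrix."""
        rng = np.random.default_rng(42)
        n = 150
        sd = np.sqrt(0.3 * 3 / rng.chisquare(3, size=n))  # heteroscedastic
        y = rng.normal(6, 1, size=(n, 1)) + sd[:, None] * rng.normal(size=(n, 6))
        x = np.clip(np.exp2(y) - 1.0, 0, None)
        m = make_matrix(x)
        res = moderated_t(m)
        mat = tmp_path / "mat.tsv"
        np.savetxt(mat, np.log2(x + 1.0), delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{mat}", sep="\\t"))\n'
            'g <- factor(c("N","N","N","C","C","C"), levels=c("C","N"))\n'
            'fit <- eBayes(lmFit(x, model.matrix(~g)))\n'
            'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n'
            f'write.table(out, "{tmp_path / "out.tsv"}", sep="\\t", '
            'quote=FALSE, row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert res.attrs["prior_df"] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res["t"].values, ref["t"].values, rtol=1e-8)
        np.testing.assert_allclose(res["p"].values, ref["p"].values, rtol=1e-8)


class TestEnrichmentTable:
    def test_columns_and_row_count(self):
        m, _ = gen_expression(n_probes=60, n_enriched=3, seed=11)
        table = enrichment_table(m, AnalysisConfig())
        assert list(table.columns) == [
            "probe_id", "mean_nuclear", "mean_cytoplasmic", "nuclear_pct",
            "method2_call", "method1_t", "method1_p", "method1_q",
            "method3_call",
        ]
        kept = filter_low_signal(m, 30.0)
        assert len(table) == len(kept.signals)

    def test_planted_probes_called_by_method3(self):
        m, truth = gen_expression(n_probes=200, n_enriched=5, seed=12)
        table = enrichment_table(m, AnalysisConfig())
        called = set(table.loc[table["method3_call"], "probe_id"])
        assert called == set(truth.enriched_probe_ids)
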