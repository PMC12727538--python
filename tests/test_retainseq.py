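"""Retention-screen caller: every filter and statistic against hand
arithmetic, plus the replicate calling rule and filter monotonicity."""

import numpy as np
import pandas as pd
import pytest

from retainkit.intervals import GenomeLayout, IntervalSet, bin_genome
from retainkit.retainseq import (
    WindowCounts,
    call_retention_elements,
    filter_windows,
    genome_representation_qc,
    log2_enrichment,
    neighbor_normalize,
    normalize_cpm,
    run_pipeline,
    read_counts_tsv,
    write_counts_tsv,
    window_significance,
)
from retainkit.synthetic import (
    RetainSeqSimConfig,
    simulate_retainseq_counts,
    truth_for_windows,
)


def make_counts(input_counts, output_columns=None, bin_size=1000):
    """WindowCounts on consecutive 1-kb windows of one chromosome."""
    n = len(input_counts)
    layout = GenomeLayout.from_dict({"chrT": n * bin_size})
    windows = bin_genome(layout, bin_size)
    cols = {"input": np.asarray(input_counts)}
    rows = [{"sample": "input", "role": "input", "replicate": 0, "timepoint": 0}]
    for name, (vals, rep, tp) in (output_columns or {}).items():
        cols[name] = np.asarray(vals)
        rows.append({"sample": name, "role": "output", "replicate": rep, "timepoint": tp})
    return WindowCounts(windows, pd.DataFrame(cols), pd.DataFrame(rows).set_index("sample"))


class TestFilterWindows:
    def test_min_reads_then_outlier_on_survivors(self):
        wc = make_counts([9, 10, 50])
        filtered, reasons = filter_windows(wc)
        # window 0 removed by min-reads; survivors {10, 50} have mean 30,
        # sd ~28.3, threshold ~115 -> no outlier removal
        assert reasons["low_input"].tolist() == [True, False, False]
        assert not reasons["input_outlier"].any()
        assert len(filtered) == 2

    def test_blacklist_overrides_counts(self):
        wc = make_counts([100, 100, 100])
        bl = IntervalSet.from_records([("chrT", 1000, 2000)])
        filtered, reasons = filter_windows(wc, blacklist=bl)
        assert reasons["blacklist"].tolist() == [False, True, False]
        assert len(filtered) == 2

    def test_constant_counts_produce_no_outliers(self):
        wc = make_counts([50] * 20)
        _, reasons = filter_windows(wc)
        assert not reasons["input_outlier"].any()

    def test_outlier_detected_above_three_sd(self):
        vals = [100] * 50 + [105] * 49 + [100000]
        _, reasons = filter_windows(make_counts(vals))
        assert reasons["input_outlier"].to_numpy()[-1]
        assert reasons["input_outlier"].sum() == 1

    def test_all_removed_raises(self):
        with pytest.raises(ValueError):
            filter_windows(make_counts([1, 2, 3]))


class TestQC:
    def test_fraction_and_threshold(self):
        wc = make_counts(
            [100] * 8,
            {"out": ([12, 11, 10, 10, 9, 0, 0, 0], 1, 1)},
        )
        qc = genome_representation_qc(wc)
        row = qc.table.set_index("sample").loc["out"]
        assert row["fraction_represented"] == 0.5
        assert row["passed"]

    def test_all_zero_fails(self):
        wc = make_counts([100] * 4, {"out": ([0, 0, 0, 0], 1, 1)})
        qc = genome_representation_qc(wc)
        assert qc.failed_output_samples() == ["out"]

    def test_simulated_dropout_is_flagged(self):
        cfg = RetainSeqSimConfig(
            n_windows=2000, n_timepoints=1, dropout_rate=0.6, seed=5
        )
        wc, _ = simulate_retainseq_counts(cfg)
        qc = genome_representation_qc(wc)
        assert len(qc.failed_output_samples()) == cfg.n_replicates


class TestNormalisation:
    def test_cpm_hand_arithmetic(self):
        wc = make_counts([1, 1, 2])
        cpm = normalize_cpm(wc)
        np.testing.assert_allclose(cpm["input"], [250000, 250000, 500000])

    def test_cpm_columns_sum_to_one_million(self, rng):
        wc = make_counts(rng.integers(1, 1000, size=50))
        assert normalize_cpm(wc)["input"].sum() == pytest.approx(1e6)

    def test_zero_total_raises(self):
        wc = make_counts([10, 20], {"out": ([0, 0], 1, 1)})
        with pytest.raises(ValueError):
            normalize_cpm(wc)

    @pytest.mark.parametrize(
        "cpm_out,cpm_in,pseudo,expected",
        [(100.0, 100.0, 0.0, 0.0), (400.0, 100.0, 0.0, 2.0),
         (0.0, 100.0, 1.0, np.log2(1 / 101))],
    )
    def test_log2fc_values(self, cpm_out, cpm_in, pseudo, expected):
        cpm = pd.DataFrame({"input": [cpm_in, cpm_in], "out": [cpm_out, cpm_in]})
        l2 = log2_enrichment(cpm, "input", pseudocount=pseudo)
        assert l2["out"].iloc[0] == pytest.approx(expected)

    def test_zero_output_without_pseudocount_floored_to_sample_min(self):
        cpm = pd.DataFrame({"input": [100.0, 100.0], "out": [0.0, 50.0]})
        l2 = log2_enrichment(cpm, "input")
        assert np.isfinite(l2["out"]).all()
        assert l2["out"].iloc[0] == l2["out"].min()


class TestNeighborNormalize:
    def test_uniform_signal_adjusts_to_zero(self):
        wc = make_counts([10] * 20)
        l2 = pd.DataFrame({"out": np.full(20, 1.7)})
        adj, flag = neighbor_normalize(l2, wc.windows)
        np.testing.assert_allclose(adj["out"], 0.0)
        assert not flag.any()

    def test_amplified_block_with_spike(self):
        # 30 windows: block of 11 at +3 (windows 10..20), spiked window 15 at +6
        vals = np.zeros(30)
        vals[10:21] = 3.0
        vals[15] = 6.0
        wc = make_counts([10] * 30)
        adj, _ = neighbor_normalize(pd.DataFrame({"out": vals}), wc.windows)
        a = adj["out"].to_numpy()
        assert a[15] == pytest.approx(3.0)  # spike stands out over the block
        for w in (12, 13, 14, 16, 17, 18):
            assert a[w] == pytest.approx(0.0)  # block interior is background
        # block edges: upper median sides with the amplified level
        assert a[10] == pytest.approx(0.0)
        assert a[20] == pytest.approx(0.0)

    def test_isolated_window_flagged_and_unchanged(self):
        layout = GenomeLayout.from_dict({"chrT": 100_000})
        windows = IntervalSet.from_records(
            [("chrT", 0, 1000), ("chrT", 50_000, 51_000)]
        )
        l2 = pd.DataFrame({"out": [2.0, 3.0]})
        adj, flag = neighbor_normalize(l2, windows)
        assert flag.all()
        np.testing.assert_allclose(adj["out"], l2["out"])

    def test_neighbors_do_not_cross_chromosomes(self):
        layout = GenomeLayout.from_dict({"c1": 2000, "c2": 2000})
        windows = bin_genome(layout, 1000)
        l2 = pd.DataFrame({"out": [0.0, 0.0, 5.0, 5.0]})
        adj, _ = neighbor_normalize(l2, windows)
        np.testing.assert_allclose(adj["out"], 0.0)


class TestSignificance:
    def test_z_and_upper_tail_p(self):
        sig = window_significance(pd.DataFrame({"s": [1.0, 2.0, 3.0]}))["s"]
        assert sig["z"].iloc[2] == pytest.approx(1.0)
        assert sig["p"].iloc[2] == pytest.approx(0.15865525, abs=1e-6)
        assert sig["p"].iloc[1] == pytest.approx(0.5)  # x == m

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            window_significance(pd.DataFrame({"s": [1.0, 1.0, 1.0]}))

    def test_fdr_at_least_p(self, rng):
        sig = window_significance(pd.DataFrame({"s": rng.normal(size=500)}))["s"]
        assert (sig["fdr"] >= sig["p"] - 1e-15).all()


def significance_from_fdr(windows, fdr_by_sample):
    return {
        s: pd.DataFrame(
            {"z": np.zeros(len(windows)), "p": f, "fdr": np.asarray(f)}
        )
        for s, f in fdr_by_sample.items()
    }


class TestCallingRule:
    def setup_method(self):
        layout = GenomeLayout.from_dict({"chrT": 3000})
        self.windows = bin_genome(layout, 1000)
        self.samples = pd.DataFrame(
            {
                "sample": ["d7_r1", "d7_r2", "d14_r1", "d14_r2"],
                "role": "output",
                "replicate": [1, 2, 1, 2],
                "timepoint": [7, 7, 14, 14],
            }
        ).set_index("sample")

    def call(self, fdr_by_sample, **kw):
        sig = significance_from_fdr(self.windows, fdr_by_sample)
        return call_retention_elements(sig, self.windows, self.samples, **kw)

    def test_both_replicates_same_timepoint_called(self):
        hi = [0.9, 0.9, 0.9]
        res = self.call(
            {"d7_r1": [0.05, 0.9, 0.9], "d7_r2": [0.05, 0.9, 0.9],
             "d14_r1": hi, "d14_r2": hi}
        )
        assert res.window_calls["significant"].tolist() == [True, False, False]
        assert len(res.elements) == 1

    def test_single_replicate_everywhere_not_called(self):
        hi = [0.9, 0.9, 0.9]
        res = self.call(
            {"d7_r1": [0.05, 0.9, 0.9], "d7_r2": hi,
             "d14_r1": [0.05, 0.9, 0.9], "d14_r2": hi}
        )
        assert not res.window_calls["significant"].any()

    def test_cross_timepoint_support_needs_relaxed_mode(self):
        hi = [0.9, 0.9, 0.9]
        tables = {"d7_r1": [0.05, 0.9, 0.9], "d7_r2": hi,
                  "d14_r1": hi, "d14_r2": [0.05, 0.9, 0.9]}
        strict = self.call(tables)
        assert not strict.window_calls["significant"].any()
        relaxed = self.call(tables, same_timepoint=False)
        assert relaxed.window_calls["significant"].tolist() == [True, False, False]

    def test_threshold_is_strict(self):
        hi = [0.9, 0.9, 0.9]
        res = self.call(
            {"d7_r1": [0.1, 0.9, 0.9], "d7_r2": [0.1, 0.9, 0.9],
             "d14_r1": hi, "d14_r2": hi}
        )
        assert not res.window_calls["significant"].any()

    def test_adjacent_significant_windows_merge(self):
        lo = [0.01, 0.01, 0.9]
        hi = [0.9, 0.9, 0.9]
        res = self.call({"d7_r1": lo, "d7_r2": lo, "d14_r1": hi, "d14_r2": hi})
        assert len(res.elements) == 1
        el = res.elements.iloc[0]
        assert (el["start"], el["end"], el["n_windows"]) == (0, 2000, 2)


class TestPipeline:
    def test_counts_tsv_roundtrip(self, tmp_path):
        cfg = RetainSeqSimConfig(n_windows=200, n_timepoints=1, seed=1)
        wc, _ = simulate_retainseq_counts(cfg)
        write_counts_tsv(wc, tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.counts, wc.counts)
        pd.testing.assert_frame_equal(back.windows.df, wc.windows.df[["chrom", "start", "end"]])

    def test_filter_relaxation_only_adds_calls(self):
        cfg = RetainSeqSimConfig(n_windows=3000, n_timepoints=2, seed=9)
        wc, _ = simulate_retainseq_counts(cfg)
        strictset, _, _ = run_pipeline(wc, min_input_reads=10)
        relaxedset, _, _ = run_pipeline(wc, min_input_reads=0)

        def called(res):
            c = res.window_calls
            return set(map(tuple, c.loc[c["significant"], ["chrom", "start"]].values))

        assert called(strictset) <= called(relaxedset)

    def test_null_screen_calls_almost_nothing(self):
        cfg = RetainSeqSimConfig(
            n_windows=3000, n_timepoints=1, spike_fraction=0.0, cn_blocks=(), seed=2
        )
        wc, truth = simulate_retainseq_counts(cfg)
        assert not truth.any()
        res, _, _ = run_pipeline(wc)
        frac = res.window_calls["significant"].mean()
        assert frac <= 0.01

    def test_copy_number_block_windows_not_called(self):
        cfg = RetainSeqSimConfig(
            n_windows=3000, n_timepoints=2, spike_fraction=0.0,
            cn_blocks=((1500, 1560, 8.0),), seed=4
        )
        wc, _ = simulate_retainseq_counts(cfg)
        res, _, _ = run_pipeline(wc)
        calls = res.window_calls
        block = (calls["chrom"] == "chrS1") & (calls["start"] >= 1_500_000) & (
            calls["start"] < 1_560_000
        )
        assert not calls.loc[block, "significant"].any()
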