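"""Winscore quantification: window grids, RPKM, winscore, peak calling,
quantile normalization and matched-window pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scm6a.config import QuantConfig
from scm6a.quant import (WindowCountTable, call_merge_split, make_windows,
                         match_windows, parse_site_id, peak_levels, rpkm,
                         tpm_quantile_normalize, winscore)


def _ann(lengths):
    return pd.DataFrame({
        "transcript_id": [f"tx{i}" for i in range(len(lengths))],
        "gene_id": [f"G{i}" for i in range(len(lengths))],
        "length": lengths,
        "strand": ["+"] * len(lengths),
    })


def _table(windows, counts, library_size=None):
    df = windows.copy()
    df["count"] = counts
    return WindowCountTable(df, int(library_size or max(sum(counts), 1)))


class TestMakeWindows:
    def test_300bp_transcript_gives_five_windows_spanning_it(self):
        w = make_windows(_ann([300]))
        assert len(w) == 5
        assert w.start.min() == 0 and w.end.max() == 300
        assert (w.end - w.start == 100).all()

    def test_100bp_transcript_gives_single_window(self):
        w = make_windows(_ann([100]))
        assert len(w) == 1
        assert (w.start.iloc[0], w.end.iloc[0]) == (0, 100)

    def test_windows_sorted_and_overlapping_by_half(self):
        w = make_windows(_ann([500]))
        starts = w.start.to_numpy()
        assert (np.diff(starts) == 50).all()
        # each window overlaps its successor by window_size - step
        assert ((w.end.to_numpy()[:-1] - starts[1:]) == 50).all()

    def test_trailing_partial_window_kept_when_wide_enough(self):
        w = make_windows(_ann([320]))
        assert w.end.max() == 320
        assert (w.end - w.start).min() >= 50

    def test_transcript_shorter_than_step_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            make_windows(_ann([40]))


class TestRpkm:
    def test_hand_example(self):
        w = make_windows(_ann([100]))
        t = _table(w, [10], library_size=1_000_000)
        assert rpkm(t)[0] == pytest.approx(100.0)

    def test_zero_count_gives_zero(self):
        w = make_windows(_ann([100]))
        assert rpkm(_table(w, [0], 1000))[0] == 0.0

    def test_doubling_library_halves_rpkm(self):
        w = make_windows(_ann([300]))
        counts = [3, 1, 4, 1, 5]
        a = rpkm(_table(w, counts, 10_000))
        b = rpkm(_table(w, counts, 20_000))
        np.testing.assert_allclose(a, 2 * b)

    def test_linear_in_counts(self):
        w = make_windows(_ann([300]))
        c = np.array([3, 1, 4, 1, 5])
        a = rpkm(_table(w, list(c), 10_000))
        b = rpkm(_table(w, list(3 * c), 10_000))
        np.testing.assert_allclose(b, 3 * a)


class TestWinscore:
    def test_equal_libraries_give_unit_winscore(self):
        x = np.array([0.0, 1.0, 7.5, 100.0])
        np.testing.assert_allclose(winscore(x, x), 1.0)

    def test_boundary_example_not_called(self):
        # (9+1)/(4+1) = 2.0 exactly: not a peak under the strict > 2 rule
        ws = winscore(np.array([9.0]), np.array([4.0]))
        assert ws[0] == pytest.approx(2.0)
        cfg = QuantConfig()
        assert not (ws > cfg.winscore_cutoff).any()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ip=st.floats(0, 1e4), lo=st.floats(0, 1e4), hi=st.floats(0, 1e4))
    def test_monotone_in_ip_and_input(self, ip, lo, hi):
        lo, hi = sorted((lo, hi))
        assert winscore(np.array([lo]), np.array([ip]))[0] <= \
            winscore(np.array([hi]), np.array([ip]))[0]
        assert winscore(np.array([ip]), np.array([hi]))[0] <= \
            winscore(np.array([ip]), np.array([lo]))[0]

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            winscore(np.ones(3), np.ones(4))

    def test_gene_median_normalization_flag(self):
        cfg = QuantConfig(gene_median_norm=True)
        ip = np.array([2.0, 4.0, 8.0])
        inp = np.array([4.0, 4.0, 4.0])
        genes = np.array(["g", "g", "g"])
        ws = winscore(ip, inp, cfg, gene_ids=genes)
        # adjusted ip (3,5,9)/median 5; adjusted input (5,5,5)/median 5
        np.testing.assert_allclose(ws, [3 / 5, 1.0, 9 / 5])


class TestCallMergeSplit:
    def test_twelve_consecutive_windows_split_5_5_2(self):
        w = make_windows(_ann([650]))  # 12 windows
        assert len(w) == 12
        peaks = call_merge_split(w, np.full(12, 3.0))
        assert [len(p.window_rows) for p in peaks] == [5, 5, 2]

    def test_exactly_five_windows_not_split(self):
        w = make_windows(_ann([300]))
        peaks = call_merge_split(w, np.full(5, 3.0))
        assert len(peaks) == 1 and len(peaks[0].window_rows) == 5

    def test_isolated_window_single_peak(self):
        w = make_windows(_ann([300]))
        ws = np.array([0.0, 0.0, 3.0, 0.0, 0.0])
        peaks = call_merge_split(w, ws)
        assert len(peaks) == 1 and list(peaks[0].window_rows) == [2]

    def test_empty_input_empty_output(self):
        w = make_windows(_ann([300]))
        assert call_merge_split(w, np.zeros(5)) == []

    def test_runs_do_not_cross_transcripts(self):
        w = make_windows(_ann([300, 300]))
        peaks = call_merge_split(w, np.full(10, 3.0))
        assert len(peaks) == 2
        assert {p.chrom for p in peaks} == {"tx0", "tx1"}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sig=st.lists(st.booleans(), min_size=1, max_size=40))
    def test_peaks_partition_significant_windows(self, sig):
        n = len(sig)
        length = 100 + 50 * (n - 1)
        w = make_windows(_ann([length]))
        ws = np.where(np.array(sig[:len(w)]), 3.0, 0.5)
        peaks = call_merge_split(w, ws)
        covered = sorted(r for p in peaks for r in p.window_rows)
        assert covered == sorted(np.flatnonzero(ws > 2.0))
        assert all(len(p.window_rows) <= 5 for p in peaks)


class TestPeakLevels:
    def test_single_window_peak_equals_its_winscore(self):
        w = make_windows(_ann([300]))
        ws = np.array([0.0, 0.0, 3.7, 0.0, 0.0])
        peaks = call_merge_split(w, ws)
        lv = peak_levels(peaks, pd.DataFrame({"s1": ws}))
        assert lv.iloc[0, 0] == pytest.approx(3.7)

    def test_mean_vs_max_statistic(self):
        w = make_windows(_ann([300]))
        ws = np.array([3.0, 5.0, 0.0, 0.0, 0.0])
        peaks = call_merge_split(w, ws)
        mean_lv = peak_levels(peaks, pd.DataFrame({"s": ws}),
                              QuantConfig(peak_level_stat="mean"))
        max_lv = peak_levels(peaks, pd.DataFrame({"s": ws}),
                             QuantConfig(peak_level_stat="max"))
        assert mean_lv.iloc[0, 0] == pytest.approx(4.0)
        assert max_lv.iloc[0, 0] == pytest.approx(5.0)

    def test_matrix_shape(self):
        w = make_windows(_ann([650]))
        ws = np.full(12, 3.0)
        peaks = call_merge_split(w, ws)
        mat = pd.DataFrame({"a": ws, "b": ws * 2})
        lv = peak_levels(peaks, mat)
        assert lv.shape == (len(peaks), 2)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        x = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        pd.testing.assert_frame_equal(tpm_quantile_normalize(x), x)

    def test_hand_example(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = tpm_quantile_normalize(x)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_column_means_equal_after_normalization(self, rng):
        x = pd.DataFrame(rng.gamma(2, 3, size=(50, 4)))
        out = tpm_quantile_normalize(x)
        means = out.mean(axis=0).to_numpy()
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_single_column_warns_and_is_noop(self):
        x = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = tpm_quantile_normalize(x)
        pd.testing.assert_frame_equal(out, x)

    def test_preserves_within_column_order(self, rng):
        x = pd.DataFrame(rng.normal(10, 2, size=(30, 3)) ** 2)
        out = tpm_quantile_normalize(x)
        for c in x:
            assert (np.argsort(x[c].to_numpy(), kind="stable")
                    == np.argsort(out[c].to_numpy(), kind="stable")).all()


class TestMatchWindows:
    def _mat(self, ids):
        return pd.DataFrame(np.zeros((len(ids), 1)), index=ids)

    def test_identical_ids_all_matched(self):
        ids = ["G1:0-100", "G2:50-150"]
        pairs = match_windows(self._mat(ids), self._mat(ids))
        assert sorted(p[0] for p in pairs) == sorted(ids)
        assert all(a == b for a, b, _ in pairs)

    def test_disjoint_genes_no_matches(self):
        assert match_windows(self._mat(["G1:0-100"]),
                             self._mat(["G2:0-100"])) == []

    def test_greedy_keeps_larger_overlap(self):
        a = self._mat(["G:0-100", "G:80-200"])
        b = self._mat(["G:60-160"])
        pairs = match_windows(a, b)
        assert len(pairs) == 1
        assert pairs[0][0] == "G:80-200"  # 80 bp overlap beats 40 bp

    def test_malformed_ids_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_site_id("not-a-site-id")


class TestWindowCountTableIO:
    def test_tsv_round_trip(self, tmp_path):
        w = make_windows(_ann([300]))
        t = _table(w, [3, 1, 4, 1, 5], 14)
        path = tmp_path / "counts.tsv"
        t.to_tsv(path)
        back = WindowCountTable.from_tsv(path)
        assert back.library_size == 14
        pd.testing.assert_frame_equal(back.df, t.df)
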