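"""Feature construction and cleaning: missing-value filter, cell QC,
normalization, trans/cis encoders and ortholog mapping."""

import numpy as np
import pandas as pd
import pytest

import scm6a
from scm6a.config import QCConfig
from scm6a.features import (CisFeatureEncoder, MissingValueFilter,
                            build_cis_features, build_trans_features,
                            filter_missing, map_orthologs,
                            normalize_expression, qc_filter_cells)


class TestMissingValueFilter:
    def test_clean_matrix_unchanged(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 6)))
        out, report = filter_missing(x)
        pd.testing.assert_frame_equal(out, x)
        assert report == {"dropped_rows": [], "dropped_cols": []}

    def test_row_with_20pct_missing_dropped(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 10)))
        x.iloc[3, [0, 1]] = np.nan  # 20% of that row
        out, report = filter_missing(x)
        assert out.shape == (9, 10)
        assert report["dropped_rows"] == [3]

    def test_exact_10pct_boundary_retained(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 10)))
        x.iloc[1, 0] = np.nan  # exactly 10% of the row; 25% of the column
        out, _ = filter_missing(x, max_frac=0.10)
        assert 1 in out.index          # row at the boundary is kept
        assert 0 not in out.columns    # column above it is dropped

    def test_percentages_from_original_matrix_rows_then_cols(self):
        # after the bad row goes, the column would fall to 0% missing; it is
        # still dropped because fractions are assessed on the original matrix
        x = pd.DataFrame(np.ones((5, 20)))
        x.iloc[0, :12] = np.nan   # row 60% missing
        x.iloc[0, 0] = np.nan     # col 0: 20% missing (only via row 0)
        out, report = filter_missing(x)
        assert report["dropped_rows"] == [0]
        assert report["dropped_cols"] == list(range(12))

    def test_idempotent(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 10)))
        x.iloc[0, :5] = np.nan
        once, _ = filter_missing(x)
        twice, report = filter_missing(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report == {"dropped_rows": [], "dropped_cols": []}

    def test_dropping_everything_is_an_error(self):
        x = pd.DataFrame(np.full((3, 3), np.nan))
        with pytest.raises(ValueError, match="drop everything"):
            MissingValueFilter().fit(x)


def _counts_matrix(rng, n_genes=300, n_cells=20, depth=2000):
    genes = [f"GENE{i}" for i in range(n_genes - 3)] + \
        ["MT-CO1", "MT-CO2", "MT-ND1"]
    x = rng.poisson(depth / n_genes, size=(n_genes, n_cells))
    return pd.DataFrame(x, index=genes,
                        columns=[f"c{i}" for i in range(n_cells)])


class TestCellQC:
    def test_all_cells_within_bounds_unchanged_cells(self, rng):
        x = _counts_matrix(rng)
        out = qc_filter_cells(x)
        assert list(out.columns) == list(x.columns)

    def test_high_mito_cell_removed(self, rng):
        x = _counts_matrix(rng)
        x.loc["MT-CO1", "c0"] = int(x["c0"].sum())  # ~50% mito in c0
        out = qc_filter_cells(x)
        assert "c0" not in out.columns

    def test_cell_with_150_genes_removed(self, rng):
        x = _counts_matrix(rng)
        col = np.zeros(len(x), int)
        col[:150] = 5
        x["c0"] = col  # 150 detected genes, 750 counts
        out = qc_filter_cells(x)
        assert "c0" not in out.columns

    def test_rare_gene_removed(self, rng):
        x = _counts_matrix(rng)
        x.loc["GENE0"] = 0
        x.loc["GENE0", "c1"] = 3  # expressed in one cell < min 3
        out = qc_filter_cells(x)
        assert "GENE0" not in out.index

    def test_everything_filtered_is_an_error(self, rng):
        x = pd.DataFrame(np.ones((10, 3), int),
                         index=[f"g{i}" for i in range(10)],
                         columns=list("abc"))
        with pytest.raises(ValueError, match="every cell"):
            qc_filter_cells(x, cfg=QCConfig())


class TestNormalizeExpression:
    def test_closed_form_two_gene_cell(self):
        x = pd.DataFrame({"cell": [10.0, 90.0]}, index=["g1", "g2"])
        out = normalize_expression(x)
        np.testing.assert_allclose(out["cell"],
                                   [np.log(1001.0), np.log(9001.0)])

    def test_all_zero_gene_stays_zero(self, rng):
        x = pd.DataFrame(rng.poisson(5, size=(4, 3)).astype(float))
        x.iloc[2] = 0.0
        out = normalize_expression(x)
        assert (out.iloc[2] == 0).all()

    def test_scaled_totals_hit_scale_factor(self, rng):
        x = pd.DataFrame(rng.poisson(5, size=(50, 4)).astype(float))
        scaled = x / x.sum(axis=0) * 1e4
        np.testing.assert_allclose(scaled.sum(axis=0), 1e4)
        np.testing.assert_allclose(normalize_expression(x), np.log1p(scaled))

    def test_preserves_within_cell_rank_order(self, rng):
        x = pd.DataFrame(rng.gamma(2, 10, size=(40, 3)))
        out = normalize_expression(x)
        for c in x:
            assert (np.argsort(x[c].to_numpy(), kind="stable")
                    == np.argsort(out[c].to_numpy(), kind="stable")).all()

    def test_zero_total_cell_rejected(self):
        x = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero-total"):
            normalize_expression(x)


class TestTransFeatures:
    def test_panel_order_and_missing_fill(self, rng):
        expr = pd.DataFrame(rng.random((3, 4)),
                            index=["R2", "R0", "R1"],
                            columns=list("abcd"))
        out = build_trans_features(expr, ["R0", "R1", "R2"])
        assert list(out.columns) == ["R0", "R1", "R2"]
        assert out.shape == (4, 3)
        with pytest.warns(UserWarning, match="absent"):
            out2 = build_trans_features(expr, ["R0", "R9"])
        assert (out2["R9"] == 0).all()

    def test_order_invariant_to_expression_row_order(self, rng):
        expr = pd.DataFrame(rng.random((4, 5)),
                            index=["R3", "R1", "R0", "R2"],
                            columns=[f"c{i}" for i in range(5)])
        shuffled = expr.sample(frac=1, random_state=1)
        a = build_trans_features(expr, ["R0", "R1", "R2", "R3"])
        b = build_trans_features(shuffled, ["R0", "R1", "R2", "R3"])
        pd.testing.assert_frame_equal(a, b)

    def test_no_regulator_found_is_error(self, rng):
        expr = pd.DataFrame(rng.random((2, 2)), index=["x", "y"])
        with pytest.raises(ValueError, match="no regulator"):
            build_trans_features(expr, ["R0"])


class TestCisFeatures:
    def test_uniform_ppm_flattens_to_quarter_vector(self):
        ppm = pd.DataFrame(np.full((4, 5), 0.25), index=list("ACGU"))
        out = build_cis_features({"s1": ppm}, mode="flatten")
        assert out.shape == (1, 20)
        np.testing.assert_allclose(out.iloc[0], 0.25)

    def test_flatten_round_trips_to_ppm(self):
        ppms = scm6a.gen_ppms(3, "GGACU", seed=4)
        out = build_cis_features({f"s{i}": p for i, p in enumerate(ppms)},
                                 mode="flatten")
        for i, p in enumerate(ppms):
            back = out.loc[f"s{i}"].to_numpy().reshape(4, 5)
            np.testing.assert_allclose(back, np.asarray(p))

    def test_ragged_lengths_rejected(self):
        a = pd.DataFrame(np.full((4, 5), 0.25), index=list("ACGU"))
        b = pd.DataFrame(np.full((4, 3), 0.25), index=list("ACGU"))
        with pytest.raises(ValueError, match="ragged"):
            build_cis_features({"s1": a, "s2": b}, mode="flatten")

    def test_consensus_sequence_maximizes_scan_score(self):
        ppms = scm6a.gen_ppms(1, "GGACU", seed=0, perturbation=0.05)
        enc = CisFeatureEncoder(mode="score", ppms=ppms).fit()
        best = enc.scan_score("GGACU", ppms[0])
        # the consensus beats every other 5-mer
        import itertools
        for seq in itertools.product("ACGU", repeat=5):
            assert enc.scan_score("".join(seq), ppms[0]) <= best + 1e-12

    def test_42_motifs_give_42_features(self):
        ppms = scm6a.gen_ppms(42, "GGACU", seed=1)
        out = build_cis_features(site_sequences={"s1": "AAGGACUAA"},
                                 mode="score", motif_ppms=ppms)
        assert out.shape == (1, 42)


class TestOrthologMapping:
    def test_identity_mapping_relabels_only(self, rng):
        expr = pd.DataFrame(rng.random((3, 2)), index=["m1", "m2", "m3"],
                            columns=["c1", "c2"])
        mapping = pd.DataFrame({"src": ["m1", "m2", "m3"],
                                "dst": ["h1", "h2", "h3"]})
        out, report = map_orthologs(expr, mapping, log_transform=False)
        assert list(out.index) == ["h1", "h2", "h3"]
        np.testing.assert_allclose(out.to_numpy(), expr.to_numpy())
        assert report["dropped_genes"] == []

    def test_unmapped_genes_dropped_and_reported(self, rng):
        expr = pd.DataFrame(rng.random((10, 2)),
                            index=[f"m{i}" for i in range(10)])
        mapping = pd.DataFrame({"src": [f"m{i}" for i in range(7)],
                                "dst": [f"h{i}" for i in range(7)]})
        out, report = map_orthologs(expr, mapping)
        assert out.shape[0] == 7
        assert sorted(report["dropped_genes"]) == ["m7", "m8", "m9"]

    def test_many_to_one_aggregates_by_sum_then_logs(self):
        expr = pd.DataFrame({"c": [3.0, 5.0]}, index=["m1", "m2"])
        mapping = pd.DataFrame({"src": ["m1", "m2"], "dst": ["h", "h"]})
        out, _ = map_orthologs(expr, mapping)
        assert out.loc["h", "c"] == pytest.approx(np.log1p(8.0))

    def test_duplicate_sources_rejected(self, rng):
        expr = pd.DataFrame(rng.random((2, 1)), index=["m1", "m2"])
        mapping = pd.DataFrame({"src": ["m1", "m1"], "dst": ["h1", "h2"]})
        with pytest.raises(ValueError, match="many-to-one"):
            map_orthologs(expr, mapping)

    def test_empty_mapping_rejected(self, rng):
        expr = pd.DataFrame(rng.random((2, 1)), index=["m1", "m2"])
        with pytest.raises(ValueError, match="empty"):
            map_orthologs(expr, pd.DataFrame(columns=["s", "t"]))
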