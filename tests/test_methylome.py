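"""Cytosine-report parsing, level computation and methylome summaries."""
import gzip
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methex import methylome
from methex.methylome import (ReportParseError, classify_sites,
                              compute_levels, context_composition,
                              level_histogram, merge_samples,
                              methylation_pca, pairwise_sample_correlation,
                              parse_cytosine_report)


def report_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                       "count_methylated",
                                       "count_unmethylated", "context"])


class TestParse:
    def test_parses_simple_line(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("chr1\t101\t+\t3\t2\tCpG\n")
        df = parse_cytosine_report(p)
        assert df.loc[0, "count_methylated"] == 3
        assert df.loc[0, "count_unmethylated"] == 2
        assert df.loc[0, "pos"] == 101

    def test_gzip_accepted(self, tmp_path):
        p = tmp_path / "r.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t-\t0\t7\tCpG\n")
        df = parse_cytosine_report(p)
        assert len(df) == 1 and df.loc[0, "strand"] == "-"

    def test_empty_file_gives_empty_table(self, tmp_path, caplog):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with caplog.at_level("WARNING"):
            df = parse_cytosine_report(p)
        assert df.empty
        assert "empty" in caplog.text

    @pytest.mark.parametrize("line,match", [
        ("chr1\t101\t+\t-1\t2\tCpG\n", "line 1"),
        ("chr1\t101\t+\t3\t2\tCpG\nchr1\t102\t+\tx\t2\tCpG\n", "line 2"),
        ("chr1\t0\t+\t3\t2\tCpG\n", "line 1"),
        ("chr1\t101\t*\t3\t2\tCpG\n", "strand"),
        ("chr1\t101\t+\t3\t2\tCpA\n", "context"),
    ])
    def test_malformed_rows_name_the_line(self, tmp_path, line, match):
        p = tmp_path / "bad.tsv"
        p.write_text(line)
        with pytest.raises(ReportParseError, match=match):
            parse_cytosine_report(p)

    def test_too_few_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t101\t+\n")
        with pytest.raises(ReportParseError, match="columns"):
            parse_cytosine_report(p)


class TestContextComposition:
    def test_fraction_arithmetic(self):
        rows = [("chr1", i + 1, "+", 1, 1, c)
                for i, c in enumerate(["CpG"] * 6 + ["CHG"] * 2 + ["CHH"] * 2)]
        frac = context_composition(report_df(rows))
        assert frac.tolist() == pytest.approx([0.6, 0.2, 0.2])
        assert frac.sum() == pytest.approx(1.0)

    def test_all_cpg(self):
        rows = [("chr1", i + 1, "+", 2, 0, "CpG") for i in range(5)]
        assert context_composition(report_df(rows)).tolist() == [1.0, 0.0, 0.0]

    def test_unmethylated_sites_not_counted(self):
        rows = [("chr1", 1, "+", 0, 9, "CHH"), ("chr1", 2, "+", 3, 1, "CpG")]
        assert context_composition(report_df(rows))["CpG"] == 1.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            context_composition(report_df([]))

    def test_simulated_reports_are_cpg_dominated(self, default_dataset):
        df = default_dataset.reports[default_dataset.design.index[0]]
        assert context_composition(df)["CpG"] > 0.9


class TestComputeLevels:
    @pytest.mark.parametrize("meth,unmeth,kept,level", [
        (3, 2, True, 0.6),    # coverage 5 retained, level C/(C+T)
        (4, 0, False, None),  # coverage 4 dropped
        (0, 5, True, 0.0),    # fully unmethylated boundary
        (5, 0, True, 1.0),
    ])
    def test_level_formula_and_filter(self, meth, unmeth, kept, level):
        out = compute_levels(report_df([("chr1", 10, "+", meth, unmeth, "CpG")]))
        if kept:
            assert len(out) == 1
            assert out.loc[0, "level"] == pytest.approx(level)
        else:
            assert out.empty

    def test_non_cpg_contexts_excluded(self):
        out = compute_levels(report_df([("chr1", 10, "+", 9, 1, "CHG")]))
        assert out.empty

    def test_min_coverage_below_one_rejected(self):
        with pytest.raises(ValueError):
            compute_levels(report_df([]), min_coverage=0)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)),
                    min_size=1, max_size=50),
           st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_filter_monotone_in_coverage(self, counts, min_cov):
        rows = [("chr1", i + 1, "+", c, t, "CpG")
                for i, (c, t) in enumerate(counts)]
        tab = report_df(rows)
        n_lo = len(compute_levels(tab, min_coverage=min_cov))
        n_hi = len(compute_levels(tab, min_coverage=min_cov + 1))
        assert n_hi <= n_lo

    def test_level_exactness_on_simulation(self, default_matrix):
        """level * coverage reproduces the methylated count everywhere."""
        lv = default_matrix.level.to_numpy()
        cov = default_matrix.coverage.to_numpy()
        meth = default_matrix.meth.to_numpy()
        ok = ~np.isnan(lv)
        np.testing.assert_allclose(lv[ok] * cov[ok], meth[ok], atol=1e-9)
        assert np.nanmin(lv) >= 0 and np.nanmax(lv) <= 1


class TestMerge:
    def test_identity_single_sample(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 5, 3, 2)]})
        assert mat.level.shape == (1, 1)
        assert mat.level.iloc[0, 0] == pytest.approx(0.6)

    def test_disjoint_sites_union_with_missing(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 5, 3, 2)],
                                   "s2": [("chr1", 9, 1, 4)]})
        assert mat.level.shape == (2, 2)
        assert mat.level.isna().sum().sum() == 2

    def test_input_order_invariance(self, tiny_matrix_factory):
        design = pd.DataFrame({"stage": ["p21", "p21"], "replicate": [1, 2]},
                              index=pd.Index(["s1", "s2"], name="sample"))
        rows1 = [("chr1", 5, 3, 2), ("chr2", 1, 0, 8)]
        rows2 = [("chr1", 9, 1, 4)]
        a = tiny_matrix_factory({"s1": rows1, "s2": rows2}, design)
        b = tiny_matrix_factory({"s2": rows2, "s1": rows1}, design)
        pd.testing.assert_frame_equal(a.level, b.level)

    def test_duplicate_site_rejected(self, tiny_matrix_factory):
        with pytest.raises(ValueError, match="duplicate"):
            tiny_matrix_factory({"s1": [("chr1", 5, 3, 2), ("chr1", 5, 1, 6)]})

    def test_sites_sorted(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr2", 7, 1, 5), ("chr1", 9, 1, 4),
                                          ("chr1", 2, 2, 4)]})
        assert mat.level.index.tolist() == [("chr1", 2), ("chr1", 9), ("chr2", 7)]


class TestHistogramAndClasses:
    def test_all_zero_levels_fill_first_bin(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", i + 1, 0, 5)
                                          for i in range(4)]})
        hist = level_histogram(mat)
        assert hist["s1"].iloc[0] == 4
        assert hist["s1"].sum() == 4

    def test_uniform_grid_one_per_bin(self, tiny_matrix_factory):
        # levels k/40 for odd k: 0.025, 0.075, ..., 0.975 -> one per 5% bin
        mat = tiny_matrix_factory({"s1": [("chr1", k, 2 * k - 1, 40 - (2 * k - 1))
                                          for k in range(1, 21)]})
        assert (level_histogram(mat)["s1"] == 1).all()

    def test_histogram_bin_count_param(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 1, 1, 1)]})
        assert len(level_histogram(mat, n_bins=10)) == 10
        with pytest.raises(ValueError):
            level_histogram(mat, n_bins=1)

    def test_boundary_levels_classified_as_quoted(self, tiny_matrix_factory):
        # 0.25 -> low, 0.5 -> medium, 0.75 -> high (closed thresholds)
        mat = tiny_matrix_factory({"s1": [("chr1", 1, 1, 3), ("chr1", 2, 2, 2),
                                          ("chr1", 3, 3, 1)]})
        frac = classify_sites(mat).loc["s1"]
        assert frac.tolist() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_all_high(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", i + 1, 9, 1)
                                          for i in range(3)]})
        assert classify_sites(mat).loc["s1"].tolist() == [0.0, 0.0, 1.0]

    def test_fractions_sum_to_one(self, default_matrix):
        frac = classify_sites(default_matrix)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_heavily_methylated_genome_shape(self, default_matrix):
        """Simulated methylome: more high- than mid-methylated CpGs."""
        frac = classify_sites(default_matrix).mean()
        assert frac["high"] > frac["medium"]


class TestCorrelationAndPca:
    def test_duplicated_sample_correlates_perfectly(self, tiny_matrix_factory):
        rows = [("chr1", i + 1, i, 10 - i) for i in range(8)]
        mat = tiny_matrix_factory({"s1": rows, "s2": rows})
        corr = pairwise_sample_correlation(mat)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert corr.loc["s1", "s1"] == 1.0

    def test_complement_sample_anticorrelates(self, tiny_matrix_factory):
        rows = [("chr1", i + 1, i, 10 - i) for i in range(8)]
        flipped = [("chr1", i + 1, 10 - i, i) for i in range(8)]
        mat = tiny_matrix_factory({"s1": rows, "s2": flipped})
        assert pairwise_sample_correlation(mat).loc["s1", "s2"] == pytest.approx(-1.0)

    def test_insufficient_overlap_flagged_nan(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 1, 3, 3), ("chr1", 2, 1, 5)],
                                   "s2": [("chr1", 9, 1, 5), ("chr1", 10, 2, 4)]})
        assert np.isnan(pairwise_sample_correlation(mat).loc["s1", "s2"])

    def test_single_sample_rejected(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 1, 3, 3)]})
        with pytest.raises(ValueError):
            pairwise_sample_correlation(mat)

    def test_replicates_correlate_higher_within_stage(self, default_matrix):
        corr = pairwise_sample_correlation(default_matrix)
        within, across = [], []
        samples = list(corr.index)
        for i, s1 in enumerate(samples):
            for s2 in samples[i + 1:]:
                bucket = within if s1.split("_")[0] == s2.split("_")[0] else across
                bucket.append(corr.loc[s1, s2])
        assert np.mean(within) > np.mean(across)

    def test_identical_samples_coincide_in_pca(self, tiny_matrix_factory):
        rows = [("chr1", i + 1, i % 7, 10) for i in range(30)]
        other = [("chr1", i + 1, (i * 3) % 7, 10) for i in range(30)]
        mat = tiny_matrix_factory({"s1": rows, "s2": rows, "s3": other})
        coords, evr = methylation_pca(mat, n_components=2)
        np.testing.assert_allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-9)
        assert evr.sum() <= 1.0 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()  # non-increasing

    def test_too_few_complete_sites_rejected(self, tiny_matrix_factory):
        mat = tiny_matrix_factory({"s1": [("chr1", 1, 3, 3)],
                                   "s2": [("chr1", 1, 2, 4)]})
        with pytest.raises(ValueError, match="complete"):
            methylation_pca(mat, n_components=2)

    def test_stages_separate_in_pca(self, default_matrix):
        from sklearn.metrics import silhouette_score

        coords, _ = methylation_pca(default_matrix, n_components=2)
        stages = [s.split("_")[0] for s in coords.index]
        assert silhouette_score(coords.to_numpy(), stages) > 0


class TestBedgraph:
    def test_roundtrip_values(self, tiny_matrix_factory, tmp_path):
        mat = tiny_matrix_factory({"s1": [("chr1", 5, 3, 2)]})
        path = tmp_path / "s1.bedGraph"
        methylome.write_bedgraph(mat, "s1", path)
        chrom, start, end, value = path.read_text().split()
        assert (chrom, int(start), int(end)) == ("chr1", 4, 5)
        assert float(value) == pytest.approx(0.6)
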