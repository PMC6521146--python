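import numpy as np
import pandas as pd
import pytest

from regulasso import (
    BindingMatrix,
    ExpressionMatrix,
    aggregate_mirna_isoforms,
    assign_subtype,
    average_gene_methylation,
    filter_missing,
    intersect_common,
    log_transform,
    map_peaks_to_promoters,
)
from regulasso.preprocess import read_dataset
from regulasso.simulate import write_dataset


class TestLogTransform:
    @pytest.mark.parametrize("raw,expected", [(3.0, 2.0), (0.0, 0.0), (1023.0, 10.0)])
    def test_values(self, raw, expected):
        out = log_transform(pd.DataFrame({"s1": [raw]}, index=["g1"]))
        assert out.values.iloc[0, 0] == pytest.approx(expected)

    def test_missing_preserved(self):
        out = log_transform(pd.DataFrame({"s1": [np.nan], "s2": [1.0]}, index=["g1"]))
        assert np.isnan(out.values.iloc[0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_transform(pd.DataFrame({"s1": [-1.0]}, index=["g1"]))

    def test_double_transform_refused(self):
        with pytest.raises(ValueError, match="already log2"):
            log_transform(pd.DataFrame({"s1": [1.0]}, index=["g1"]), unit="gene-RSEM-log2")


class TestAggregateMirnaIsoforms:
    def test_isoforms_summed_then_logged(self):
        table = pd.DataFrame(
            {
                "isoform": ["i1", "i2"],
                "mature_id": ["miR-a", "miR-a"],
                "sample": ["s1", "s1"],
                "rpm": [1.0, 2.0],
            }
        )
        out = aggregate_mirna_isoforms(table)
        assert out.values.loc["miR-a", "s1"] == pytest.approx(2.0)  # log2(1+2+1)

    def test_zero_rpm(self):
        table = pd.DataFrame(
            {"isoform": ["i1"], "mature_id": ["miR-a"], "sample": ["s1"], "rpm": [0.0]}
        )
        assert aggregate_mirna_isoforms(table).values.loc["miR-a", "s1"] == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        isoforms = [f"i{k}" for k in range(12)]
        rows = []
        for iso in isoforms:
            for s in ["s1", "s2", "s3"]:
                rows.append(
                    {
                        "isoform": iso,
                        "mature_id": f"miR-{int(iso[1:]) % 4}",
                        "sample": s,
                        "rpm": float(rng.uniform(0, 50)),
                    }
                )
        table = pd.DataFrame(rows)
        out = aggregate_mirna_isoforms(table)
        # independent loop-based recomputation
        for m in out.values.index:
            for s in out.values.columns:
                total = sum(
                    r["rpm"]
                    for _, r in table.iterrows()
                    if r["mature_id"] == m and r["sample"] == s
                )
                assert out.values.loc[m, s] == pytest.approx(np.log2(total + 1))

    def test_duplicate_rows_rejected(self):
        table = pd.DataFrame(
            {
                "isoform": ["i1", "i1"],
                "mature_id": ["miR-a", "miR-a"],
                "sample": ["s1", "s1"],
                "rpm": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_mirna_isoforms(table)


class TestFilterMissing:
    def _matrix(self, missing_count, n=10):
        vals = [np.nan] * missing_count + [1.0] * (n - missing_count)
        df = pd.DataFrame([vals, [1.0] * n], index=["gA", "gB"])
        df.columns = [f"s{i}" for i in range(n)]
        return ExpressionMatrix(df)

    def test_row_over_half_removed(self):
        out = filter_missing(self._matrix(6))
        assert list(out.values.index) == ["gB"]

    def test_complete_row_kept(self):
        out = filter_missing(self._matrix(0))
        assert list(out.values.index) == ["gA", "gB"]

    def test_exactly_half_kept(self):
        out = filter_missing(self._matrix(5))
        assert list(out.values.index) == ["gA", "gB"]


class TestAverageGeneMethylation:
    def test_mean_of_probes(self):
        table = pd.DataFrame(
            {
                "probe": ["p1", "p2"],
                "gene": ["gA", "gA"],
                "sample": ["s1", "s1"],
                "beta": [0.2, 0.4],
            }
        )
        assert average_gene_methylation(table).loc["gA", "s1"] == pytest.approx(0.3)

    def test_single_probe(self):
        table = pd.DataFrame(
            {"probe": ["p1"], "gene": ["gA"], "sample": ["s1"], "beta": [0.7]}
        )
        assert average_gene_methylation(table).loc["gA", "s1"] == pytest.approx(0.7)

    def test_matches_bruteforce_oracle(self, rng):
        rows = []
        for p in range(15):
            for s in ["s1", "s2"]:
                rows.append(
                    {
                        "probe": f"p{p}",
                        "gene": f"g{p % 4}",
                        "sample": s,
                        "beta": float(rng.uniform()),
                    }
                )
        table = pd.DataFrame(rows)
        out = average_gene_methylation(table)
        for g in out.index:
            for s in out.columns:
                betas = [
                    r["beta"]
                    for _, r in table.iterrows()
                    if r["gene"] == g and r["sample"] == s
                ]
                assert out.loc[g, s] == pytest.approx(np.mean(betas))

    def test_out_of_range_beta_rejected(self):
        table = pd.DataFrame(
            {"probe": ["p1"], "gene": ["gA"], "sample": ["s1"], "beta": [1.2]}
        )
        with pytest.raises(ValueError, match="beta"):
            average_gene_methylation(table)


@pytest.mark.parametrize(
    "er,pr,her2,expected",
    [
        ("+", "-", "-", "LumA"),
        ("-", "+", "-", "LumA"),
        ("+", "+", "-", "LumA"),
        ("+", "-", "+", "LumB"),
        ("-", "+", "+", "LumB"),
        ("-", "-", "+", "Her2"),
        ("-", "-", "-", "TN"),
        ("missing", "-", "-", "unclassified"),
        ("-", "equivocal", "+", "unclassified"),
        ("+", "-", "missing", "unclassified"),
    ],
)
def test_assign_subtype(er, pr, her2, expected):
    assert assign_subtype(er, pr, her2) == expected


class TestMapPeaksToPromoters:
    TSS = pd.DataFrame(
        {
            "gene": ["gPlus", "gMinus"],
            "chrom": ["chr1", "chr1"],
            "position": [10000, 50000],
            "strand": ["+", "-"],
        }
    )

    def _peaks(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    def test_peak_in_plus_strand_window(self):
        peaks = self._peaks([("chr1", 9000, 9100, "TF1", 5.0, ".")])
        out = map_peaks_to_promoters(peaks, self.TSS)
        assert out.counts.loc["gPlus", "TF1"] == pytest.approx(5.0)

    def test_multiple_peaks_averaged(self):
        peaks = self._peaks(
            [
                ("chr1", 9000, 9100, "TF1", 4.0, "."),
                ("chr1", 9500, 9600, "TF1", 6.0, "."),
            ]
        )
        out = map_peaks_to_promoters(peaks, self.TSS)
        assert out.counts.loc["gPlus", "TF1"] == pytest.approx(5.0)

    def test_half_open_boundary_no_overlap(self):
        # + strand promoter is [8000, 10200); a peak ending at 8000 misses it
        peaks = self._peaks([("chr1", 7900, 8000, "TF1", 5.0, ".")])
        out = map_peaks_to_promoters(peaks, self.TSS)
        assert out.counts.loc["gPlus", "TF1"] == 0.0

    def test_one_bp_overlap_counts(self):
        peaks = self._peaks([("chr1", 7900, 8001, "TF1", 5.0, ".")])
        out = map_peaks_to_promoters(peaks, self.TSS)
        assert out.counts.loc["gPlus", "TF1"] == pytest.approx(5.0)

    def test_minus_strand_window(self):
        # - strand promoter is [TSS-200, TSS+2000) = [49800, 52000)
        peaks = self._peaks(
            [
                ("chr1", 51500, 51600, "TF2", 3.0, "."),
                ("chr1", 49000, 49700, "TF2", 9.0, "."),  # misses
            ]
        )
        out = map_peaks_to_promoters(peaks, self.TSS)
        assert out.counts.loc["gMinus", "TF2"] == pytest.approx(3.0)

    def test_unknown_strand_rejected(self):
        tss = self.TSS.assign(strand=["*", "-"])
        with pytest.raises(ValueError, match="strand"):
            map_peaks_to_promoters(self._peaks([("chr1", 0, 1, "T", 1.0, ".")]), tss)


class TestIntersectCommon:
    def test_round_trip_on_generated_data(self, tiny, tmp_path):
        dataset, truth = tiny
        write_dataset(dataset, truth, tmp_path)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(
            back.tumor_expression.values, dataset.tumor_expression.values
        )
        pd.testing.assert_frame_equal(back.cnv, dataset.cnv)
        pd.testing.assert_frame_equal(back.methylation, dataset.methylation)
        pd.testing.assert_frame_equal(
            back.mirna_binding.counts, dataset.mirna_binding.counts
        )
        pd.testing.assert_series_equal(
            back.subtype, dataset.subtype, check_names=False
        )

    def test_subsets_to_common_ids(self, tiny):
        dataset, _ = tiny
        # drop one gene from CNV and one tumor from methylation
        cnv = dataset.cnv.iloc[1:]
        meth = dataset.methylation.iloc[:, 1:]
        out = intersect_common(
            dataset.tumor_expression,
            dataset.normal_expression,
            dataset.mirna_expression,
            dataset.mirna_normal_expression,
            cnv,
            meth,
            dataset.tf_binding,
            dataset.mirna_binding,
            dataset.subtype,
        )
        assert set(out.genes) == set(dataset.genes) - {dataset.genes[0]}
        assert set(out.tumors) == set(dataset.tumors) - {dataset.tumors[0]}

    def test_row_order_does_not_matter(self, tiny):
        dataset, _ = tiny
        shuffled = dataset.cnv.sample(frac=1.0, random_state=1)
        out = intersect_common(
            dataset.tumor_expression,
            dataset.normal_expression,
            dataset.mirna_expression,
            dataset.mirna_normal_expression,
            shuffled,
            dataset.methylation,
            dataset.tf_binding,
            dataset.mirna_binding,
            dataset.subtype,
        )
        pd.testing.assert_frame_equal(out.cnv, dataset.cnv)

    def test_disjoint_samples_rejected(self, tiny):
        dataset, _ = tiny
        cnv = dataset.cnv.rename(columns=lambda c: "x" + c)
        with pytest.raises(ValueError, match="common tumor samples"):
            intersect_common(
                dataset.tumor_expression,
                dataset.normal_expression,
                dataset.mirna_expression,
                dataset.mirna_normal_expression,
                cnv,
                dataset.methylation,
                dataset.tf_binding,
                dataset.mirna_binding,
                dataset.subtype,
            )
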