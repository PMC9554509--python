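import numpy as np
import pytest

from lohmil import facets_io
from lohmil.facets_io import (
    CNCF_COLUMNS,
    DEFAULT_FEATURES,
    CncfFormatError,
    CncfParseError,
    ConfigurationError,
    NormalizationBounds,
    SegmentRecord,
    apply_minmax,
    assemble_bags,
    extract_features,
    fit_minmax,
    read_cncf,
    read_labels,
    write_cncf,
)

from conftest import CNCF_HEADER, CNCF_ROWS


class TestReadCncf:
    def test_reads_three_records_in_order(self, cncf_file):
        records = read_cncf(cncf_file)
        assert len(records) == 3
        first = records[0]
        assert first.chrom == 1
        assert first.seg == 1
        assert first.num_mark == 120
        assert first.nhet == 35
        assert first.cnlr_median == pytest.approx(-0.25)
        assert first.segclust == 2
        assert first.cnlr_median_clust == pytest.approx(-0.21)
        assert first.start == 1_000_000
        assert first.end == 5_000_000
        assert first.mafR == pytest.approx(1.5)
        assert first.mafR_clust == pytest.approx(1.4)
        assert first.cf_em == pytest.approx(0.8)
        assert first.tcn_em == pytest.approx(2.0)
        assert first.lcn_em == pytest.approx(1.0)

    def test_chrom_x_encoded_as_23(self, cncf_file):
        records = read_cncf(cncf_file)
        assert records[2].chrom == 23

    def test_na_cell_becomes_missing(self, make_cncf):
        row = CNCF_ROWS[0].rsplit("\t", 1)[0] + "\tNA"
        path = make_cncf(CNCF_HEADER, [row])
        # expected record written by hand: identical to row 0 except lcn_em
        expected = SegmentRecord(
            chrom=1, seg=1, num_mark=120, nhet=35, cnlr_median=-0.25,
            segclust=2, cnlr_median_clust=-0.21, start=1_000_000,
            end=5_000_000, mafR=1.5, mafR_clust=1.4, cf_em=0.8,
            tcn_em=2.0, lcn_em=None,
        )
        assert read_cncf(path)[0] == expected

    def test_missing_column_names_it(self, make_cncf):
        header = CNCF_HEADER.replace("\tmafR\t", "\t")
        rows = ["\t".join(r.split("\t")[:9] + r.split("\t")[10:]) for r in CNCF_ROWS]
        path = make_cncf(header, rows)
        with pytest.raises(CncfFormatError, match="mafR"):
            read_cncf(path)

    def test_non_numeric_cell_reports_row(self, make_cncf):
        bad = CNCF_ROWS[1].replace("0.5", "oops", 1)
        path = make_cncf(CNCF_HEADER, [CNCF_ROWS[0], bad])
        with pytest.raises(CncfParseError, match="row 3"):
            read_cncf(path)

    def test_underscore_headers_accepted(self, make_cncf):
        header = CNCF_HEADER.replace(".", "_").upper()
        path = make_cncf(header, CNCF_ROWS)
        assert len(read_cncf(path)) == 3

    def test_roundtrip_write_read(self, tmp_path, cncf_file):
        records = read_cncf(cncf_file)
        out = tmp_path / "rt_cncf.tsv"
        write_cncf(records, out)
        assert read_cncf(out) == records


class TestExtractFeatures:
    def test_two_feature_projection(self):
        rec = SegmentRecord(nhet=5, cnlr_median=-0.2)
        table = extract_features([rec], ("nhet", "cnlr_median"))
        assert table.values.tolist() == [[5.0, -0.2]]
        assert not table.imputed[0]

    def test_default_nine_features_order(self, cncf_file):
        records = read_cncf(cncf_file)
        table = extract_features(records)
        assert table.values.shape == (3, 9)
        assert table.feature_names == DEFAULT_FEATURES
        np.testing.assert_allclose(
            table.values[0],
            [35, -0.25, 1.5, 1.4, 1_000_000, 5_000_000, 0.8, 2, 1],
        )

    def test_missing_value_imputed_and_flagged(self):
        rec = SegmentRecord(nhet=5, cnlr_median=-0.2, mafR=1.0, mafR_clust=1.0,
                            start=1, end=2, cf_em=0.5, tcn_em=2.0, lcn_em=None)
        table = extract_features([rec])
        assert table.values[0, DEFAULT_FEATURES.index("lcn_em")] == 0.0
        assert table.imputed[0]
        assert table.n_imputed == 1

    def test_unknown_feature_name(self):
        with pytest.raises(ConfigurationError):
            extract_features([SegmentRecord()], ("nhet", "bogus"))

    def test_projection_permutes_with_names(self, cncf_file):
        records = read_cncf(cncf_file)
        fwd = extract_features(records, ("nhet", "mafR", "tcn_em"))
        rev = extract_features(records, ("tcn_em", "mafR", "nhet"))
        np.testing.assert_array_equal(fwd.values[:, ::-1], rev.values)


class TestMinMax:
    def test_simple_column(self):
        v = np.array([[0.0], [5.0], [10.0]])
        b = fit_minmax(v)
        assert b.minimum[0] == 0 and b.maximum[0] == 10
        np.testing.assert_allclose(apply_minmax(v, b).ravel(), [0, 0.5, 1])

    def test_single_vector_degenerate(self):
        b = fit_minmax(np.array([[3.0, -1.0]]))
        np.testing.assert_array_equal(b.minimum, b.maximum)

    def test_constant_column_maps_to_zero(self):
        v = np.array([[1.0, 7.0], [2.0, 7.0]])
        b = fit_minmax(v)
        out = apply_minmax(v, b)
        np.testing.assert_allclose(out[:, 1], [0.0, 0.0])
        np.testing.assert_allclose(out[:, 0], [0.0, 1.0])

    def test_out_of_bounds_clipped(self):
        b = NormalizationBounds(np.array([0.0]), np.array([10.0]))
        assert apply_minmax(np.array([[12.0]]), b)[0, 0] == 1.0
        assert apply_minmax(np.array([[-3.0]]), b)[0, 0] == 0.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_minmax(np.empty((0, 3)))

    def test_dimension_mismatch_errors(self):
        b = NormalizationBounds(np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            apply_minmax(np.zeros((1, 3)), b)


class TestAssembleBags:
    def test_sizes_and_labels(self):
        bags = assemble_bags(
            {"s1": np.zeros((3, 2)), "s2": np.zeros((5, 2))},
            {"s1": 1, "s2": -1},
        )
        assert [b.n_instances for b in bags] == [3, 5]
        assert [b.label for b in bags] == [1, -1]

    def test_unlabeled_sample(self):
        bags = assemble_bags({"s1": np.zeros((2, 2))})
        assert bags[0].label is None

    def test_zero_segments_errors(self):
        with pytest.raises(ValueError, match="zero segments"):
            assemble_bags({"s1": np.zeros((0, 2))})

    def test_label_without_data_errors(self):
        with pytest.raises(ValueError):
            assemble_bags({"s1": np.zeros((2, 2))}, {"s2": 1})


class TestLabels:
    def test_read_labels(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("s1\t1\ns2\t-1\ns3\tpos\ns4\tNEG\n")
        assert read_labels(path) == {"s1": 1, "s2": -1, "s3": 1, "s4": -1}

    def test_header_row_tolerated(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("sample_id\tlabel\ns1\t1\n")
        assert read_labels(path) == {"s1": 1}

    def test_bad_label_errors(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("s1\tmaybe\n")
        with pytest.raises(CncfFormatError):
            read_labels(path)
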