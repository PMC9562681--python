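import gzip

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from topotag.stio import (
    ExpressionMatrix,
    FormatError,
    SlideBundle,
    SpotPosition,
    read_expression,
    read_gmt,
    read_point_clouds,
    read_positions,
    write_expression,
    write_gmt,
    write_point_clouds,
    write_positions,
)


def _write_triplet(tmp_path, mtx_body, barcodes, features):
    (tmp_path / "matrix.mtx").write_text(mtx_body)
    (tmp_path / "barcodes.tsv").write_text("".join(b + "\n" for b in barcodes))
    (tmp_path / "features.tsv").write_text("".join(f + "\n" for f in features))
    return (tmp_path / "matrix.mtx", tmp_path / "barcodes.tsv",
            tmp_path / "features.tsv")


class TestExpression:
    def test_direct_transcription_with_orientation_flip(self, tmp_path):
        # on disk: 3 genes x 2 spots; in memory: spots x genes
        body = "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 2\n"
        paths = _write_triplet(tmp_path, body, ["S1", "S2"], ["G1", "G2", "G3"])
        expr = read_expression(*paths)
        expected = pd.DataFrame([[5, 0, 0], [0, 0, 2]],
                                index=["S1", "S2"], columns=["G1", "G2", "G3"])
        pd.testing.assert_frame_equal(expr.counts.astype(int), expected)

    def test_empty_matrix_keeps_declared_dims(self, tmp_path):
        body = "%%MatrixMarket matrix coordinate integer general\n2 3 0\n"
        paths = _write_triplet(tmp_path, body, ["S1", "S2", "S3"], ["G1", "G2"])
        expr = read_expression(*paths)
        assert expr.shape == (3, 2)
        assert (expr.counts.to_numpy() == 0).all()

    def test_round_trip_identity_on_random_sparse(self, tmp_path, rng):
        dense = scipy.sparse.random(
            50, 100, density=0.05, random_state=np.random.RandomState(0),
            data_rvs=lambda n: rng.integers(1, 40, n),
        ).toarray().astype(int)
        expr = ExpressionMatrix(pd.DataFrame(
            dense,
            index=[f"S{i}" for i in range(50)],
            columns=[f"G{j}" for j in range(100)],
        ))
        paths = write_expression(expr, tmp_path)
        back = read_expression(paths["mtx"], paths["barcodes"], paths["features"])
        pd.testing.assert_frame_equal(back.counts.astype(int), expr.counts)

    def test_dimension_mismatch_names_offending_file(self, tmp_path):
        body = "%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 5\n"
        paths = _write_triplet(tmp_path, body, ["S1", "S2"], ["G1", "G2"])
        with pytest.raises(FormatError, match="features"):
            read_expression(*paths)

    def test_gzipped_barcodes_detected_by_extension(self, tmp_path):
        body = "%%MatrixMarket matrix coordinate integer general\n1 1 1\n1 1 7\n"
        (tmp_path / "matrix.mtx").write_text(body)
        with gzip.open(tmp_path / "barcodes.tsv.gz", "wt") as fh:
            fh.write("S1\n")
        (tmp_path / "features.tsv").write_text("G1\n")
        expr = read_expression(tmp_path / "matrix.mtx",
                               tmp_path / "barcodes.tsv.gz",
                               tmp_path / "features.tsv")
        assert expr.counts.loc["S1", "G1"] == 7


class TestPositions:
    def test_headerless_row_parsed(self, tmp_path):
        p = tmp_path / "pos.csv"
        p.write_text("AAAC-1,1,0,0,1200,3400\n")
        (pos,) = read_positions(p)
        assert pos == SpotPosition("AAAC-1", True, 0, 0, 1200.0, 3400.0)

    def test_header_dialect_auto_detected(self, tmp_path):
        p1 = tmp_path / "v1.csv"
        p1.write_text("AAAC-1,0,2,3,10,20\nAAAC-2,1,2,4,10,400\n")
        p2 = tmp_path / "v2.csv"
        p2.write_text(
            "barcode,in_tissue,array_row,array_col,pxl_row_in_fullres,pxl_col_in_fullres\n"
            "AAAC-1,0,2,3,10,20\nAAAC-2,1,2,4,10,400\n"
        )
        assert read_positions(p1) == read_positions(p2)

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        p = tmp_path / "pos.csv"
        p.write_text("")
        assert read_positions(p) == []

    def test_non_numeric_pixel_field_reports_row(self, tmp_path):
        p = tmp_path / "pos.csv"
        p.write_text("AAAC-1,1,0,0,1200,3400\nAAAC-2,1,0,1,oops,3400\n")
        with pytest.raises(FormatError, match="row 2"):
            read_positions(p)

    def test_write_read_round_trip(self, tmp_path):
        positions = [
            SpotPosition("S1", True, 0, 0, 175.0, 175.0),
            SpotPosition("S2", False, 0, 1, 175.0, 525.5),
        ]
        path = write_positions(positions, tmp_path / "pos.csv")
        assert read_positions(path) == positions


class TestPointClouds:
    def test_round_trip(self, tmp_path, rng):
        clouds = {
            "S1": rng.uniform(0, 350, (5, 2)),
            "S2": rng.uniform(0, 350, (3, 2)),
        }
        path = write_point_clouds(clouds, tmp_path / "pc.tsv")
        back = read_point_clouds(path)
        assert set(back) == {"S1", "S2"}
        for k in clouds:
            np.testing.assert_array_equal(back[k], clouds[k])


class TestGmt:
    def test_duplicates_within_term_deduplicated(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("GO:1\tdesc\tA\tB\tB\n")
        assert read_gmt(p) == {"GO:1": {"A", "B"}}

    def test_terms_sharing_genes_parsed_independently(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("GO:1\td\tA\tB\nGO:2\td\tB\tC\n")
        assert read_gmt(p) == {"GO:1": {"A", "B"}, "GO:2": {"B", "C"}}

    def test_short_lines_skipped_empty_file_empty_map(self, tmp_path, caplog):
        p = tmp_path / "t.gmt"
        p.write_text("GO:1\tonly-two-fields\nGO:2\td\tA\n")
        assert read_gmt(p) == {"GO:2": {"A"}}
        p2 = tmp_path / "empty.gmt"
        p2.write_text("")
        assert read_gmt(p2) == {}

    def test_write_read_round_trip(self, tmp_path):
        terms = {"GO:1": {"A", "B"}, "GO:2": {"C"}}
        path = write_gmt(terms, tmp_path / "t.gmt")
        assert read_gmt(path) == terms


class TestSlideBundle:
    def test_spot_id_mismatch_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1], [2]], index=["S1", "S2"], columns=["G1"]))
        positions = [SpotPosition("S1", True, 0, 0, 10, 10)]
        with pytest.raises(FormatError, match="disagree"):
            SlideBundle(expression=expr, positions=positions)

    def test_duplicate_positions_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1]], index=["S1"], columns=["G1"]))
        positions = [SpotPosition("S1", True, 0, 0, 10, 10),
                     SpotPosition("S1", True, 0, 1, 10, 20)]
        with pytest.raises(FormatError, match="duplicate"):
            SlideBundle(expression=expr, positions=positions)
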