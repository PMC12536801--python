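import numpy as np
import pytest

from spomag import (
    FeatureMatrix,
    align_matrix,
    build_matrix,
    encode_genome,
    parse_emapper,
)
from spomag.features import (
    AnnotationRecord,
    AnnotationSchemaError,
    MatrixError,
)
from .conftest import make_matrix

HEADER = "#query\tseed_ortholog\tevalue\tscore\tPreferred_name\tKEGG_ko\n"


def _annfile(tmp_path, name, rows, header=HEADER):
    path = tmp_path / name
    path.write_text("## comment\n" + header + "".join(rows))
    return path


class TestParseEmapper:
    def test_ko_token_split(self, tmp_path):
        path = _annfile(tmp_path, "g.tsv",
                        ["orf1\ts\t1e-30\t100\t-\tko:K06382,ko:K06381\n"])
        (rec,) = parse_emapper(path)
        assert rec.ko_ids == {"K06382", "K06381"}
        assert rec.preferred_name is None

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("## only comments\n## nothing else\n")
        assert parse_emapper(path) == []

    def test_evalue_filter_drops_weak_hits(self, tmp_path):
        path = _annfile(tmp_path, "g.tsv", [
            "orf1\ts\t1e-3\t10\tspoVD\t-\n",
            "orf2\ts\t1e-30\t99\tgerD\t-\n",
        ])
        recs = parse_emapper(path, max_evalue=1e-5)
        assert [r.preferred_name for r in recs] == ["gerD"]

    def test_bad_header_echoes_observed(self, tmp_path):
        path = _annfile(tmp_path, "g.tsv", ["orf1\tx\n"],
                        header="#query\tsomething\n")
        with pytest.raises(AnnotationSchemaError, match="something"):
            parse_emapper(path)

    def test_dash_fields_become_absent(self, tmp_path):
        path = _annfile(tmp_path, "g.tsv", ["orf1\ts\t-\t-\t-\t-\n"])
        (rec,) = parse_emapper(path)
        assert rec.evalue is None and rec.preferred_name is None
        assert rec.ko_ids == frozenset()


class TestEncodeGenome:
    def test_name_match(self, small_catalog):
        vec = encode_genome([AnnotationRecord("o1", preferred_name="spoVD")],
                            small_catalog)
        assert vec.tolist() == [1, 0, 0, 0, 0, 0, 0, 0]

    def test_empty_records_all_zero(self, small_catalog):
        assert encode_genome([], small_catalog).sum() == 0

    def test_ko_only_match(self, small_catalog):
        vec = encode_genome(
            [AnnotationRecord("o1", ko_ids=frozenset({"K06382"}))],
            small_catalog,
        )
        assert vec[small_catalog.gene_symbols.index("spoIIR")] == 1
        assert vec.sum() == 1

    def test_case_insensitive_and_alias(self, small_catalog):
        vec = encode_genome(
            [AnnotationRecord("o1", preferred_name="SPOVD"),
             AnnotationRecord("o2", preferred_name="cotP1")],
            small_catalog,
        )
        assert vec[small_catalog.gene_symbols.index("spoVD")] == 1
        assert vec[small_catalog.gene_symbols.index("cotP")] == 1

    def test_idempotent_under_duplication(self, small_catalog):
        recs = [AnnotationRecord("o1", preferred_name="gerD"),
                AnnotationRecord("o2", ko_ids=frozenset({"K03092"}))]
        base = encode_genome(recs, small_catalog)
        doubled = encode_genome(recs * 3, small_catalog)
        assert (base == doubled).all()

    def test_removing_records_never_adds_presence(self, small_catalog):
        recs = [AnnotationRecord(f"o{i}", preferred_name=s)
                for i, s in enumerate(small_catalog.gene_symbols)]
        full = encode_genome(recs, small_catalog)
        for i in range(len(recs)):
            reduced = encode_genome(recs[:i] + recs[i + 1:], small_catalog)
            assert ((reduced == 1) <= (full == 1)).all()


class TestBuildMatrix:
    def test_empty_file_gives_zero_row(self, tmp_path, small_catalog):
        _annfile(tmp_path, "a.tsv", ["orf1\ts\t1e-30\t9\tspoVD\t-\n"])
        (tmp_path / "b.tsv").write_text("## empty genome\n")
        m = build_matrix(tmp_path, small_catalog)
        assert m.genome_ids == ["a", "b"]
        assert m.values[0].sum() == 1 and m.values[1].sum() == 0

    def test_stray_label_warned_and_ignored(self, tmp_path, small_catalog, caplog):
        _annfile(tmp_path, "a.tsv", ["orf1\ts\t1e-30\t9\tspoVD\t-\n"])
        m = build_matrix(tmp_path, small_catalog,
                         labels={"a": "Sporulating", "ghost": "Sporulating"})
        assert m.labels == {"a": "Sporulating"}
        assert any("ghost" in r.message for r in caplog.records)

    def test_rerun_is_byte_identical(self, tmp_path, small_catalog):
        (tmp_path / "ann").mkdir()
        _annfile(tmp_path / "ann", "a.tsv", ["orf1\ts\t1e-30\t9\tspoVD\t-\n"])
        out1, out2 = tmp_path / "m1.csv", tmp_path / "m2.csv"
        build_matrix(tmp_path / "ann", small_catalog).to_csv(out1)
        build_matrix(tmp_path / "ann", small_catalog).to_csv(out2)
        assert out1.read_bytes() == out2.read_bytes()


class TestAlignMatrix:
    def test_permuted_columns_restored(self, small_catalog):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 2, (5, 8)))
        m.gene_symbols = list(small_catalog.gene_symbols)
        perm = rng.permutation(8)
        shuffled = FeatureMatrix(
            genome_ids=m.genome_ids,
            gene_symbols=[m.gene_symbols[j] for j in perm],
            values=m.values[:, perm],
        )
        aligned = align_matrix(shuffled, small_catalog)
        assert aligned.gene_symbols == small_catalog.gene_symbols
        assert (aligned.values == m.values).all()

    def test_missing_gene_zero_filled(self, small_catalog, caplog):
        m = FeatureMatrix(
            genome_ids=["g1"],
            gene_symbols=small_catalog.gene_symbols[:-1],
            values=np.ones((1, 7), dtype=np.uint8),
        )
        aligned = align_matrix(m, small_catalog)
        assert aligned.values[0, -1] == 0
        assert any("zero-filling" in r.message for r in caplog.records)

    def test_unknown_column_dropped(self, small_catalog, caplog):
        m = FeatureMatrix(
            genome_ids=["g1"],
            gene_symbols=small_catalog.gene_symbols + ["mystery"],
            values=np.ones((1, 9), dtype=np.uint8),
        )
        aligned = align_matrix(m, small_catalog)
        assert aligned.n_genes == 8
        assert any("non-catalog" in r.message for r in caplog.records)

    def test_too_few_genes_is_hard_error(self, small_catalog):
        m = make_matrix(np.ones((2, 3)), gene_prefix="unknown")
        with pytest.raises(MatrixError, match="refusing"):
            align_matrix(m, small_catalog)


class TestFeatureMatrixValidation:
    def test_non_binary_rejected(self):
        with pytest.raises(MatrixError, match="0 or 1"):
            make_matrix(np.array([[0, 2]]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(MatrixError, match="duplicate"):
            FeatureMatrix(["a", "a"], ["f1"], np.zeros((2, 1)))

    def test_bad_label_value_rejected(self):
        with pytest.raises(MatrixError, match="labels"):
            FeatureMatrix(["a"], ["f1"], np.zeros((1, 1)),
                          labels={"a": "maybe"})

    def test_csv_roundtrip(self, tmp_path):
        m = make_matrix(np.eye(3, dtype=np.uint8))
        m.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(tmp_path / "m.csv")
        assert back.genome_ids == m.genome_ids
        assert (back.values == m.values).all()
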