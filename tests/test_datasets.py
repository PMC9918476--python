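"""Containers, readers/writers, filtering and the log2 transform."""

import numpy as np
import pandas as pd
import pytest

from sigspec.datasets import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    ParseError,
    filter_samples,
    read_expression,
    read_gmt,
    read_metadata,
    to_log2,
    write_expression,
    write_gmt,
    write_metadata,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadExpression:
    def test_tsv_identity(self, tmp_path):
        p = _write(tmp_path / "e.tsv",
                   "gene_id\tS1\tS2\nKRT5\t1\t2\nGATA6\t3\t4\nPRSS1\t5\t6\n")
        ds = read_expression(p)
        assert ds.values.shape == (3, 2)
        assert ds.gene_ids == ["KRT5", "GATA6", "PRSS1"]
        assert ds.sample_ids == ["S1", "S2"]
        assert ds.scale == "linear"

    def test_csv_matches_tsv(self, tmp_path):
        tsv = _write(tmp_path / "e.tsv", "gene_id\tS1\tS2\nA\t1\t2\nB\t3\t4\n")
        csv = _write(tmp_path / "e.csv", "gene_id,S1,S2\nA,1,2\nB,3,4\n")
        pd.testing.assert_frame_equal(read_expression(tsv).values, read_expression(csv).values)

    def test_duplicate_gene_named(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "gene_id\tS1\nKRT5\t1\nKRT5\t2\n")
        with pytest.raises(ParseError, match="KRT5"):
            read_expression(p)

    def test_non_numeric_cell_located(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "gene_id\tS1\tS2\nA\t1\tx\nB\t3\t4\n")
        with pytest.raises(ParseError, match="'x'.*'A'.*'S2'"):
            read_expression(p)

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(5, 3)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(3)])
        ds = ExpressionDataset(values=vals, scale="log2", log2_pseudocount=1.0)
        out = tmp_path / "rt.tsv"
        write_expression(ds, out)
        back = read_expression(out, scale="log2", log2_pseudocount=1.0)
        assert back.gene_ids == ds.gene_ids and back.sample_ids == ds.sample_ids
        assert np.array_equal(back.values.to_numpy(), ds.values.to_numpy())


class TestDatasetInvariants:
    def test_negative_linear_rejected(self):
        vals = pd.DataFrame([[-1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="negative"):
            ExpressionDataset(values=vals, scale="linear")

    def test_log2_requires_pseudocount(self):
        vals = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="pseudocount"):
            ExpressionDataset(values=vals, scale="log2")

    def test_extra_metadata_rows_error(self):
        vals = pd.DataFrame([[1.0]], index=["g"], columns=["s1"])
        meta = pd.DataFrame({"tissue_type": ["caf", "caf"]}, index=["s1", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            ExpressionDataset(values=vals, scale="linear", metadata=meta)


class TestGmt:
    def test_basic_line(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "SetA\tdesc\tG1\tG2\n")
        coll = read_gmt(p)
        assert coll["SetA"].genes == ("G1", "G2")
        assert coll["SetA"].source == "desc"

    def test_duplicate_gene_deduped(self, tmp_path, caplog):
        p = _write(tmp_path / "s.gmt", "SetA\tdesc\tG1\tG1\n")
        with caplog.at_level("WARNING"):
            coll = read_gmt(p)
        assert coll["SetA"].genes == ("G1",)
        assert any("duplicate" in r.message for r in caplog.records)

    def test_empty_file_valid(self, tmp_path):
        assert len(read_gmt(_write(tmp_path / "s.gmt", ""))) == 0

    def test_short_line_reports_lineno(self, tmp_path):
        p = _write(tmp_path / "s.gmt", "SetA\tdesc\tG1\nBad\tonly2fields\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gmt(p)

    def test_roundtrip(self, tmp_path):
        coll = GeneSetCollection([GeneSet("A", ("G1", "G2"), "src")])
        out = tmp_path / "out.gmt"
        write_gmt(coll, out)
        back = read_gmt(out)
        assert back["A"].genes == ("G1", "G2") and back["A"].source == "src"


class TestMetadata:
    def test_missing_tokens_and_purity(self, tmp_path):
        p = _write(
            tmp_path / "m.tsv",
            "sample_id\ttissue_type\tpurity\nS1\tprimary_tumor\t0.7\nS2\t\tNA\n",
        )
        meta = read_metadata(p)
        assert meta.loc["S1", "purity"] == 0.7
        assert pd.isna(meta.loc["S2", "tissue_type"]) and pd.isna(meta.loc["S2", "purity"])

    def test_purity_out_of_range(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "sample_id\tpurity\nS1\t1.5\n")
        with pytest.raises(ValueError, match="S1"):
            read_metadata(p)

    def test_roundtrip(self, tmp_path):
        p = _write(
            tmp_path / "m.tsv",
            "sample_id\ttissue_type\tpair_id\nS1\tprimary_tumor\tp1\nS2\tcell_line\tNA\n",
        )
        meta = read_metadata(p)
        out = tmp_path / "m2.tsv"
        write_metadata(meta, out)
        pd.testing.assert_frame_equal(read_metadata(out), meta)


class TestFilterSamples:
    def test_boolean_clause_count(self, tiny_dataset):
        out = filter_samples(tiny_dataset, {"histology_confirmed": True})
        assert out.sample_ids == ["S1", "S2", "S3"]

    def test_empty_predicate_identity(self, tiny_dataset):
        out = filter_samples(tiny_dataset, {})
        pd.testing.assert_frame_equal(out.values, tiny_dataset.values)

    def test_unknown_field_lists_available(self, tiny_dataset):
        with pytest.raises(KeyError, match="tissue_type"):
            filter_samples(tiny_dataset, {"flavor": "x"})

    def test_matches_truth_tally(self, default_cohort):
        ds, truth, _ = default_cohort
        out = filter_samples(ds, {"tissue_type": "primary_tumor"})
        assert out.n_samples == (truth.samples["tissue_type"] == "primary_tumor").sum()

    def test_conjunction_order_independent(self, tiny_dataset):
        a = filter_samples(
            filter_samples(tiny_dataset, {"tissue_type": "primary_tumor"}),
            {"purity": lambda v: v >= 0.6},
        )
        b = filter_samples(
            filter_samples(tiny_dataset, {"purity": lambda v: v >= 0.6}),
            {"tissue_type": "primary_tumor"},
        )
        c = filter_samples(
            tiny_dataset,
            {"tissue_type": "primary_tumor", "purity": lambda v: v >= 0.6},
        )
        assert a.sample_ids == b.sample_ids == c.sample_ids == ["S2"]

    def test_original_untouched(self, tiny_dataset):
        before = tiny_dataset.values.copy()
        filter_samples(tiny_dataset, {"tissue_type": "caf"})
        pd.testing.assert_frame_equal(tiny_dataset.values, before)


class TestToLog2:
    def test_known_values(self):
        vals = pd.DataFrame([[0.0, 3.0]], index=["g"], columns=["a", "b"])
        ds = to_log2(ExpressionDataset(values=vals), pseudocount=1.0)
        assert ds.values.loc["g", "a"] == 0.0
        assert ds.values.loc["g", "b"] == 2.0
        assert ds.scale == "log2" and ds.log2_pseudocount == 1.0

    def test_elementwise_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(0, 50, size=(4, 4))
        vals = pd.DataFrame(raw, index=list("abcd"), columns=list("wxyz"))
        ds = to_log2(ExpressionDataset(values=vals), pseudocount=0.5)
        import math
        for i in range(4):
            for j in range(4):
                assert ds.values.iat[i, j] == pytest.approx(math.log2(raw[i, j] + 0.5), abs=1e-12)

    def test_double_transform_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="already log2"):
            to_log2(tiny_dataset)

    def test_bad_pseudocount(self):
        vals = pd.DataFrame([[1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError, match="pseudocount"):
            to_log2(ExpressionDataset(values=vals), pseudocount=0.0)

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 100, size=(10, 3))
        vals = pd.DataFrame(raw, index=[f"g{i}" for i in range(10)], columns=list("abc"))
        ds = to_log2(ExpressionDataset(values=vals))
        for col in "abc":
            assert (
                vals[col].rank(method="first").tolist()
                == ds.values[col].rank(method="first").tolist()
            )
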