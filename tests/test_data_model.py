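"""Containers, GCT / gene-set I/O, taxonomy and set algebra."""

import numpy as np
import pytest

import tissueshift as ts
from tissueshift.errors import (
    EmptyGeneSetError,
    GctFormatError,
    ValidationError,
)


class TestExpressionMatrix:
    def test_rejects_negative_values(self):
        with pytest.raises(ValidationError):
            ts.ExpressionMatrix(["A"], ["T1", "T2"], np.array([[1.0, -0.1]]))

    def test_rejects_shape_mismatch_and_duplicates(self):
        with pytest.raises(ValidationError):
            ts.ExpressionMatrix(["A", "B"], ["T1"], np.array([[1.0]]))
        with pytest.raises(ValidationError):
            ts.ExpressionMatrix(["A", "A"], ["T1"], np.array([[1.0], [2.0]]))

    def test_column_lookup(self, tiny_matrix):
        np.testing.assert_array_equal(
            tiny_matrix.column("Pancreas"), [2.0, 1.0, 3.0, 90.0]
        )
        with pytest.raises(KeyError):
            tiny_matrix.column("Kidney")


class TestGctIO:
    def test_round_trip_is_bit_exact(self, tiny_matrix, tmp_path):
        p = tmp_path / "m.gct"
        ts.write_gct(tiny_matrix, p)
        assert ts.read_gct(p) == tiny_matrix
        # idempotent: a second write of the re-read matrix is byte-identical
        p2 = tmp_path / "m2.gct"
        ts.write_gct(ts.read_gct(p), p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_declared_dimensions_come_from_file(self, tmp_path):
        lines = ["#1.2", "3\t2", "Name\tDescription\tT1\tT2"]
        for i in range(3):
            lines.append(f"ENSG{i}.1\tG{i}\t{i}.0\t{i + 1}.5")
        p = tmp_path / "m.gct"
        p.write_text("\n".join(lines) + "\n")
        em = ts.read_gct(p)
        assert em.n_genes == 3 and em.tissue_ids == ["T1", "T2"]
        assert em.gene_ids == ["G0", "G1", "G2"]  # Description symbol wins

    def test_bad_version_line(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.3\n1\t1\nName\tDescription\tT1\nA\tA\t1.0\n")
        with pytest.raises(GctFormatError):
            ts.read_gct(p)

    def test_dimension_mismatch(self, tmp_path):
        p = tmp_path / "bad.gct"
        p.write_text("#1.2\n5\t1\nName\tDescription\tT1\nA\tA\t1.0\n")
        with pytest.raises(GctFormatError):
            ts.read_gct(p)

    def test_negative_cell_rejected(self, tmp_path):
        p = tmp_path / "neg.gct"
        p.write_text("#1.2\n1\t1\nName\tDescription\tT1\nA\tA\t-2.0\n")
        with pytest.raises(ValidationError):
            ts.read_gct(p)

    def test_duplicate_symbol_keeps_first(self, tmp_path, caplog):
        p = tmp_path / "dup.gct"
        p.write_text(
            "#1.2\n2\t1\nName\tDescription\tT1\nE1\tactb\t1.0\nE2\tACTB\t9.0\n"
        )
        with caplog.at_level("WARNING"):
            em = ts.read_gct(p)
        assert em.gene_ids == ["ACTB"] and em.values[0, 0] == 1.0
        assert any("duplicate" in r.message for r in caplog.records)


class TestGeneSetIO:
    def test_duplicates_collapse_and_scores_parse(self, tmp_path):
        p = tmp_path / "gs.csv"
        p.write_text("gene,score\nSHANK3,1\nmecp2 ,2S\nSHANK3,1\nFMR1,S\nCNTNAP2,3\n")
        gs = ts.read_gene_set(p, name="autism")
        assert len(gs) == 4
        assert gs.genes == {"SHANK3", "MECP2", "FMR1", "CNTNAP2"}
        assert gs.scores["MECP2"] == "2S"

    def test_blank_file_is_empty_set_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("gene,score\n\n,\n , \n")
        with pytest.raises(EmptyGeneSetError):
            ts.read_gene_set(p)

    def test_tsv_dialect_and_default_name(self, tmp_path):
        p = tmp_path / "ataxia.tsv"
        p.write_text("gene\tscore\nATXN1\t\nATXN2\t\n")
        gs = ts.read_gene_set(p)
        assert gs.name == "ataxia" and len(gs) == 2

    def test_missing_gene_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("symbol\nA\n")
        with pytest.raises(ValidationError):
            ts.read_gene_set(p)


class TestSetAlgebra:
    def test_intersect_with_matrix(self, tiny_matrix):
        gs = ts.GeneSet("d", {"ACTB", "GFAP", "NOTPRESENT"})
        sub, report = ts.intersect_with_matrix(gs, tiny_matrix)
        assert sub.genes == {"ACTB", "GFAP"}
        assert report.absent == ["NOTPRESENT"] and report.n_absent == 1

    def test_intersect_disjoint_and_subset(self, tiny_matrix):
        empty, rep = ts.intersect_with_matrix(ts.GeneSet("d", {"X", "Y"}), tiny_matrix)
        assert not empty.genes and rep.n_absent == 2
        full, rep2 = ts.intersect_with_matrix(ts.GeneSet("d", {"INS"}), tiny_matrix)
        assert full.genes == {"INS"} and rep2.n_absent == 0

    def test_intersect_is_idempotent(self, tiny_matrix):
        gs = ts.GeneSet("d", {"ACTB", "ZZZ"})
        once, _ = ts.intersect_with_matrix(gs, tiny_matrix)
        twice, rep = ts.intersect_with_matrix(once, tiny_matrix)
        assert twice.genes == once.genes and rep.n_absent == 0

    def test_overlap_examples(self):
        a = ts.GeneSet("a", {"A", "B", "C"}, scores={"B": "1"})
        b = ts.GeneSet("b", {"B", "C", "D"})
        ov = ts.overlap_gene_sets(a, b)
        assert ov.genes == {"B", "C"} and ov.scores == {"B": "1"}
        assert ov.name == "a∩b"
        assert not ts.overlap_gene_sets(a, ts.GeneSet("z", {"Z"})).genes

    def test_overlap_size_bounds(self):
        a = ts.GeneSet("a", {"A", "B"})
        b = ts.GeneSet("b", {"A", "B", "C"})
        assert len(ts.overlap_gene_sets(a, b)) == len(a)  # a subset of b
        assert len(ts.overlap_gene_sets(b, a)) <= min(len(a), len(b))

    def test_planted_overlap_of_14_matches_brute_force(self):
        cfg = ts.SyntheticConfig(
            disease_sets=[
                ts.DiseaseSpec(name="autism_like", size=60),
                ts.DiseaseSpec(name="ataxia_like", size=40),
            ],
            overlaps=[ts.OverlapSpec("autism_like", "ataxia_like", 14)],
            seed=0,
        )
        a, b = ts.generate_gene_sets(cfg)
        ov = ts.overlap_gene_sets(a, b)
        assert len(ov) == 14
        assert ov.genes == a.genes & b.genes  # brute-force set oracle


class TestExtractSubmatrix:
    def test_row_restriction(self, tiny_matrix):
        sub = ts.extract_submatrix(tiny_matrix, ts.GeneSet("d", {"GFAP", "INS"}))
        assert sub.gene_ids == ["GFAP", "INS"]
        assert sub.tissue_ids == tiny_matrix.tissue_ids

    def test_log_transform_values(self, tiny_matrix):
        gs = ts.GeneSet("d", {"GFAP", "INS"})
        sub = ts.extract_submatrix(tiny_matrix, gs, log_transform=True)
        # GFAP has TPM 0 in the heart column -> log10(1) = 0
        assert sub.values[0, 1] == 0.0
        # a TPM of 99 maps to exactly 2
        m = ts.ExpressionMatrix(["G"], ["T"], np.array([[99.0]]))
        sub99 = ts.extract_submatrix(m, ts.GeneSet("d", {"G"}), log_transform=True)
        assert sub99.values[0, 0] == pytest.approx(2.0)

    def test_empty_selection_errors(self, tiny_matrix):
        with pytest.raises(EmptyGeneSetError):
            ts.extract_submatrix(tiny_matrix, ts.GeneSet("d", {"NOPE"}))


class TestTaxonomy:
    def test_default_rules_cover_gtex_names(self):
        tax = ts.TissueTaxonomy.default()
        assert tax.group_of("Brain - Amygdala") == "CNS"
        assert tax.group_of("Brain - Spinal cord (cervical c-1)") == "CNS"
        assert tax.group_of("Heart - Left Ventricle") == "heart"
        assert tax.group_of("Muscle - Skeletal") == "muscle_skeletal"
        assert tax.group_of("Pancreas") == "peripheral_organ"

    def test_first_match_wins_in_file_order(self, tmp_path):
        p = tmp_path / "tax.yaml"
        p.write_text(
            "- {pattern: 'heart', group: heart}\n"
            "- {pattern: 'art', group: CNS}\n"
        )
        tax = ts.TissueTaxonomy.from_yaml(p)
        assert tax.group_of("Heart - Left Ventricle") == "heart"
        assert tax.group_of("Artery - Aorta") == "CNS"

    def test_unmatched_tissue_warns_and_falls_back(self, caplog):
        tax = ts.TissueTaxonomy(rules=[("brain", "CNS")])
        with caplog.at_level("WARNING"):
            assert tax.group_of("Liver") == "peripheral_organ"
        assert any("matched no taxonomy pattern" in r.message for r in caplog.records)

    def test_yaml_round_trip(self, tmp_path):
        tax = ts.TissueTaxonomy.default()
        p = tmp_path / "tax.yaml"
        tax.to_yaml(p)
        assert ts.TissueTaxonomy.from_yaml(p).rules == tax.rules

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            ts.TissueTaxonomy(rules=[("brain", "cortex")])
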