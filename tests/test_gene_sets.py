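"""Gene-set reading, membership-matrix construction and module expansion."""

import numpy as np
import pytest

from pathxtalk.gene_sets import (
    GmtParseError,
    build_membership,
    expand_with_modules,
    read_gmt,
)
from pathxtalk.modules_detect import Module


def _write(tmp_path, text, name="sets.gmt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGmt:
    def test_dedup_and_description_discarded(self, tmp_path):
        p = _write(tmp_path, "PATH_A\tdesc\tG1\tG2\tG2\n")
        coll = read_gmt(p)
        assert coll.pathway_ids == ["PATH_A"]
        assert coll.sets[0][1] == {"G1", "G2"}

    def test_empty_file_gives_empty_collection(self, tmp_path):
        assert len(read_gmt(_write(tmp_path, ""))) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "OK\td\tG1\nBAD\tonly-two-fields\n")
        with pytest.raises(GmtParseError, match="line 2"):
            read_gmt(p)

    def test_duplicate_pathway_name_rejected(self, tmp_path):
        p = _write(tmp_path, "P\td\tG1\nP\td\tG2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_restrict_intersects_and_drops_empty_sets(self, tmp_path):
        p = _write(tmp_path, "P1\td\tG1\tG2\nP2\td\tG3\n")
        coll = read_gmt(p).restrict({"G1", "G2"})
        assert coll.pathway_ids == ["P1"]
        assert coll.genes == {"G1", "G2"}


class TestBuildMembership:
    def test_rows_sorted_by_pvalue_and_de_count(self):
        coll_sets = {"A": {"g1", "g2"}, "B": {"g2", "g3"}}
        from conftest import make_membership  # noqa: F401  (helper used below)

        X = make_membership(coll_sets, de_genes={"g3"})
        assert X.gene_ids[0] == "g3"  # DE gene first
        assert X.n_de == 1
        assert X.n_nde == 2
        # column sums equal restricted pathway sizes
        assert dict(zip(X.pathway_ids, X.column_sizes())) == {"A": 2, "B": 2}

    def test_disjoint_pathways_identity_pattern(self):
        from pathxtalk.gene_sets import GeneSetCollection

        coll = GeneSetCollection((("A", frozenset({"G1"})), ("B", frozenset({"G2"}))))
        X = build_membership(coll, {"G1": 0.2, "G2": 0.3}, alpha=0.05)
        assert X.n_de == 0
        assert X.values.tolist() == [[1, 0], [0, 1]]

    def test_ties_broken_by_gene_id(self):
        from pathxtalk.gene_sets import GeneSetCollection

        coll = GeneSetCollection((("A", frozenset({"Gb", "Ga", "Gc"})),))
        X = build_membership(coll, {"Gb": 0.1, "Ga": 0.1, "Gc": 0.1})
        assert X.gene_ids == ["Ga", "Gb", "Gc"]

    def test_row_order_independent_of_input_order(self):
        from pathxtalk.gene_sets import GeneSetCollection

        coll = GeneSetCollection((("A", frozenset({"G1", "G2", "G3"})),))
        p = [("G1", 0.4), ("G2", 0.01), ("G3", 0.2)]
        X1 = build_membership(coll, p)
        X2 = build_membership(coll, list(reversed(p)))
        assert X1.gene_ids == X2.gene_ids == ["G2", "G3", "G1"]
        assert np.array_equal(X1.values, X2.values)

    def test_missing_pvalue_listed(self):
        from pathxtalk.gene_sets import GeneSetCollection

        coll = GeneSetCollection((("A", frozenset({"G1", "G2"})),))
        with pytest.raises(ValueError, match="G2"):
            build_membership(coll, {"G1": 0.5})

    def test_genes_outside_all_sets_dropped(self):
        from pathxtalk.gene_sets import GeneSetCollection

        coll = GeneSetCollection((("A", frozenset({"G1"})),))
        X = build_membership(coll, {"G1": 0.5, "G9": 0.01})
        assert X.gene_ids == ["G1"]


class TestExpandWithModules:
    def test_empty_module_list_is_identity(self, toy_membership):
        X = toy_membership({"A": {"g1", "g2"}}, de_genes=set())
        assert expand_with_modules(X, []) is X

    def test_column_count_grows_by_module_count(self, toy_membership):
        X = toy_membership(
            {"A": {"g1", "g2", "g3"}, "B": {"g3", "g4"}, "C": {"g5"}},
            de_genes={"g3"},
        )
        mods = [
            Module("M1", frozenset({"g3"}), frozenset({"A", "B"})),
            Module("M2", frozenset({"g5"}), frozenset({"C"})),
        ]
        Xe = expand_with_modules(X, mods)
        assert Xe.n_pathways == X.n_pathways + 2
        assert Xe.pathway_ids[-2:] == ["M1", "M2"]

    def test_module_equal_to_whole_pathway_empties_column(self, toy_membership):
        X = toy_membership({"A": {"g1", "g2", "g3"}}, de_genes=set())
        mod = Module("M", frozenset({"g1", "g2", "g3"}), frozenset({"A"}))
        with pytest.warns(UserWarning, match="emptied"):
            Xe = expand_with_modules(X, [mod])
        frame = Xe.to_frame()
        assert frame["A"].sum() == 0
        assert frame["M"].tolist() == X.to_frame()["A"].tolist()

    def test_module_genes_removed_only_from_overlapping_columns(self, toy_membership):
        X = toy_membership(
            {"A": {"g1", "g2"}, "B": {"g1", "g3"}, "C": {"g4"}},
            de_genes=set(),
        )
        mod = Module("M", frozenset({"g1"}), frozenset({"A", "B"}))
        Xe = expand_with_modules(X, [mod])
        f = Xe.to_frame()
        assert f.loc["g1", ["A", "B"]].sum() == 0
        assert f.loc["g1", "M"] == 1
        assert f.loc["g4", "C"] == 1

    def test_id_collision_rejected(self, toy_membership):
        X = toy_membership({"A": {"g1"}}, de_genes=set())
        with pytest.raises(ValueError, match="collides"):
            expand_with_modules(X, [Module("A", frozenset({"g1"}), frozenset({"A"}))])


def test_membership_tsv_roundtrip(tmp_path, toy_membership):
    X = toy_membership({"A": {"g1", "g2"}, "B": {"g2", "g3"}}, de_genes={"g1"})
    path = tmp_path / "m.tsv"
    X.to_tsv(path)
    from pathxtalk.gene_sets import MembershipMatrix

    pvals = dict(zip(X.gene_ids, X.de_pvalues))
    X2 = MembershipMatrix.from_tsv(path, pvals)
    assert X2.gene_ids == X.gene_ids
    assert X2.pathway_ids == X.pathway_ids
    assert np.array_equal(X2.values, X.values)
    assert X2.n_de == X.n_de
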