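import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathformer.cohort_io import (
    ExpressionTransform,
    GdaTable,
    canonical_order,
    load_cohort,
    read_gene_ranking,
    write_cohort,
    write_gene_ranking,
)

from conftest import make_sample


class TestCanonicalOrder:
    @pytest.mark.parametrize(
        "symbols, expected",
        [
            (["TP53", "APOE", "BRCA1"], {"APOE": 0, "BRCA1": 1, "TP53": 2}),
            (["A"], {"A": 0}),
            # byte-wise, not numeric, ordering
            (["g2", "g10", "g1"], {"G1": 0, "G10": 1, "G2": 2}),
        ],
    )
    def test_lexicographic_rank(self, symbols, expected):
        universe = canonical_order(symbols)
        assert {g: universe.h(g) for g in universe.genes} == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            canonical_order([])

    def test_bijection_onto_range(self):
        universe = canonical_order(["X", "Y", "Z", "X"])
        assert sorted(universe.order.values()) == list(range(len(universe)))

    @given(st.permutations(["TP53", "APOE", "BRCA1", "EGFR", "KRAS"]))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariant(self, shuffled):
        assert canonical_order(shuffled) == canonical_order(sorted(shuffled))

    def test_case_normalized(self):
        assert canonical_order(["tp53", "TP53"]).genes == ("TP53",)


@pytest.fixture
def cohort_files(tmp_path):
    (tmp_path / "expr.tsv").write_text(
        "gene\ts1\ts2\nA\t1.0\t4.0\nB\t2.0\t5.0\nC\t3.0\t6.0\n"
    )
    # reciprocal duplicate A-B plus an endpoint (D) with no expression row
    (tmp_path / "edges.txt").write_text("# comment\nA\tB\nB\tA\nB\tC\nC\tD\n")
    (tmp_path / "gda.tsv").write_text("A\t0.9\nB\t0.5\nC\t0.0\n")
    (tmp_path / "labels.tsv").write_text("s1\tctrl\ns2\tdisease\n")
    return tmp_path


class TestLoadCohort:
    def test_small_fixture_roundtrip_values(self, cohort_files):
        cohort, gda = load_cohort(
            cohort_files / "expr.tsv",
            cohort_files / "edges.txt",
            cohort_files / "gda.tsv",
            cohort_files / "labels.tsv",
        )
        # D enters the universe via the edge file but no sample carries it
        assert cohort.universe.genes == ("A", "B", "C", "D")
        assert cohort.n_samples == 2
        assert cohort.samples[0].expression == {"A": 1.0, "B": 2.0, "C": 3.0}
        assert all("D" not in s.present_genes for s in cohort.samples)
        # reciprocal edge lines collapse to a single undirected edge
        assert frozenset(("A", "B")) in cohort.edges
        assert len(cohort.edges) == 3
        # class indices follow sorted class-name order
        assert cohort.class_names == ["ctrl", "disease"]
        assert [s.label for s in cohort.samples] == [0, 1]
        assert gda("A") == 0.9 and gda("UNLISTED") == 0.0

    def test_shared_connection_property(self, cohort_files):
        cohort, _ = load_cohort(
            cohort_files / "expr.tsv",
            cohort_files / "edges.txt",
            cohort_files / "gda.tsv",
            cohort_files / "labels.tsv",
        )
        for s in cohort.samples:
            induced = cohort.induced_edges(s)
            assert induced <= cohort.edges
            expected = {
                e for e in cohort.edges if all(g in s.present_genes for g in e)
            }
            assert induced == expected

    def test_missing_labeled_sample_rejected(self, cohort_files):
        (cohort_files / "labels.tsv").write_text("s1\tctrl\nGHOST\tdisease\n")
        with pytest.raises(ValueError, match="GHOST"):
            load_cohort(
                cohort_files / "expr.tsv",
                cohort_files / "edges.txt",
                cohort_files / "gda.tsv",
                cohort_files / "labels.tsv",
            )

    def test_gda_score_out_of_range_rejected(self, cohort_files):
        (cohort_files / "gda.tsv").write_text("A\t1.5\n")
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            load_cohort(
                cohort_files / "expr.tsv",
                cohort_files / "edges.txt",
                cohort_files / "gda.tsv",
                cohort_files / "labels.tsv",
            )


class TestWriteCohort:
    def test_write_then_reload_identity(self, tmp_path, small_cohort):
        cohort, gda, _ = small_cohort
        paths = write_cohort(cohort, gda, tmp_path)
        re_cohort, re_gda = load_cohort(
            paths["expression"], paths["edges"], paths["gda"], paths["labels"]
        )
        assert re_cohort.universe == cohort.universe
        assert re_cohort.edges == cohort.edges
        assert re_cohort.class_names == cohort.class_names
        assert [s.label for s in re_cohort.samples] == [s.label for s in cohort.samples]
        for a, b in zip(cohort.samples, re_cohort.samples):
            assert a.present_genes == b.present_genes
            for g in a.present_genes:
                assert abs(a.expression[g] - b.expression[g]) < 1e-12
        assert all(abs(re_gda(g) - gda(g)) < 1e-12 for g in cohort.universe.genes)

    def test_reload_invariant_to_row_order(self, tmp_path, small_cohort):
        """Shuffling on-disk expression rows must not change the loaded cohort."""
        cohort, gda, _ = small_cohort
        paths = write_cohort(cohort, gda, tmp_path)
        lines = (tmp_path / "cohort_expression.tsv").read_text().splitlines()
        header, rows = lines[0], lines[1:]
        rng = np.random.default_rng(3)
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        shuf_path = tmp_path / "shuffled.tsv"
        shuf_path.write_text("\n".join([header] + shuffled) + "\n")
        a, _ = load_cohort(paths["expression"], paths["edges"], paths["gda"], paths["labels"])
        b, _ = load_cohort(shuf_path, paths["edges"], paths["gda"], paths["labels"])
        assert a.universe == b.universe
        assert [s.expression for s in a.samples] == [s.expression for s in b.samples]


class TestGeneRanking:
    def test_tie_broken_by_canonical_order(self, tmp_path):
        out = tmp_path / "rank.tsv"
        write_gene_ranking(out, [("ZZZ", 0.5), ("AAA", 0.5), ("MMM", 0.9)])
        got = read_gene_ranking(out)
        assert [g for g, _ in got] == ["MMM", "AAA", "ZZZ"]

    def test_empty_ranking_writes_header_only(self, tmp_path):
        out = tmp_path / "rank.tsv"
        write_gene_ranking(out, [])
        assert out.read_text() == "gene\tepsilon_score\trank\tgda_score\n"

    def test_round_trips_unchanged(self, tmp_path):
        out = tmp_path / "rank.tsv"
        ranking = [("A", 0.7), ("B", 0.2), ("C", 0.1)]
        write_gene_ranking(out, ranking, gda=GdaTable(scores={"A": 0.4}))
        assert read_gene_ranking(out) == ranking

    def test_nonfinite_score_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="non-finite"):
            write_gene_ranking(tmp_path / "rank.tsv", [("A", float("nan"))])


class TestExpressionTransform:
    def test_zscore_fit_on_training_only(self):
        train = [make_sample("a", {"G": 3.0}), make_sample("b", {"G": 7.0})]
        tf = ExpressionTransform("zscore").fit(train)
        vals = [tf("G", 3.0), tf("G", 7.0)]
        assert abs(np.mean(vals)) < 1e-12 and abs(np.std(vals) - 1.0) < 1e-12
        # unseen gene falls back to identity log2p1
        assert tf("NEW", 3.0) == pytest.approx(2.0)

    def test_log2p1(self):
        tf = ExpressionTransform("log2p1")
        assert tf("G", 0.0) == 0.0
        assert tf("G", 1.0) == pytest.approx(1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTransform("sqrt")
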