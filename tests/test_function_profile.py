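import numpy as np
import pandas as pd
import pytest

from taxafunc import function_profile as fp
from taxafunc.types import ClassifiedRead, GoDag, GoTerm

A, B, C = "GO:0000001", "GO:0000002", "GO:0000003"


def read(taxid, accessions, rid="r"):
    return ClassifiedRead("C", rid, taxid, accessions=list(accessions))


class TestProportionalCounts:
    def test_tied_accessions_split_the_read(self, toy_tree):
        counts = fp.proportional_protein_counts([read(2, ["a", "b"])], toy_tree)
        assert counts == {(2, "a"): 0.5, (2, "b"): 0.5}

    def test_single_accession_counts_whole_reads(self, toy_tree):
        reads = [read(2, ["a"], f"r{i}") for i in range(3)]
        assert fp.proportional_protein_counts(reads, toy_tree) == {(2, "a"): 3.0}

    def test_hand_sum_and_conservation(self, toy_tree):
        reads = [read(2, ["a"], "r1"), read(2, ["a", "b"], "r2")]
        counts = fp.proportional_protein_counts(reads, toy_tree)
        assert counts[(2, "a")] == 1.5
        assert counts[(2, "b")] == 0.5
        assert sum(counts.values()) == pytest.approx(2.0)

    def test_strain_read_attributed_to_parent_species(self, toy_tree):
        counts = fp.proportional_protein_counts([read(3, ["a"])], toy_tree)
        assert counts == {(2, "a"): 1.0}

    def test_read_without_accession_tallied(self, toy_tree):
        diag = fp.ProteinDiagnostics()
        counts = fp.proportional_protein_counts([read(2, [])], toy_tree, diag)
        assert counts == {}
        assert diag.reads_without_accession == 1

    def test_per_species_sums_equal_accession_bearing_reads(self, toy_tree):
        rng = np.random.default_rng(23)
        reads = []
        for i in range(400):
            taxid = int(rng.choice([2, 3, 4, 7]))
            k = int(rng.integers(1, 3))
            accs = [f"p{j}" for j in rng.choice(6, size=k, replace=False)]
            reads.append(read(taxid, accs, f"r{i}"))
        counts = fp.proportional_protein_counts(reads, toy_tree)
        sums: dict[int, float] = {}
        for (species, _acc), c in counts.items():
            sums[species] = sums.get(species, 0.0) + c
        expected: dict[int, float] = {}
        for r in reads:
            s = toy_tree.species_ancestor(r.taxid)
            if s is not None and r.accessions:
                expected[s] = expected.get(s, 0.0) + 1
        for species in expected:
            assert sums[species] == pytest.approx(expected[species], abs=1e-9)


class TestScaleProteinCounts:
    def test_percent_formula(self):
        table = pd.DataFrame({"s": {(2, "a"): 2.0}})
        out = fp.scale_protein_counts(table, pd.Series({"s": 10}))
        assert out.loc[(2, "a"), "s"] == 20.0

    def test_hand_values(self):
        table = pd.DataFrame({"s": {(2, "a"): 1.5, (2, "b"): 0.5}})
        out = fp.scale_protein_counts(table, pd.Series({"s": 4}))
        assert out["s"].tolist() == [37.5, 12.5]

    def test_zero_total_warns(self):
        table = pd.DataFrame({"s": {(2, "a"): 0.0}})
        with pytest.warns(UserWarning):
            out = fp.scale_protein_counts(table, pd.Series({"s": 0}))
        assert out.loc[(2, "a"), "s"] == 0.0


class TestPropagateGo:
    def brute_force_closure(self, direct, dag):
        """Independent enumeration of every upward path's nodes."""
        out = set()

        def walk(node):
            out.add(node)
            for parent in dag.terms[node].parents:
                if parent in dag.terms:
                    walk(parent)

        for d in direct:
            walk(d)
        return out

    def test_diamond_counts_each_ancestor_once(self, diamond_dag):
        closure = fp.propagate_go({C}, diamond_dag)
        assert closure == {A, B, C}
        assert closure == self.brute_force_closure({C}, diamond_dag)

    def test_empty_and_root_cases(self, diamond_dag):
        assert fp.propagate_go(set(), diamond_dag) == frozenset()
        assert fp.propagate_go({A}, diamond_dag) == {A}

    def test_alt_id_resolved_and_obsolete_dropped(self):
        dag = GoDag(
            {
                A: GoTerm("a", "biological_process", [], []),
                B: GoTerm("b", "biological_process", [A], [], alt_ids=["GO:0000099"]),
                C: GoTerm("c", "biological_process", [A], [], obsolete=True),
            }
        )
        diag = fp.ProteinDiagnostics()
        closure = fp.propagate_go({"GO:0000099", C, "GO:7777777"}, dag, diag)
        assert closure == {A, B}
        assert diag.obsolete_go_ids[C] == 1
        assert diag.unresolved_go_ids["GO:7777777"] == 1


class FakeStore:
    def __init__(self, mapping):
        self.mapping = {k: frozenset(v) for k, v in mapping.items()}


class TestAggregateGoCounts:
    def make_inputs(self, diamond_dag):
        proteins = pd.DataFrame(
            {"s1": {(2, "p1"): 2.0, (2, "p2"): 1.0}}
        )
        proteins.index = pd.MultiIndex.from_tuples(
            proteins.index, names=["taxid", "accession"]
        )
        store = FakeStore({"p1": {C}, "p2": {B}})
        return proteins, store

    def test_hand_aggregation_on_diamond(self, diamond_dag):
        proteins, store = self.make_inputs(diamond_dag)
        out = fp.aggregate_go_counts(proteins, store, diamond_dag)
        assert out.loc[A, "s1"] == 3.0  # never doubled despite two paths
        assert out.loc[B, "s1"] == 3.0
        assert out.loc[C, "s1"] == 2.0

    def test_parent_count_at_least_child_count(self, diamond_dag):
        proteins, store = self.make_inputs(diamond_dag)
        out = fp.aggregate_go_counts(proteins, store, diamond_dag)
        for child, term in diamond_dag.terms.items():
            for parent in term.parents:
                if child in out.index and parent in out.index:
                    assert out.loc[parent, "s1"] >= out.loc[child, "s1"]

    def test_no_annotated_proteins_gives_empty_table(self, diamond_dag):
        proteins, _ = self.make_inputs(diamond_dag)
        out = fp.aggregate_go_counts(proteins, FakeStore({}), diamond_dag)
        assert out.empty

    def test_unannotated_accession_tallied(self, diamond_dag):
        proteins, _ = self.make_inputs(diamond_dag)
        diag = fp.ProteinDiagnostics()
        fp.aggregate_go_counts(proteins, FakeStore({"p1": {C}}), diamond_dag, diag)
        assert diag.unannotated_accessions == {"p2"}


class TestNamespacePercentages:
    def test_within_namespace_percentages(self):
        table = pd.DataFrame(
            {
                "namespace": ["biological_process"] * 3 + ["molecular_function"],
                "s1": [3.0, 3.0, 2.0, 5.0],
            },
            index=[A, B, C, "GO:0000004"],
        )
        out = fp.namespace_percentages(table)
        assert out["s1"].tolist() == [37.5, 37.5, 25.0, 100.0]

    def test_sums_to_100_per_namespace(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "namespace": rng.choice(["bp", "mf", "cc"], size=20),
                "s1": rng.exponential(1, 20),
                "s2": rng.exponential(1, 20),
            }
        )
        out = fp.namespace_percentages(table)
        for ns, block in out.groupby("namespace"):
            assert np.allclose(block[["s1", "s2"]].sum(axis=0), 100.0, atol=1e-9)


class TestCrossTables:
    def make(self, diamond_dag):
        proteins = pd.DataFrame(
            {"s1": {(2, "p1"): 2.0, (4, "p2"): 1.0, (4, "px"): 1.0}}
        )
        proteins.index = pd.MultiIndex.from_tuples(
            proteins.index, names=["taxid", "accession"]
        )
        store = FakeStore({"p1": {C}, "p2": {B}})
        group_pct = pd.DataFrame({"g1": {2: 30.0, 4: 10.0}, "g2": {2: 5.0, 4: 20.0}})
        return fp.build_cross_tables(proteins, store, diamond_dag, group_pct)

    def test_go_to_taxa_lists_whole_species_percents(self, diamond_dag):
        go2taxa, _ = self.make(diamond_dag)
        b_rows = go2taxa[go2taxa["go_id"] == B]
        assert sorted(b_rows["taxid"]) == [2, 4]
        row = b_rows[b_rows["taxid"] == 2].iloc[0]
        assert row["percent_g1"] == 30.0  # whole-species abundance

    def test_symmetry_of_views(self, diamond_dag):
        go2taxa, taxa2go = self.make(diamond_dag)
        pairs_a = set(zip(go2taxa["go_id"], go2taxa["taxid"]))
        pairs_b = set(zip(taxa2go["go_id"], taxa2go["taxid"]))
        assert pairs_a == pairs_b
        for go, taxid in pairs_a:
            assert taxid in fp.species_of_go_term(go2taxa, go)
            assert go in fp.go_terms_of_species(taxa2go, taxid)

    def test_unannotated_species_and_unused_term_empty(self, diamond_dag):
        go2taxa, taxa2go = self.make(diamond_dag)
        assert fp.go_terms_of_species(taxa2go, 999) == []
        assert fp.species_of_go_term(go2taxa, "GO:0099999") == []
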