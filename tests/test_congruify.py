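"""Congruification: clade matching, the halving rule, stable node names."""

import random

import pytest

from chronograft.chronodb import search
from chronograft.congruify import (
    CalibrationTable,
    assign_node_names,
    build_calibration_table,
    congruify_one,
)
from chronograft.names import resolve_names
from chronograft.trees import Tree, as_chronogram, parse_newick, patristic_matrix

from conftest import random_ultrametric


@pytest.fixture(scope="module")
def small_table(small_example, canonical_db):
    _db, _tax, query, target = small_example
    return build_calibration_table(target, search(query, canonical_db))


class TestCongruifyOne:
    def test_published_root_calibration_recovered(self, small_example, canonical_db):
        """The yellowhammer/vegetarian-finch pair at total distance 19.302
        calibrates the root (n1) at 9.651 Myr."""
        _db, _tax, query, target = small_example
        result = search(query, canonical_db)
        hooper1 = next(m for m in result.matches if m.record_id == "hooper2017_1")
        assert hooper1.matrix.entry(
            "Emberiza citrinella", "Platyspiza crassirostris"
        ) == pytest.approx(19.302)
        points = congruify_one(target, hooper1.matrix)
        n1 = next(p for p in points if p.node == "n1")
        assert n1.age == pytest.approx(9.651)
        assert (n1.taxon_a, n1.taxon_b) == (
            "Emberiza citrinella", "Platyspiza crassirostris"
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_identity_congruence_recovers_all_node_ages(self, seed):
        """A chronogram's own matrix against its own topology yields exactly
        its internal-node ages."""
        chrono = random_ultrametric(seed, n_tips=4 + seed % 12)
        matrix = patristic_matrix(chrono)
        names = assign_node_names(chrono)
        points = congruify_one(chrono, matrix, node_names=names)
        expected = {names[n]: chrono.age_of(n) for n in chrono.internal_nodes()}
        got = {p.node: p.age for p in points}
        assert set(got) == set(expected)
        for node, age in expected.items():
            assert got[node] == pytest.approx(age, rel=1e-9)

    def test_conflicting_source_topology_skips_node_but_not_root(self):
        """Source ((A,C),B) vs target ((A,B),C): the {A,B} clade is not
        congruent and yields no calibration; the root still does."""
        target = parse_newick("((A,B),C);")
        source = patristic_matrix(
            as_chronogram(parse_newick("((A:1,C:1):2,B:3);"))
        )
        points = congruify_one(target, source)
        assert [p.node for p in points] == ["n1"]
        assert points[0].age == pytest.approx(3.0)

    def test_no_overlap_returns_no_points(self, small_example):
        _db, _tax, _query, target = small_example
        source = patristic_matrix(as_chronogram(parse_newick("(X:1,Y:1);")))
        assert congruify_one(target, source) == []


class TestBuildCalibrationTable:
    def test_small_example_yields_28_unique_points(self, small_table):
        assert len(small_table) == 28

    def test_every_age_is_half_a_source_matrix_entry(
        self, small_example, canonical_db, small_table
    ):
        _db, _tax, query, _target = small_example
        matrices = {
            m.record_id: m.matrix for m in search(query, canonical_db).matches
        }
        for p in small_table.points:
            entry = matrices[p.record_id].entry(p.taxon_a, p.taxon_b)
            assert p.age == pytest.approx(entry / 2.0, rel=1e-12)

    def test_synonym_resolution_unlocks_five_points_for_n4(
        self, small_example, canonical_db
    ):
        db, _tax, query, target = small_example
        with_syn = build_calibration_table(target, search(query, canonical_db))
        n4 = [p for p in with_syn.points if p.node == "n4"]
        assert len(n4) == 5
        # without canonicalizing the database, the elegans bunting tips keep
        # their published name and never match the target tip
        without = build_calibration_table(target, search(query, db))
        assert [p for p in without.points if p.node == "n4"] == []

    def test_empty_search_result_gives_empty_messaged_table(
        self, small_example, canonical_db
    ):
        _db, tax, _query, target = small_example
        query = resolve_names(["Tyrannosaurus rex", "Iguanodon bernissartensis"], tax)
        table = build_calibration_table(target, search(query, canonical_db))
        assert len(table) == 0
        assert table.message is not None

    @pytest.mark.parametrize("seed", range(6))
    def test_pruned_target_reproduces_rows_whose_witness_clade_survives(self, seed):
        """Congruification is local to the shared tips: any row whose
        shared-tip witness set survives a prune of the target intact is
        reproduced by the pruned run with the identical age."""
        rng = random.Random(seed)
        target = random_ultrametric(seed + 100, n_tips=9)
        full_names = assign_node_names(target)
        clade_of_full = {name: target.tip_set(n) for n, name in full_names.items()}
        sources = []
        for k in range(3):
            keep = rng.sample(target.tip_labels, 5)
            scale = rng.uniform(0.5, 2.0)
            pruned = as_chronogram(target.prune(keep))
            m = patristic_matrix(pruned)
            sources.append(type(m)(m.labels, m.values * scale))
        keep = set(rng.sample(target.tip_labels, 6))
        sub_target = target.prune(keep)
        sub_names = assign_node_names(sub_target)
        clade_of_sub = {name: sub_target.tip_set(n) for n, name in sub_names.items()}
        compared = 0
        for k, m in enumerate(sources):
            full_rows = {
                frozenset(set(m.labels) & clade_of_full[p.node]): p.age
                for p in congruify_one(target, m)
            }
            sub_rows = {
                frozenset(set(m.labels) & clade_of_sub[p.node]): p.age
                for p in congruify_one(sub_target, m, node_names=sub_names)
            }
            for shared_set, age in full_rows.items():
                if shared_set <= keep:
                    assert shared_set in sub_rows
                    assert sub_rows[shared_set] == pytest.approx(age)
                    compared += 1
        assert compared > 0


class TestNodeNames:
    def test_names_follow_canonical_preorder(self, small_example):
        _db, _tax, _query, target = small_example
        names = {v: k for k, v in assign_node_names(target).items()}
        assert target.tip_set(names["n1"]) == set(target.tip_labels)
        assert target.tip_set(names["n2"]) == {
            "Pheucticus tibialis", "Rhodothraupis celaeno", "Platyspiza crassirostris",
        }
        assert target.tip_set(names["n3"]) == {
            "Pheucticus tibialis", "Rhodothraupis celaeno",
        }
        assert target.tip_set(names["n4"]) == {
            "Emberiza citrinella", "Emberiza leucocephalos", "Schoeniclus elegans",
        }
        assert target.tip_set(names["n5"]) == {
            "Emberiza citrinella", "Emberiza leucocephalos",
        }

    def test_names_invariant_under_newick_child_order(self, small_example):
        _db, _tax, _query, target = small_example
        rewritten = parse_newick(target.write_newick(include_lengths=False))
        by_clade = lambda t: {
            t.tip_set(node): name for node, name in assign_node_names(t).items()
        }
        assert by_clade(target) == by_clade(rewritten)


class TestTableIO:
    def test_csv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        small_table.to_csv(path)
        back = CalibrationTable.from_csv(path, small_table.target)
        assert len(back) == len(small_table)
        assert back.ages_by_node() == small_table.ages_by_node()
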