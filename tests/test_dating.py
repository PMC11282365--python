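"""Conflict filtering, root-age policy, BLADJ interpolation, end-to-end."""

import random

import pytest

from chronograft.congruify import assign_node_names, build_calibration_table
from chronograft.chronodb import ChronogramDB, search
from chronograft.dating import (
    DEFAULT_ROOT_FACTOR,
    DISCARDED_OLDER,
    DISCARDED_YOUNGER,
    CalibrationSet,
    DatingError,
    RandomRootWarning,
    bladj,
    date_topology,
    external_dater_config,
    filter_calibrations,
    resolve_root_age,
)
from chronograft.summarize import NodeAgeSummary, summarize_node_ages
from chronograft.trees import parse_newick

from conftest import random_ultrametric


def _summary(node: str, age: float) -> NodeAgeSummary:
    return NodeAgeSummary(
        node=node, n=1, min=age, q1=age, median=age, mean=age, q3=age, max=age,
        variance=float("nan"), sd=float("nan"),
    )


def ages_by_name(chrono):
    names = assign_node_names(chrono)
    return {name: chrono.age_of(node) for node, name in names.items()}


@pytest.fixture(scope="module")
def small_summaries(small_example, canonical_db):
    _db, _tax, query, target = small_example
    table = build_calibration_table(target, search(query, canonical_db))
    return summarize_node_ages(table), target


class TestFilterCalibrations:
    def test_n2_median_discarded_against_younger_ancestor(self, small_summaries):
        """The cardinal+tanager clade's median (19.709) exceeds the root
        median (16.950) and is excluded, exactly as in the published run."""
        summaries, target = small_summaries
        cal = filter_calibrations(summaries, target, stat="median")
        assert "n2" not in cal.ages
        assert cal.provenance["n2"] == DISCARDED_OLDER
        assert cal.ages["n1"] == pytest.approx(16.950)
        assert cal.ages["n4"] == pytest.approx(10.339)
        assert cal.root_age == pytest.approx(16.950)

    def test_strictly_nested_ages_all_retained(self):
        target = parse_newick("(((A,B),C),D);")
        summaries = [_summary("n1", 30.0), _summary("n2", 20.0), _summary("n3", 10.0)]
        cal = filter_calibrations(summaries, target)
        assert cal.ages == {"n1": 30.0, "n2": 20.0, "n3": 10.0}
        assert all(v == "used" for v in cal.provenance.values())

    def test_ancestor_precedence_resolves_inverted_chains(self):
        # the mid node (5) conflicts with its deeper child (8): the
        # root-down pass keeps the more inclusive node and discards the
        # child as older-than-ancestor (ancestor precedence), after which
        # no younger-than-descendant violation can remain
        target = parse_newick("(((A,B),C),D);")
        summaries = [_summary("n2", 5.0), _summary("n3", 8.0)]
        cal = filter_calibrations(summaries, target)
        assert cal.provenance["n3"] == DISCARDED_OLDER
        assert cal.ages == {"n2": 5.0}
        assert all(v != DISCARDED_YOUNGER for v in cal.provenance.values())

    def test_all_conflicting_raises(self):
        target = parse_newick("((A,B),C);")
        # single calibration equal to ancestor: root-down keeps the root,
        # drops the child; dropping every age is impossible here, so force
        # the degenerate case with an empty summary list
        with pytest.raises(DatingError):
            filter_calibrations([], target)


class TestResolveRootAge:
    def test_user_root_wins_without_warning(self, recwarn):
        cal = CalibrationSet(ages={"n2": 10.0})
        assert resolve_root_age(cal, user_root=25.0) == 25.0
        assert cal.root_policy == "user"
        assert not [w for w in recwarn.list if w.category is RandomRootWarning]

    def test_root_summary_used_when_present(self):
        cal = CalibrationSet(ages={"n1": 16.95, "n2": 10.0}, root_age=16.95)
        assert resolve_root_age(cal) == pytest.approx(16.95)

    def test_default_policy_scales_oldest_calibration_and_warns(self):
        cal = CalibrationSet(ages={"n2": 16.950})
        with pytest.warns(RandomRootWarning):
            root = resolve_root_age(cal)
        assert root == pytest.approx(DEFAULT_ROOT_FACTOR * 16.950)
        assert root == pytest.approx(18.645)

    def test_randomized_policy_is_seeded_and_bounded(self):
        roots = set()
        for _ in range(3):
            cal = CalibrationSet(ages={"n2": 10.0})
            with pytest.warns(RandomRootWarning):
                roots.add(resolve_root_age(cal, rng_seed=42))
        assert len(roots) == 1
        assert 10.0 <= roots.pop() <= 20.0

    def test_no_information_at_all_raises(self):
        with pytest.raises(DatingError):
            resolve_root_age(CalibrationSet(ages={}))


class TestBladj:
    def test_all_nodes_fixed_reproduces_ages_exactly(self):
        chrono = random_ultrametric(5, n_tips=8)
        cal = CalibrationSet(
            ages={n: a for n, a in ages_by_name(chrono).items()},
            root_age=chrono.root_age,
        )
        topo = parse_newick(chrono.write_newick(include_lengths=False))
        dated = bladj(topo, cal)
        for name, age in ages_by_name(dated).items():
            assert age == pytest.approx(cal.ages[name], abs=1e-12)

    def test_chain_interpolation_matches_the_closed_form(self):
        # two unfixed nodes between the fixed root (12) and a fixed deep
        # node (3): even spacing gives 12, 9, 6, 3
        target = parse_newick("((((A,B),C),D),E);")
        cal = CalibrationSet(ages={"n1": 12.0, "n4": 3.0}, root_age=12.0)
        ages = ages_by_name(bladj(target, cal))
        assert ages["n1"] == pytest.approx(12.0)
        assert ages["n2"] == pytest.approx(9.0)
        assert ages["n3"] == pytest.approx(6.0)
        assert ages["n4"] == pytest.approx(3.0)

    def test_uncalibrated_chain_interpolates_toward_the_nearest_tip(self):
        # with only the root fixed, every chain node halves the remaining
        # interval to its nearest (zero-age) tip
        target = parse_newick("(((A,B),C),D);")
        cal = CalibrationSet(ages={"n1": 9.0}, root_age=9.0)
        ages = ages_by_name(bladj(target, cal))
        assert ages["n2"] == pytest.approx(4.5)
        assert ages["n3"] == pytest.approx(2.25)

    def test_unfixed_cherry_sits_at_the_midpoint(self):
        target = parse_newick("((A,B),C);")
        cal = CalibrationSet(ages={"n1": 10.0}, root_age=10.0)
        assert ages_by_name(bladj(target, cal))["n2"] == pytest.approx(5.0)

    def test_output_is_exactly_ultrametric(self):
        chrono = random_ultrametric(9, n_tips=12)
        names = ages_by_name(chrono)
        kept = dict(list(sorted(names.items()))[::2])  # calibrate every other node
        root_name = "n1"
        cal = CalibrationSet(ages=dict(kept), root_age=names[root_name])
        cal.ages[root_name] = names[root_name]
        topo = parse_newick(chrono.write_newick(include_lengths=False))
        dated = bladj(topo, cal)
        depths = set()
        for leaf in dated.dendropy_tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.add(round(d, 12))
        assert len(depths) == 1

    def test_interpolation_respects_deep_old_calibrations(self):
        """A deep fixed node older than a nearby tip path must cap the
        interpolated ancestors above it: parent > child everywhere."""
        target = parse_newick("((T,((X,Y),F)),Z);")
        names = {v: k for k, v in assign_node_names(target).items()}
        # fix the root at 10 and the (X,Y,F) ancestor's child clade at 9
        by_clade = {frozenset(target.tip_set(n)): nm
                    for nm, n in names.items()}
        cal = CalibrationSet(
            ages={by_clade[frozenset({"X", "Y"})]: 9.0,
                  by_clade[frozenset({"T", "X", "Y", "F", "Z"})]: 10.0},
            root_age=10.0,
        )
        dated = bladj(target, cal)
        for node in dated.internal_nodes():
            for child in node.child_nodes():
                if not child.is_leaf():
                    assert dated.age_of(node) > dated.age_of(child)

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_a_calibration_never_lowers_any_age(self, seed):
        rng = random.Random(seed)
        chrono = random_ultrametric(20 + seed, n_tips=10)
        names = ages_by_name(chrono)
        kept = {n: a for n, a in names.items() if n == "n1" or rng.random() < 0.5}
        topo = parse_newick(chrono.write_newick(include_lengths=False))
        base = ages_by_name(
            bladj(topo, CalibrationSet(ages=dict(kept), root_age=kept["n1"]))
        )
        bump_candidates = sorted(set(kept) - {"n1"})
        if not bump_candidates:
            return
        bump = bump_candidates[0]
        raised = dict(kept)
        raised[bump] = raised[bump] * 1.01
        try:
            dated = bladj(topo, CalibrationSet(ages=raised, root_age=raised["n1"]))
        except DatingError:
            return  # the bump created a conflict; nothing to compare
        ages = ages_by_name(dated)
        for name in ages:
            assert ages[name] >= base[name] - 1e-12

    def test_missing_root_age_rejected(self):
        with pytest.raises(DatingError):
            bladj(parse_newick("((A,B),C);"), CalibrationSet(ages={"n2": 1.0}))

    def test_inconsistent_fixed_ages_rejected(self):
        target = parse_newick("(((A,B),C),D);")
        cal = CalibrationSet(ages={"n1": 5.0, "n2": 7.0}, root_age=5.0)
        with pytest.raises(DatingError):
            bladj(target, cal)


class TestEndToEnd:
    def test_small_example_dated_nodes_carry_the_published_medians(
        self, small_example, canonical_db
    ):
        _db, _tax, query, target = small_example
        result = date_topology(query, canonical_db, target=target)
        ages = ages_by_name(result.chronogram)
        assert ages["n1"] == pytest.approx(16.950)
        assert ages["n3"] == pytest.approx(10.874)
        assert ages["n4"] == pytest.approx(10.339)
        assert ages["n5"] == pytest.approx(0.241)
        assert "n2" in result.provenance["discarded_calibrations"]
        assert result.provenance["root_policy"] == "summary"

    def test_empty_database_is_a_messaged_error(self, small_example):
        _db, _tax, query, target = small_example
        empty = ChronogramDB([], version="empty")
        with pytest.raises(DatingError, match="no age data"):
            date_topology(query, empty, target=target)

    def test_isomorphic_targets_give_identical_results(
        self, small_example, canonical_db
    ):
        _db, _tax, query, target = small_example
        rotated = parse_newick(target.write_newick(include_lengths=False))
        a = date_topology(query, canonical_db, target=target)
        b = date_topology(query, canonical_db, target=rotated)
        assert a.chronogram.write_newick() == b.chronogram.write_newick()

    def test_self_consistency_round_trip(self):
        """Congruifying a chronogram's own matrix onto its topology,
        summarizing, filtering and re-dating returns the original ages."""
        from chronograft.chronodb import ChronogramRecord
        from chronograft.names import NameResolution, ResolvedQuery

        chrono = random_ultrametric(33, n_tips=9)
        db = ChronogramDB(
            [ChronogramRecord("self", "Self study", chrono)], version="v"
        )
        query = ResolvedQuery(
            [NameResolution(l, l, None, "exact") for l in chrono.tip_labels]
        )
        topo = parse_newick(chrono.write_newick(include_lengths=False))
        result = date_topology(query, db, target=topo)
        recovered = ages_by_name(result.chronogram)
        for name, age in ages_by_name(chrono).items():
            assert recovered[name] == pytest.approx(age, rel=1e-9)


class TestExternalDaterAdapter:
    def test_treepl_and_mrbayes_blocks_cover_all_calibrations(self):
        target = parse_newick("((A,B),C);")
        cal = CalibrationSet(ages={"n1": 10.0, "n2": 4.0}, root_age=10.0)
        treepl = external_dater_config(target, cal, "treepl")
        assert "mrca = n2 A B" in treepl and "min = n2 4.0" in treepl
        mrbayes = external_dater_config(target, cal, "mrbayes")
        assert "constraint n2 = A B;" in mrbayes
        assert "calibrate n2 = fixed(4.0);" in mrbayes
        with pytest.raises(DatingError):
            external_dater_config(target, cal, "pathd8")
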