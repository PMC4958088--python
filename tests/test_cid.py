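"""Cultivar identification diagram: construction, traversal, extension, rendering."""

import pytest

from ssrcid import (
    CORE_MARKER_ORDER,
    CultivarRecord,
    GenotypeCall,
    MarkerNeededError,
    add_cultivar,
    build_cid,
    cid_from_json,
    cid_report,
    identify,
    render_cid,
    simulate_table,
    PopulationSpec,
)
from .conftest import make_table


@pytest.fixture(scope="module")
def tea_cid(request):
    table = request.getfixturevalue("tea_table")
    return build_cid(table, CORE_MARKER_ORDER)


class TestBuild:
    def test_root_has_nine_branches(self, tea_cid):
        assert tea_cid.root.marker == "TM442"
        assert len(tea_cid.root.branches) == 9

    def test_singleton_groups_resolve_at_depth_one(self, tea_cid):
        leaf_292 = tea_cid.root.branches[GenotypeCall((292, 292))]
        assert leaf_292.resolved and leaf_292.cultivars == (15,)
        leaf_268_292 = tea_cid.root.branches[GenotypeCall((268, 292))]
        assert leaf_268_292.resolved and leaf_268_292.cultivars == (1,)

    def test_third_group_split_by_tm324(self, tea_cid):
        node = tea_cid.root.branches[GenotypeCall((268, 286))]
        assert node.marker == "TM324"
        assert node.branches[GenotypeCall((171, 171))].cultivars == (56,)
        assert node.branches[GenotypeCall((171, 183))].cultivars == (65,)

    def test_errors(self, tea_table):
        with pytest.raises(ValueError):
            build_cid(tea_table, [])
        with pytest.raises(KeyError):
            build_cid(tea_table, ["TM999"])

    def test_partition_invariant(self, tea_cid):
        def check(node):
            if node.is_leaf:
                return
            child_sets = [set(c.member_codes()) for c in node.branches.values()]
            union = set()
            for s in child_sets:
                assert not (union & s)  # disjoint
                union |= s
            assert union == set(node.member_codes())
            for c in node.branches.values():
                check(c)

        check(tea_cid.root)
        assert sorted(tea_cid.root.member_codes()) == list(range(1, 67))


class TestIdentify:
    def test_worked_example(self, tea_cid):
        result = identify(tea_cid, {"TM442": "268/286", "TM324": "171/171"})
        assert result.outcome == "unique" and result.cultivar == 56
        assert len(result.path) == 2
        result_b = identify(tea_cid, {"TM442": "268/286", "TM324": "171/183"})
        assert result_b.cultivar == 65

    def test_every_cultivar_self_identifies(self, tea_table, tea_cid):
        for code in tea_table.codes:
            result = identify(tea_cid, tea_table.profile(code))
            assert result.outcome == "unique" and result.cultivar == code

    def test_no_match(self, tea_cid):
        result = identify(tea_cid, {"TM442": "999/999"})
        assert result.outcome == "no_match" and result.cultivar is None
        assert result.path == (("TM442", GenotypeCall((999, 999))),)

    def test_missing_required_marker(self, tea_cid):
        with pytest.raises(MarkerNeededError, match="TM324"):
            identify(tea_cid, {"TM442": "268/286"})


class TestReport:
    def test_fixture_report(self, tea_cid):
        report = cid_report(tea_cid)
        assert report["n_cultivars"] == 66
        assert report["n_resolved"] == 66
        assert report["n_unresolved_groups"] == 0
        assert report["path_length"][1] == 1 and report["path_length"][15] == 1
        assert report["path_length"][56] == 2 and report["path_length"][65] == 2
        assert report["markers_needed"][56] == ["TM442", "TM324"]
        assert report["groups_per_level"][0] == 9

    def test_path_minimality(self, tea_table, tea_cid):
        # a cultivar's depth equals the first marker index at which its
        # genotype prefix is unique in the table
        report = cid_report(tea_cid)
        for code in tea_table.codes:
            prefix = []
            for k, marker in enumerate(CORE_MARKER_ORDER, start=1):
                prefix.append(tea_table.call(code, marker))
                sharers = [
                    other
                    for other in tea_table.codes
                    if [tea_table.call(other, m) for m in CORE_MARKER_ORDER[:k]] == prefix
                ]
                if sharers == [code]:
                    assert report["path_length"][code] == k
                    break


class TestAddCultivar:
    def test_unique_root_genotype_adds_branch(self, tea_table, tea_cid):
        record = CultivarRecord(code=67, name="New One")
        genotypes = dict(tea_table.profile(2))
        genotypes["TM442"] = GenotypeCall((300, 300))
        updated, extended = add_cultivar(tea_cid, tea_table, record, genotypes)
        assert updated.root.branches[GenotypeCall((300, 300))].cultivars == (67,)
        assert len(updated.root.branches) == 10
        # previously existing branches untouched
        assert updated.root.branches[GenotypeCall((292, 292))].cultivars == (15,)

    def test_full_duplicate_becomes_unresolved_leaf(self, tea_table, tea_cid):
        record = CultivarRecord(code=67, name="Clone Of 15")
        updated, _ = add_cultivar(tea_cid, tea_table, record, tea_table.profile(15))
        result = identify(updated, tea_table.profile(15))
        assert result.outcome == "ambiguous"
        assert set(result.candidates) == {15, 67}
        assert cid_report(updated)["n_unresolved_groups"] == 1

    def test_duplicate_code_rejected(self, tea_table, tea_cid):
        from ssrcid import TableFormatError

        with pytest.raises(TableFormatError, match="duplicate"):
            add_cultivar(
                tea_cid, tea_table, CultivarRecord(code=15, name="Dup"), tea_table.profile(15)
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalent_to_rebuild_on_synthetic_tables(self, seed):
        spec = PopulationSpec.from_dict(
            loci={
                "L1": {100: 0.5, 104: 0.3, 108: 0.2},
                "L2": {200: 0.6, 208: 0.4},
                "L3": {300: 0.4, 304: 0.4, 308: 0.2},
            },
            n_individuals=12,
            triploid_fraction=0.05,
            seed=seed,
        )
        table = simulate_table(spec)
        cid = build_cid(table)
        import numpy as np

        rng = np.random.default_rng(1000 + seed)
        donor = int(rng.integers(1, 13))
        genotypes = dict(table.profile(donor))
        if rng.random() < 0.5:  # sometimes diverge to hit a fresh branch
            genotypes["L1"] = GenotypeCall((100, 112))
        record = CultivarRecord(code=99, name="New")
        incremental, extended = add_cultivar(cid, table, record, genotypes)
        assert incremental == build_cid(extended)


class TestRender:
    def test_single_leaf_dot(self):
        table = make_table({"L1": ["100/104"]})
        cid = build_cid(table)
        dot = render_cid(cid, format="dot")
        assert "digraph" in dot and "->" not in dot

    def test_json_roundtrip(self, tea_cid):
        again = cid_from_json(render_cid(tea_cid, format="json"))
        assert again == tea_cid

    def test_dot_has_nine_root_edges(self, tea_cid):
        dot = render_cid(tea_cid, format="dot")
        root_edges = [line for line in dot.splitlines() if line.startswith("  n0 ->")]
        assert len(root_edges) == 9

    def test_text_lists_groups(self, tea_cid):
        text = render_cid(tea_cid, format="text")
        assert text.startswith("TM442:")
        assert "-> 15" in text

    def test_unknown_format(self, tea_cid):
        with pytest.raises(ValueError):
            render_cid(tea_cid, format="yaml")


class TestSyntheticInvariants:
    @pytest.mark.parametrize("seed", range(25))
    def test_partition_and_self_identification(self, seed):
        spec = PopulationSpec.from_dict(
            loci={
                "L1": {100: 0.6, 104: 0.4},
                "L2": {200: 0.5, 204: 0.3, 208: 0.2},
                "L3": {300: 0.7, 308: 0.3},
            },
            n_individuals=15,
            triploid_fraction=0.04,
            seed=seed,
        )
        table = simulate_table(spec)
        cid = build_cid(table)
        leaves = list(cid.root.leaf_iter())
        members = sorted(c for leaf in leaves for c in leaf.cultivars)
        assert members == table.codes
        for code in table.codes:
            result = identify(cid, table.profile(code))
            if result.outcome == "unique":
                assert result.cultivar == code
            else:
                assert result.outcome == "ambiguous" and code in result.candidates
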