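"""Haplogroup tree loading, assignment rules and frequency reporting."""

import numpy as np
import pytest

from mitopop.haplotyper import (
    ConfigError,
    HaplogroupNode,
    HaplogroupTree,
    MotifSite,
    assign_haplogroup,
    default_tree,
    frequency_table,
    load_haplogroup_tree,
)
from mitopop.refvar import profile_from_site_list
from mitopop.synthdata import generate_nguni_fixture, synthetic_reference


# --- tree construction -----------------------------------------------------

class TestTreeLoading:
    def test_default_tree_ancestor_chain(self, tree):
        assert tree.path("T1b1") == ("T", "T1", "T1b", "T1b1")
        assert tree.root == "T"
        assert set(tree.nodes) >= {"T", "T1", "T1a", "T1b", "T1c", "T1d",
                                   "T1e", "T1f", "T1b1"}

    def test_default_tree_diagnostics(self, tree):
        t1 = {m.position for m in tree.nodes["T1"].motif}
        assert t1 == {16050, 16113, 16255}
        assert tree.nodes["T1b"].motif[0].position == 7542
        assert tree.nodes["T1c"].motif[0].position == 16122
        assert tree.nodes["T1b1"].motif[0].position == 16022
        deep = [n for n in tree.nodes.values() if n.parent == "T1b1"]
        assert len(deep) == 1 and deep[0].motif[0].change == "A>T"
        assert deep[0].motif[0].position == 14523

    def test_placeholder_motifs_marked(self, tree):
        for name in ("T1a", "T1d", "T1e", "T1f"):
            assert all(m.placeholder for m in tree.nodes[name].motif)

    def test_self_parent_rejected(self):
        with pytest.raises(ConfigError):
            load_haplogroup_tree(
                {"haplogroups": [{"name": "T", "parent": None, "motif": []},
                                 {"name": "X", "parent": "X", "motif": []}]}
            )

    def test_duplicate_name_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            load_haplogroup_tree(
                {"haplogroups": [{"name": "T", "parent": None},
                                 {"name": "T1b", "parent": "T"},
                                 {"name": "T1b", "parent": "T"}]}
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(ConfigError, match="unknown parent"):
            load_haplogroup_tree(
                {"haplogroups": [{"name": "T", "parent": None},
                                 {"name": "A", "parent": "Z"}]}
            )

    def test_cycle_rejected(self):
        with pytest.raises(ConfigError):
            load_haplogroup_tree(
                {"haplogroups": [{"name": "T", "parent": None},
                                 {"name": "A", "parent": "B"},
                                 {"name": "B", "parent": "A"}]}
            )


# --- assignment ------------------------------------------------------------

def make_profile(reference, sites):
    return profile_from_site_list("s", "pop", sites, reference)


class TestAssignment:
    @pytest.mark.parametrize(
        "sites,expected",
        [
            # full T1b1 motif path
            ([(16050, "Ts"), (16113, "Ts"), (16255, "Ts"), (7542, "Ts"),
              (16022, "Ts")], "T1b1"),
            # reversion at 16255 forgiven because 7542 provides evidence
            ([(16050, "Ts"), (16113, "Ts"), (7542, "Ts")], "T1b"),
            # basal lineage: T1 markers but nothing downstream
            ([(16050, "Ts"), (16113, "Ts"), (16255, "Ts")], "T1"),
            # empty profile falls back to the root
            ([], "T"),
        ],
    )
    def test_spec_cases(self, reference_full, tree, sites, expected):
        assignment = assign_haplogroup(make_profile(reference_full, sites), tree)
        assert assignment.haplogroup == expected

    def test_reversion_recorded_as_missing(self, reference_full, tree):
        a = assign_haplogroup(
            make_profile(reference_full, [(16050, "Ts"), (16113, "Ts"), (7542, "Ts")]),
            tree,
        )
        assert a.haplogroup == "T1b"
        assert [m.position for m in a.missing] == [16255]
        assert a.score == 3

    def test_marker_below_branch_resolves_sibling_conflict(self, reference_full, tree):
        # carries both T1b and T1c markers; the 14523 transversion below
        # T1b1 pulls the assignment into the T1b branch, 16122 becomes a
        # conflict.
        a = assign_haplogroup(
            make_profile(
                reference_full,
                [(16050, "Ts"), (16113, "Ts"), (16255, "Ts"), (7542, "Ts"),
                 (16122, "Ts"), (14523, "AT"), (16022, "Ts")],
            ),
            tree,
        )
        assert "T1b" in tree.path(a.haplogroup)
        assert [m.position for m in a.conflicts] == [16122]

    def test_unresolved_sibling_tie_assigns_parent_with_conflicts(self, reference_full):
        tiny = HaplogroupTree(
            [
                HaplogroupNode("R", None),
                HaplogroupNode("A", "R", (MotifSite(10, "Ts"),)),
                HaplogroupNode("B", "R", (MotifSite(20, "Ts"),)),
            ]
        )
        a = assign_haplogroup(
            make_profile(reference_full, [(10, "Ts"), (20, "Ts")]), tiny
        )
        assert a.haplogroup == "R"
        assert {m.position for m in a.conflicts} == {10, 20}

    def test_pure_function_repeatable(self, reference_full, tree):
        profile = make_profile(reference_full, [(16050, "Ts"), (16113, "Ts")])
        first = assign_haplogroup(profile, tree)
        second = assign_haplogroup(profile, tree)
        assert first == second

    def test_monotone_in_child_evidence(self, reference_full, tree):
        # adding a variant matching a child motif never moves the
        # assignment to a shallower node
        base_sites = [(16050, "Ts"), (16113, "Ts"), (16255, "Ts")]
        before = assign_haplogroup(make_profile(reference_full, base_sites), tree)
        after = assign_haplogroup(
            make_profile(reference_full, base_sites + [(7542, "Ts")]), tree
        )
        assert tree.depth(after.haplogroup) >= tree.depth(before.haplogroup)

    def test_parameter_recovery_clean_profiles(self, reference_full, tree):
        # a profile carrying exactly the root-to-node motif path is
        # assigned to that node, for every node in the tree
        for name in tree.nodes:
            sites = [
                (m.position, "Ts" if m.change == "Ts" else m.change.replace(">", ""))
                for _, m in tree.path_motifs(name)
            ]
            a = assign_haplogroup(
                profile_from_site_list(name, "p", sites, reference_full), tree
            )
            assert a.haplogroup == name
            assert not a.missing


# --- brute-force oracle ----------------------------------------------------

def oracle_assign(profile, tree):
    """Independent hand-coded enumeration of the documented rules."""
    matches = {}
    for name, node in tree.nodes.items():
        matches[name] = [m for m in node.motif if m.matches(profile)]
    results = {}
    for name in tree.nodes:
        results[name] = sum(len(matches[n]) for n in tree.path(name))
    eligible = [n for n in tree.nodes if n == tree.root or matches[n]]
    best = max(results[n] for n in eligible)
    tied = [n for n in eligible if results[n] == best]
    deepest = max(len(tree.path(n)) for n in tied)
    tied = sorted(n for n in tied if len(tree.path(n)) == deepest)
    if len(tied) == 1:
        return tied[0]
    lca = tree.lca(tied)
    below = {n: results[n] - results[lca] for n in tied}
    most = max(below.values())
    tied = [n for n in tied if below[n] == most]
    return tied[0] if len(tied) == 1 else lca


def test_assignment_matches_bruteforce_enumeration(reference_full):
    rng = np.random.default_rng(42)
    positions = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120]
    for _ in range(200):
        # random tree of <= 6 nodes over the fixed position pool
        names = ["R", "A", "B", "C", "D", "E"][: int(rng.integers(3, 7))]
        nodes = [HaplogroupNode("R", None)]
        pool = list(rng.permutation(positions))
        for i, name in enumerate(names[1:], 1):
            parent = names[int(rng.integers(i))]
            n_motif = int(rng.integers(1, 3))
            motif = tuple(MotifSite(pool.pop(), "Ts") for _ in range(n_motif))
            nodes.append(HaplogroupNode(name, parent, motif))
        tree = HaplogroupTree(nodes)
        used = [m.position for n in nodes for m in n.motif]
        chosen = [p for p in used if rng.random() < 0.5][:8]
        profile = profile_from_site_list(
            "s", "p", [(p, "Ts") for p in chosen], reference_full
        )
        assert assign_haplogroup(profile, tree).haplogroup == oracle_assign(profile, tree)


# --- frequency table -------------------------------------------------------

class TestFrequencyTable:
    def test_single_sample(self, reference_full, tree):
        a = assign_haplogroup(
            make_profile(reference_full, [(16050, "Ts"), (16113, "Ts"), (16255, "Ts")]),
            tree,
        )
        table = frequency_table([a], tree)
        assert table.loc[0, "haplogroup"] == "T1"
        assert table.loc[0, "percent"] == 100.0

    def test_empty_input(self, tree):
        assert frequency_table([], tree).empty

    def test_fixture_counts_and_rollup(self, reference_full, tree, fixture_profiles):
        assignments = [assign_haplogroup(p, tree) for p in fixture_profiles]
        table = frequency_table(assignments, tree).set_index("haplogroup")
        assert table.loc["T1b", "count"] == 32
        assert table.loc["T1b", "percent"] == 91.4
        assert table.loc["T1", "count"] == 1
        assert table.loc["T1c", "count"] == 1
        assert table.loc["T1d", "count"] == 1
        # exactly three samples outside the T1b lineage
        outside = [
            a for a in assignments if "T1b" not in tree.path(a.haplogroup)
        ]
        assert len(outside) == 3
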