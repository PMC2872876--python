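"""Character matrices, Dollo loss placement, trajectories, conservation laws."""

import numpy as np
import pytest

from phylocov import (
    Character,
    TreeError,
    assign_gains,
    build_matrix,
    build_tally,
    compare_mappings,
    content_trajectory,
    losses_through_time,
    parse_gene_trees,
    parse_species_tree,
    place_losses_dollo,
    reconcile,
)

from ._oracles import brute_force_dollo, random_gene_tree_newick


def _results(newicks, stree):
    forest = parse_gene_trees("\n".join(newicks), stree)
    return [reconcile(gt, stree, tree_id=f"fam{i}") for i, gt in enumerate(forest)]


class TestBuildMatrix:
    def test_families_only_counts(self, three_species_tree):
        # 3 multi-gene families + 2 singletons
        results = _results(
            [
                "((g1_A,g1_B),g1_C);",
                "(g2_A,g2_B);",
                "(g3_B,g3_C);",
                "g4_A;",
                "g5_C;",
            ],
            three_species_tree,
        )
        matrix = build_matrix(results, three_species_tree, "families")
        assert len(matrix) == 5
        kinds = [c.kind for c in matrix.characters]
        assert kinds.count("singleton") == 2 and kinds.count("family") == 3

    def test_duplications_add_characters(self, three_species_tree):
        # one family with 2 duplications -> 1 family + 2 duplication characters
        results = _results(
            ["((g1_A,g2_A),(g3_B,g4_B));"], three_species_tree
        )
        assert results[0].n_duplications == 2
        fam_only = build_matrix(results, three_species_tree, "families")
        with_dups = build_matrix(results, three_species_tree, "with_duplications")
        assert len(fam_only) == 1
        assert len(with_dups) == 3

    def test_ubiquitous_family_origin_at_root(self, three_species_tree):
        results = _results(["((g1_A,g1_B),g1_C);"], three_species_tree)
        matrix = build_matrix(results, three_species_tree, "families")
        char = matrix.characters[0]
        assert char.origin == "Root"
        assert char.present == frozenset("ABC")

    def test_duplication_character_presence_within_origin_clade(
        self, eutherian_tree, rng
    ):
        species = eutherian_tree.leaf_labels
        newicks = [
            random_gene_tree_newick(int(rng.integers(2, 7)), species, rng)
            for _ in range(30)
        ]
        results = _results(newicks, eutherian_tree)
        matrix = build_matrix(results, eutherian_tree, "with_duplications")
        for c in matrix.characters:
            clade = eutherian_tree.leaf_set(eutherian_tree.node(c.origin))
            assert c.present <= clade

    def test_unknown_flavor_rejected(self, three_species_tree):
        with pytest.raises(ValueError, match="flavor"):
            build_matrix([], three_species_tree, "bogus")


class TestGains:
    def test_total_gains_equals_character_count(self, eutherian_tree, rng):
        species = eutherian_tree.leaf_labels
        newicks = [
            random_gene_tree_newick(int(rng.integers(1, 7)), species, rng)
            for _ in range(40)
        ]
        results = _results(newicks, eutherian_tree)
        for flavor in ("families", "with_duplications"):
            matrix = build_matrix(results, eutherian_tree, flavor)
            gains = assign_gains(matrix)
            assert sum(gains.values()) == len(matrix)

    def test_singleton_gain_on_terminal_branch(self, three_species_tree):
        matrix = build_matrix(
            _results(["g1_A;"], three_species_tree), three_species_tree, "families"
        )
        assert assign_gains(matrix) == {"A": 1}

    def test_duplication_gain_on_duplication_branch(self, eutherian_tree):
        # duplication of a boreoeutherian gene retained in primates and dog
        results = _results(
            ["((g1_Human,g1_Dog),(g2_Human,g2_Dog));"], eutherian_tree
        )
        matrix = build_matrix(results, eutherian_tree, "with_duplications")
        gains = assign_gains(matrix)
        assert gains["Boreoeutheria"] == 2  # family + duplication characters


class TestDolloPlacement:
    def test_two_terminal_losses(self, three_species_tree):
        char = Character("c", "family", "Root", frozenset({"A"}))
        assert sorted(place_losses_dollo(char, three_species_tree)) == ["B", "C"]

    def test_all_present_no_losses(self, three_species_tree):
        char = Character("c", "family", "Root", frozenset("ABC"))
        assert place_losses_dollo(char, three_species_tree) == []

    def test_absent_subtree_single_loss(self, three_species_tree):
        char = Character("c", "family", "Root", frozenset({"C"}))
        assert place_losses_dollo(char, three_species_tree) == ["AB"]

    def test_presence_outside_origin_clade_rejected(self, three_species_tree):
        char = Character("c", "family", "AB", frozenset({"C"}))
        with pytest.raises(TreeError, match="outside"):
            place_losses_dollo(char, three_species_tree)

    def test_minimality_against_brute_force(self, eutherian_tree, rng):
        """Dollo placement equals the exhaustive minimum (which is unique)."""
        internal = [
            n.label for n in eutherian_tree.root.preorder() if not n.is_leaf
        ]
        checked = 0
        while checked < 300:
            origin_label = internal[rng.integers(0, len(internal))]
            origin = eutherian_tree.node(origin_label)
            clade = sorted(eutherian_tree.leaf_set(origin))
            k = int(rng.integers(1, len(clade) + 1))
            present = frozenset(
                np.array(clade)[rng.choice(len(clade), size=k, replace=False)]
            )
            char = Character("c", "family", origin_label, present)
            ours = frozenset(place_losses_dollo(char, eutherian_tree))
            minima = brute_force_dollo(origin, present)
            assert len(minima) == 1, "Dollo minimum should be unique"
            assert ours == minima[0]
            checked += 1


class TestTrajectory:
    def test_no_events_flat_trajectory(self, eutherian_tree):
        results = _results(
            ["(((((g_Human,g_Chimp),(g_Mouse,g_Rat)),(g_Dog,g_Cow)),g_Tenrec),g_Opossum);"],
            eutherian_tree,
        )
        matrix = build_matrix(results, eutherian_tree, "families")
        tally = build_tally(matrix, eutherian_tree)
        traj = content_trajectory(tally, eutherian_tree, "Human")
        assert traj.contents == [1] * len(traj.contents)

    def test_terminal_gain_increments_endpoint(self, eutherian_tree):
        results = _results(["g1_Human;"], eutherian_tree)
        tally = build_tally(
            build_matrix(results, eutherian_tree, "families"), eutherian_tree
        )
        traj = content_trajectory(tally, eutherian_tree, "Human")
        assert traj.contents[-1] == traj.contents[-2] + 1

    def test_endpoint_equals_species_character_count(self, eutherian_tree, rng):
        """Leaf-end content equals the species' column sum in the matrix."""
        species = eutherian_tree.leaf_labels
        newicks = [
            random_gene_tree_newick(int(rng.integers(1, 7)), species, rng)
            for _ in range(60)
        ]
        results = _results(newicks, eutherian_tree)
        matrix = build_matrix(results, eutherian_tree, "with_duplications")
        tally = build_tally(matrix, eutherian_tree)
        for sp in species:
            traj = content_trajectory(tally, eutherian_tree, sp)
            assert traj.endpoint == matrix.presence_count(sp)

    def test_stepwise_conservation(self, eutherian_tree, rng):
        """content(child) = content(parent) + gains − losses at every step."""
        species = eutherian_tree.leaf_labels
        newicks = [
            random_gene_tree_newick(int(rng.integers(1, 6)), species, rng)
            for _ in range(40)
        ]
        tally = build_tally(
            build_matrix(_results(newicks, eutherian_tree), eutherian_tree,
                         "with_duplications"),
            eutherian_tree,
        )
        traj = content_trajectory(tally, eutherian_tree, "Cow")
        for prev, node, content in zip(traj.contents, traj.lineage[1:], traj.contents[1:]):
            assert content == prev + tally.gains_at(node) - tally.losses_at(node)

    def test_unknown_target_rejected(self, eutherian_tree):
        with pytest.raises(TreeError):
            content_trajectory(build_tally(
                build_matrix([], eutherian_tree, "families"), eutherian_tree
            ), eutherian_tree, "Platypus")


class TestLossesThroughTime:
    def test_sum_over_branches_is_total(self, eutherian_tree, rng):
        species = eutherian_tree.leaf_labels
        newicks = [
            random_gene_tree_newick(int(rng.integers(2, 6)), species, rng)
            for _ in range(30)
        ]
        tally = build_tally(
            build_matrix(_results(newicks, eutherian_tree), eutherian_tree, "families"),
            eutherian_tree,
        )
        table = losses_through_time(tally, eutherian_tree)
        assert table["losses"].sum() == tally.total_losses
        terminal = table[table["species"] != ""]
        assert set(terminal["species"]) <= set(species)


class TestCompareMappings:
    def test_identical_tallies_zero_delta_unit_ratio(self, eutherian_tree):
        results = _results(
            ["(((g_Human,g_Chimp),g_Mouse),g_Opossum);"], eutherian_tree
        )
        tally = build_tally(
            build_matrix(results, eutherian_tree, "families"), eutherian_tree
        )
        deltas, ratio = compare_mappings(tally, tally, eutherian_tree, "Human")
        assert (deltas["gain_delta"] == 0).all()
        assert all(r == pytest.approx(1.0) for r in ratio.contents)

    def test_extra_basal_gain_shifts_ratio(self, eutherian_tree):
        base = _results(
            ["(((g_Human,g_Chimp),g_Mouse),g_Opossum);"], eutherian_tree
        )
        tally_b = build_tally(
            build_matrix(base, eutherian_tree, "families"), eutherian_tree
        )
        import copy

        tally_a = copy.deepcopy(tally_b)
        tally_a.gains["Euarchontoglires"] = tally_a.gains.get("Euarchontoglires", 0) + 1
        deltas, ratio = compare_mappings(tally_a, tally_b, eutherian_tree, "Human")
        row = deltas.set_index("branch")
        assert row.loc["Euarchontoglires", "gain_delta"] == 1
        idx = ratio.lineage.index("Euarchontoglires")
        assert all(r > 1 for r in ratio.contents[idx:])
        assert all(r == pytest.approx(1.0) for r in ratio.contents[:idx])

    def test_alternative_root_topologies_redistribute_events(self):
        """Moving a basal lineage between alternative species trees moves
        gains/losses among the basal branches without making content negative."""
        # Same gene forest reconciled under three placements of lineage X.
        trees = {
            "afro_first": "(((A:10,B:10)AB:5,X:15)Core:5,O:20)Root;",
            "x_sister_a": "(((A:10,X:10)AX:5,B:15)Core:5,O:20)Root;",
            "x_outer": "(((A:10,B:10)AB:5,O:15)Core:5,X:20)Root;",
        }
        forest_newick = "((g_A,g_B),g_X);\n((g_A,g_X),g_B);\ng_O;"
        summaries = {}
        for name, newick in trees.items():
            stree = parse_species_tree(newick)
            results = _results(forest_newick.splitlines(), stree)
            tally = build_tally(
                build_matrix(results, stree, "with_duplications"), stree
            )
            summaries[name] = (tally.total_gains, tally.total_losses)
            for sp in stree.leaf_labels:
                traj = content_trajectory(tally, stree, sp)
                assert all(c >= 0 for c in traj.contents)
        assert len(set(summaries.values())) > 1  # placement changes the mapping
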