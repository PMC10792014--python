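from collections import Counter

import pandas as pd
import pytest

from phylofam.complements import (
    aggregate_groups,
    copy_numbers,
    duplication_bursts,
    origin_node,
    orthogroups,
    presence_matrix,
)
from phylofam.reconcile import reconcile
from phylofam.simulate import SimParams, simulate_family, true_reconciliation
from phylofam.treeio import SpeciesTree, leaf_species_map, parse_newick


def recon_of(newick, species_newick="((A,B)AB,C)R;"):
    st = SpeciesTree.from_newick(species_newick)
    gt = parse_newick(newick)
    lmap = {l: l.split("_")[0] for l in gt.leaf_labels()}
    return reconcile(gt, st, lmap), st


class TestCopyNumbers:
    def test_congruent_single_copy(self):
        recon, st = recon_of("((A_1,B_1),C_1);")
        series = copy_numbers(recon)
        assert all(series[label] == 1 for label in st.node_labels())

    def test_one_duplication_at_internal_node(self):
        recon, st = recon_of("((A_1,B_1),(A_2,B_2),C_1);".replace(
            "((A_1,B_1),(A_2,B_2),C_1)", "(((A_1,B_1),(A_2,B_2)),C_1)"
        ))
        series = copy_numbers(recon)
        assert series["R"] == 1
        assert series["AB"] == 2
        assert series["A"] == 2
        assert series["B"] == 2
        assert series["C"] == 1

    def test_zero_outside_origin_subtree(self):
        recon, st = recon_of("(A_1,B_1);")
        series = copy_numbers(recon)
        assert series["AB"] == 1 and series["A"] == 1 and series["B"] == 1
        assert series["R"] == 0 and series["C"] == 0

    def test_equals_event_log_replay_on_simulations(self, species12):
        checked = 0
        for seed in range(1000):
            gt, log = simulate_family(species12, SimParams(0.5, 0.2, seed=seed))
            if gt is None:
                continue
            recon = true_reconciliation(gt, species12)
            series = copy_numbers(recon)
            replay = log.replay(species12, mode="observable")
            for label in species12.node_labels():
                assert int(series[label]) == replay[label], (seed, label)
            checked += 1
        assert checked > 950

    def test_leaf_conservation_and_edge_balance(self, species12):
        for seed in range(200):
            gt, _ = simulate_family(species12, SimParams(0.6, 0.3, seed=seed))
            if gt is None:
                continue
            recon = true_reconciliation(gt, species12)
            series = copy_numbers(recon)
            counts = Counter(l.split("_")[0] for l in gt.leaf_labels())
            for sp in species12.leaf_labels():
                assert int(series[sp]) == counts.get(sp, 0)
            dups = recon.duplications_by_species()
            losses = recon.losses_by_species_edge
            origin = recon.origin()
            for parent, child in species12.edges():
                if not species12.is_ancestor_or_equal(origin, parent):
                    continue
                assert (
                    int(series[child.label]) - int(series[parent.label])
                    == dups.get(child.label, 0) - losses.get(child.label, 0)
                )


class TestOriginNode:
    def test_single_gene_family(self):
        recon, _ = recon_of("(A_1,A_2);")
        # both genes in A: family originates in A despite the 2-leaf tree
        assert origin_node(recon) == "A"

    def test_span_forces_lca_origin(self):
        recon, _ = recon_of("(A_1,C_1);")
        assert origin_node(recon) == "R"

    def test_simulated_origin_matches_log_unless_masked(self, species12):
        agree = masked = 0
        for seed in range(300):
            gt, log = simulate_family(species12, SimParams(0.4, 0.3, seed=seed))
            if gt is None:
                continue
            recon = true_reconciliation(gt, species12)
            replay = log.replay(species12, mode="observable")
            got = origin_node(recon)
            if got == log.root_species:
                agree += 1
            else:
                # masked by basal losses: no observable lineage above
                masked += 1
                node = species12.node(got).parent
                while node is not None:
                    assert replay[node.label] == 0
                    node = node.parent
        assert agree > 0 and masked > 0


class TestOrthogroups:
    def test_cut_at_root_duplication(self):
        recon, _ = recon_of("((A_X1,B_X1),(A_X2,B_X2));", "(A,B)AB;")
        lmap = {l: l.split("_")[0] for l in recon.gene_tree.leaf_labels()}
        asg = orthogroups(recon, lmap, ["A"])
        assert set(asg.groups()) == {"X1", "X2"}
        assert asg.assignment["B_X1"] == "X1"

    def test_no_duplications_single_group(self):
        recon, _ = recon_of("((A_g,B_g),C_g);")
        lmap = {l: l.split("_")[0] for l in recon.gene_tree.leaf_labels()}
        asg = orthogroups(recon, lmap, ["A"])
        assert len(asg.groups()) == 1

    def test_unnamed_groups_deterministic(self):
        recon, _ = recon_of("((B_1,B_2),C_1);")
        lmap = {l: l.split("_")[0] for l in recon.gene_tree.leaf_labels()}
        asg = orthogroups(recon, lmap, ["A"])  # A absent: nothing named
        # cutting the B duplication splits {B_1}, {B_2}, {C_1}
        assert sorted(asg.groups()) == ["unnamed-1", "unnamed-2", "unnamed-3"]
        again = orthogroups(recon, lmap, ["A"])
        assert asg.assignment == again.assignment

    def test_cut_above_restricts_cut_set(self):
        # nested duplications: one at R (deep) and one at A (shallow);
        # cutting only at/above AB keeps the A-duplication together
        newick = "(((A_x,A_y),(B_x,B_y)),((A_z,B_z),C_z));"
        recon, st = recon_of(newick)
        lmap = {l: l.split("_")[0] for l in recon.gene_tree.leaf_labels()}
        all_cuts = orthogroups(recon, lmap, ["A"])
        deep_only = orthogroups(recon, lmap, ["A"], cut_above="AB")
        # full cutting splits the A_x/A_y duplication; restricted does not
        assert len(all_cuts.groups()) > len(deep_only.groups())
        deep_groups = {frozenset(v) for v in deep_only.groups().values()}
        assert frozenset({"A_x", "A_y", "B_x", "B_y"}) in deep_groups
        assert frozenset({"A_z", "B_z", "C_z"}) in deep_groups


class TestPresenceMatrix:
    def test_all_present_and_absent_rows(self):
        recon, st = recon_of("((A_g,B_g),C_g);")
        lmap = {l: l.split("_")[0] for l in recon.gene_tree.leaf_labels()}
        asg = orthogroups(recon, lmap, ["A"], family="fam0")
        matrix = presence_matrix([asg], ["A", "B", "C", "D"])
        assert matrix.loc["A", "g"] and matrix.loc["C", "g"]
        assert not matrix.loc["D"].any()

    def test_matches_direct_leaf_count(self, species12):
        assignments = []
        for seed in range(30):
            gt, _ = simulate_family(species12, SimParams(0.5, 0.2, seed=seed))
            if gt is None:
                continue
            recon = true_reconciliation(gt, species12)
            lmap = leaf_species_map(gt, species12)
            assignments.append(
                orthogroups(recon, lmap, ["Hsap"], family=f"f{seed}")
            )
        matrix = presence_matrix(assignments, species12.leaf_labels())
        for asg in assignments:
            for group, members in asg.groups().items():
                species_present = {asg.leaf_species[m] for m in members}
                for sp in species12.leaf_labels():
                    if sp in species_present:
                        assert matrix.loc[sp, group]


class TestDuplicationBursts:
    def test_no_duplications_all_zero(self):
        recon, st = recon_of("((A_1,B_1),C_1);")
        table = duplication_bursts([recon], st)
        assert (table["duplications"] == 0).all()

    def test_burst_localised_by_rate_override(self, species12):
        params = SimParams(0.0, 0.0,
                           overrides={"Gnathostomata": (5.0, 0.0)})
        recons = []
        for seed in range(100):
            p = SimParams(0.0, 0.0, dict(params.overrides), seed)
            gt, log = simulate_family(species12, p)
            lmap = leaf_species_map(gt, species12)
            recons.append(reconcile(gt, species12, lmap))
        table = duplication_bursts(recons, species12)
        others = table.drop(index="Gnathostomata")
        assert (others["duplications"] == 0).all()
        assert table.loc["Gnathostomata", "duplications"] > 0

    def test_counts_match_event_log_when_loss_free(self, species12):
        for seed in range(100):
            gt, log = simulate_family(species12, SimParams(0.5, 0.0, seed=seed))
            recon = reconcile(gt, species12, leaf_species_map(gt, species12))
            table = duplication_bursts([recon], species12)
            logged = log.duplications_by_edge()
            for label in species12.node_labels():
                assert table.loc[label, "duplications"] == logged.get(label, 0)


class TestAggregateGroups:
    def _columns(self):
        recon_a, st = recon_of("((A_1,B_1),C_1);")
        recon_b, _ = recon_of("((A_2,B_2),C_2);")
        return {
            "fam_a": copy_numbers(recon_a),
            "fam_b": copy_numbers(recon_b),
        }, st

    def test_two_families_one_group(self):
        columns, st = self._columns()
        table = aggregate_groups(columns, {"fam_a": "g", "fam_b": "g"})
        assert (table["g"] == 2).all()

    def test_identity_grouping(self):
        columns, _ = self._columns()
        table = aggregate_groups(
            columns, {"fam_a": "fam_a", "fam_b": "fam_b"}
        )
        pd.testing.assert_series_equal(table["fam_a"], columns["fam_a"],
                                       check_names=False)

    def test_row_sums_invariant_under_regrouping(self):
        columns, _ = self._columns()
        one = aggregate_groups(columns, {"fam_a": "x", "fam_b": "x"})
        two = aggregate_groups(columns, {"fam_a": "x", "fam_b": "y"})
        pd.testing.assert_series_equal(
            one.sum(axis=1), two.sum(axis=1)
        )

    def test_unassigned_family_rejected(self):
        columns, _ = self._columns()
        with pytest.raises(ValueError, match="fam_b"):
            aggregate_groups(columns, {"fam_a": "g"})
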