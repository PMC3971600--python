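"""Parsimony trait mapping: Fitch/Sankoff, scenario regimes, LGT flagging."""

import itertools

import numpy as np
import pytest

from phylopan import synth
from phylopan.evolution import (
    CostScheme,
    fitch_count,
    lgt_flag,
    root_on_outgroup,
    sankoff_scenarios,
    scenario_table,
)
from phylopan.phylo import PerSiteScoreMatrix, read_tree


def _exhaustive_min_cost(tree, states, gain, loss, root_state=None):
    """Brute force over all interior labelings (independent oracle)."""
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = float("inf")
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), combo))
        root = tree.seed_node
        if root_state is not None and assign[id(root)] != root_state:
            continue
        cost = 0.0
        for node in tree.postorder_node_iter():
            if node is root:
                continue
            s = (
                states[node.taxon.label]
                if node.is_leaf()
                else assign[id(node)]
            )
            p = assign[id(node.parent_node)]
            if p == 0 and s == 1:
                cost += gain
            elif p == 1 and s == 0:
                cost += loss
        best = min(best, cost)
    return best


def _random_instance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    st = synth.simulate_species_tree(n, seed=seed)
    tree = st.tree
    states = {tip: int(rng.integers(0, 2)) for tip in st.tip_order}
    return tree, states, rng


class TestFitch:
    def test_uniform_tips_need_no_changes(self):
        tree = read_tree("((A,B),(C,D));")
        assert fitch_count(tree, {t: 1 for t in "ABCD"}).changes == 0

    def test_one_informative_split_is_one_change(self):
        tree = read_tree("((A,B),(C,D));")
        assert fitch_count(tree, {"A": 1, "B": 1, "C": 0, "D": 0}).changes == 1

    def test_missing_tip_state_rejected(self):
        tree = read_tree("((A,B),(C,D));")
        with pytest.raises(ValueError, match="missing"):
            fitch_count(tree, {"A": 1, "B": 0, "C": 1})

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_unit_cost_sankoff_and_oracle(self, seed):
        tree, states, _ = _random_instance(seed)
        f = fitch_count(tree, states).changes
        s = sankoff_scenarios(tree, states, CostScheme(1, 1)).min_cost
        o = _exhaustive_min_cost(tree, states, 1, 1)
        assert f == s == o


class TestSankoff:
    @pytest.mark.parametrize("seed", range(10))
    def test_weighted_costs_match_exhaustive_oracle(self, seed):
        tree, states, rng = _random_instance(100 + seed)
        gain = float(rng.integers(1, 4))
        loss = float(rng.integers(1, 4))
        result = sankoff_scenarios(tree, states, CostScheme(gain, loss))
        assert result.min_cost == _exhaustive_min_cost(tree, states, gain, loss)

    def test_every_scenario_replays_to_the_tips(self):
        tree, states, _ = _random_instance(55)
        result = sankoff_scenarios(tree, states, CostScheme(2, 1))
        assert result.scenarios
        for scenario in result.scenarios:
            assert scenario.replay(tree) == states

    def test_costly_gains_prefer_single_origin(self):
        # trait in a 5-tip clade plus one outlier; gain 2 / loss 1, root 0
        tree = read_tree("((((A,B),(C,D)),E),((F,G),H));")
        states = dict.fromkeys("ABCDE", 1) | dict.fromkeys("FGH", 0)
        states["F"] = 1
        result = sankoff_scenarios(
            tree, states, CostScheme(gain=2, loss=1), root_state=0
        )
        oracle = _exhaustive_min_cost(tree, states, 2, 1, root_state=0)
        assert result.min_cost == oracle
        for scenario in result.scenarios:
            assert scenario.cost == result.min_cost
            assert scenario.replay(tree) == states

    def test_fixed_presence_root_yields_loss_only_scenarios(self):
        tree = read_tree("(((A,B),(C,D)),((E,F),(G,H)));")
        states = dict.fromkeys("ABCD", 0) | dict.fromkeys("EFGH", 1)
        result = sankoff_scenarios(tree, states, root_state=1)
        assert result.min_cost == 1
        scenario = result.scenarios[0]
        assert scenario.n_gains == 0 and scenario.n_losses == 1

    def test_all_zero_costs_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(0, 0)


class TestScenarioTable:
    def test_two_cherries_on_a_caterpillar(self):
        tree = read_tree("((A,B),(C,(D,(E,(F,(G,H))))));")
        # trait in the two cherries {A,B} and {G,H}
        states = dict.fromkeys("ABGH", 1) | dict.fromkeys("CDEF", 0)
        table = scenario_table(tree, states)
        assert table.loss_free_gains == 2
        assert table.dollo_gains == 1
        assert table.fitch_changes <= table.dollo_gains + table.dollo_losses
        assert table.fitch_changes <= table.loss_free_gains

    def test_single_clade_agrees_across_regimes(self):
        tree = read_tree("(((A,B),C),((D,E),F));")
        states = dict.fromkeys("AB", 1) | dict.fromkeys("CDEF", 0)
        table = scenario_table(tree, states)
        assert table.dollo_gains == 1 and table.dollo_losses == 0
        assert table.loss_free_gains == 1
        assert table.fitch_changes == 1

    def test_absent_trait_gives_empty_scenarios(self):
        tree = read_tree("((A,B),(C,D));")
        table = scenario_table(tree, {t: 0 for t in "ABCD"})
        assert (table.dollo_gains, table.loss_free_gains, table.fitch_changes) == (0, 0, 0)

    def test_habitat_loss_pattern_counts_loss_clades(self):
        # presence everywhere except two separated cherries: two Dollo losses
        tree = read_tree("(((A,B),(C,D)),((E,F),(G,H)));")
        states = dict.fromkeys("ABEF", 1) | dict.fromkeys("CDGH", 0)
        table = scenario_table(tree, states)
        assert table.dollo_gains == 1 and table.dollo_losses == 2
        # positives confined to one clade need no Dollo losses at all
        confined = dict.fromkeys("ABCD", 1) | dict.fromkeys("EFGH", 0)
        assert scenario_table(tree, confined).dollo_losses == 0


class TestRooting:
    def test_outgroup_rooting_places_outgroup_basal(self):
        tree = read_tree("((A,B),(C,D),(O1,O2));")
        rooted = root_on_outgroup(tree, ["O1", "O2"])
        children = rooted.seed_node.child_nodes()
        clades = [
            frozenset(l.taxon.label for l in c.leaf_iter()) for c in children
        ]
        assert frozenset({"O1", "O2"}) in clades

    def test_unknown_outgroup_rejected(self):
        tree = read_tree("((A,B),(C,D));")
        with pytest.raises(ValueError, match="outgroup"):
            root_on_outgroup(tree, ["Z"])


class TestLgtFlag:
    def test_identical_topologies_are_never_flagged(self):
        tree = read_tree("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        x = np.random.default_rng(0).normal(size=100)
        scores = PerSiteScoreMatrix(["reference", "gene"], np.vstack([x, x]))
        result = lgt_flag(tree, tree, scores, alpha=0.001)
        assert result.evaluable and not result.flagged
        assert result.spr.value == 0

    def test_too_few_shared_taxa_not_evaluable(self):
        t1 = read_tree("((A,B),(C,X));")
        t2 = read_tree("((A,B),(Y,Z));")
        scores = PerSiteScoreMatrix(
            ["reference", "gene"], np.zeros((2, 50)) + np.arange(50)
        )
        result = lgt_flag(t1, t2, scores)
        assert not result.evaluable

    def test_strong_discordance_is_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=300)
        # the gene topology dominates site-wise: reference should be rejected
        scores = PerSiteScoreMatrix(
            ["reference", "gene"], np.vstack([base, base + 0.08])
        )
        t1 = read_tree("((A,B),(C,D),E);")
        t2 = read_tree("((A,C),(B,D),E);")
        result = lgt_flag(t2, t1, scores, alpha=0.001, reference_id="reference")
        assert result.flagged and result.spr.value >= 1
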