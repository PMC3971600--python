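"""Parsimony mapping of binary traits onto trees and LGT flagging.

Gains and losses of a trait (e.g. butyrate-pathway presence, sporulation
capability) are placed on a rooted tree by Fitch and Sankoff parsimony.
Branches are identified by the set of tip labels below them, which makes
event lists replayable and stable across tree copies.  Three named regimes
summarize competing historical readings of a tip pattern:

* Dollo — a single origin (gain at the MRCA of the positive tips), losses
  unrestricted: "ancient acquisition followed by lineage-specific loss";
* loss-free — independent gains only: one gain per maximal positive clade;
* unconstrained — the Fitch minimum-change count with a free root state.

``lgt_flag`` combines the AU test on per-site log-likelihood scores with the
SPR distance: a gene whose alignment significantly rejects the reference
(vertical-inheritance proxy) topology is flagged as a lateral-transfer
candidate.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import dendropy

from .phylo.autest import DEFAULT_SCALES, au_test
from .phylo.likelihood import PerSiteScoreMatrix
from .phylo.treedist import SprResult, restrict_tree, spr_distance, tip_labels

Clade = frozenset


def root_on_outgroup(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Return a copy rooted on the branch leading to the given outgroup taxa."""
    clone = dendropy.Tree(tree)
    clone.is_rooted = True
    taxa = [clone.taxon_namespace.get_taxon(label) for label in outgroup]
    if any(t is None for t in taxa):
        raise ValueError(f"outgroup taxa not in tree: {outgroup}")
    if len(taxa) == 1:
        node = clone.find_node_with_taxon_label(outgroup[0])
    else:
        node = clone.mrca(taxa=taxa)
    clone.reroot_at_edge(node.edge, update_bipartitions=False)
    return clone


def _check_states(tree: dendropy.Tree, states: Mapping[str, int]) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(states)
    if missing:
        raise ValueError(f"missing tip states: {sorted(missing)}")
    bad = [k for k in states if states[k] not in (0, 1)]
    if bad:
        raise ValueError(f"states must be 0/1, got bad values for {bad}")


def _clade(node) -> Clade:
    return Clade(l.taxon.label for l in node.leaf_iter())


@dataclass
class FitchResult:
    changes: int
    state_sets: dict  # clade -> frozenset of states


def fitch_count(tree: dendropy.Tree, states: Mapping[str, int]) -> FitchResult:
    """Fitch small parsimony: minimum state changes and per-node state sets.

    The root state is unconstrained.  Internal nodes may be multifurcating;
    children are folded pairwise in order, which reproduces classic Fitch on
    binary trees.
    """
    _check_states(tree, states)
    sets: dict = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([states[node.taxon.label]])
            continue
        children = node.child_nodes()
        acc = sets[id(children[0])]
        for child in children[1:]:
            inter = acc & sets[id(child)]
            if inter:
                acc = inter
            else:
                acc = acc | sets[id(child)]
                changes += 1
        sets[id(node)] = acc
    state_sets = {}
    for node in tree.postorder_node_iter():
        state_sets[_clade(node)] = sets[id(node)]
    return FitchResult(changes=changes, state_sets=state_sets)


@dataclass(frozen=True)
class CostScheme:
    gain: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        if self.gain < 0 or self.loss < 0:
            raise ValueError("costs must be non-negative")
        if self.gain == 0 and self.loss == 0:
            raise ValueError("at least one cost must be positive")


@dataclass
class EventScenario:
    """One parsimony history: a root state plus per-branch gain/loss events."""

    root_state: int
    events: list  # (clade below the branch, "gain" | "loss")
    cost: float

    @property
    def n_gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == "gain")

    @property
    def n_losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == "loss")

    def replay(self, tree: dendropy.Tree) -> dict[str, int]:
        """Propagate the root state through the event list; returns tip states."""
        events = dict(self.events)
        if len(events) != len(self.events):
            raise ValueError("duplicate branch in event list")
        out: dict[str, int] = {}

        def walk(node, state):
            clade = _clade(node)
            if clade in events:
                kind = events[clade]
                if kind == "gain" and state == 1:
                    raise ValueError("gain on a branch already carrying the trait")
                if kind == "loss" and state == 0:
                    raise ValueError("loss of an absent trait")
                state = 1 if kind == "gain" else 0
            if node.is_leaf():
                out[node.taxon.label] = state
            for child in node.child_nodes():
                walk(child, state)

        walk(tree.seed_node, self.root_state)
        return out


@dataclass
class SankoffResult:
    min_cost: float
    scenarios: list[EventScenario]
    complete: bool  # False when enumeration hit the cap
    root_state_costs: dict


def sankoff_scenarios(
    tree: dendropy.Tree,
    states: Mapping[str, int],
    costs: CostScheme = CostScheme(),
    root_state: int | None = None,
    max_scenarios: int = 100,
) -> SankoffResult:
    """Weighted parsimony with enumeration of co-optimal event histories.

    Dynamic programming minimizes the summed event cost (state 0->1 on a
    branch costs ``costs.gain``, 1->0 costs ``costs.loss``).  All co-optimal
    scenarios are enumerated by backtracking, up to ``max_scenarios``.
    """
    _check_states(tree, states)
    if root_state is not None and root_state not in (0, 1):
        raise ValueError("root_state must be 0 or 1")
    INF = float("inf")
    trans = [[0.0, costs.gain], [costs.loss, 0.0]]

    cost_table: dict[int, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            cost_table[id(node)] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
            continue
        row = []
        for s in (0, 1):
            total = 0.0
            for child in node.child_nodes():
                total += min(
                    trans[s][t] + cost_table[id(child)][t] for t in (0, 1)
                )
            row.append(total)
        cost_table[id(node)] = row

    root = tree.seed_node
    root_costs = {s: cost_table[id(root)][s] for s in (0, 1)}
    if root_state is not None:
        min_cost = root_costs[root_state]
        root_choices = [root_state]
    else:
        min_cost = min(root_costs.values())
        root_choices = [s for s in (0, 1) if root_costs[s] == min_cost]
    if min_cost == INF:
        raise ValueError("tip states unreachable under the fixed root state")

    def optimal_child_states(child, parent_state):
        best = min(trans[parent_state][t] + cost_table[id(child)][t] for t in (0, 1))
        return [
            t
            for t in (0, 1)
            if trans[parent_state][t] + cost_table[id(child)][t] == best
        ]

    def assignments(node, state):
        """Yield per-subtree {clade: state} maps that achieve the optimum."""
        if node.is_leaf():
            yield {_clade(node): state}
            return
        child_options = []
        for child in node.child_nodes():
            opts = []
            for t in optimal_child_states(child, state):
                opts.extend(assignments(child, t))
            child_options.append(opts)
        for combo in itertools.product(*child_options):
            merged = {_clade(node): state}
            for part in combo:
                merged.update(part)
            yield merged

    scenarios: list[EventScenario] = []
    complete = True
    for rs in root_choices:
        for assignment in assignments(root, rs):
            events = []
            for node in tree.preorder_node_iter():
                if node is root:
                    continue
                parent_state = assignment[_clade(node.parent_node)]
                state = assignment[_clade(node)]
                if state != parent_state:
                    events.append((_clade(node), "gain" if state == 1 else "loss"))
            scenarios.append(EventScenario(root_state=rs, events=events, cost=min_cost))
            if len(scenarios) >= max_scenarios:
                complete = False
                break
        if not complete:
            break
    return SankoffResult(
        min_cost=min_cost,
        scenarios=scenarios,
        complete=complete,
        root_state_costs=root_costs,
    )


@dataclass
class ScenarioTable:
    """Gain/loss totals under the three named parsimony regimes."""

    dollo_gains: int
    dollo_losses: int
    loss_free_gains: int
    fitch_changes: int
    dollo_events: list = field(default_factory=list)
    loss_free_events: list = field(default_factory=list)


def _maximal_state_clades(node, states: Mapping[str, int], target: int) -> list:
    """Maximal subtrees below ``node`` whose tips are all in ``target`` state."""
    found: list = []

    def pure(n) -> bool:
        return all(states[l.taxon.label] == target for l in n.leaf_iter())

    def walk(n):
        if pure(n):
            found.append(_clade(n))
            return
        for child in n.child_nodes():
            walk(child)

    walk(node)
    return found


def scenario_table(tree: dendropy.Tree, states: Mapping[str, int]) -> ScenarioTable:
    """Compare single-origin (Dollo), independent-gain, and Fitch readings."""
    _check_states(tree, states)
    tree.is_rooted = True  # trait mapping reads the seed node as the root
    positives = [tip for tip, s in states.items() if s == 1]
    if not positives:
        return ScenarioTable(0, 0, 0, 0)
    fitch = fitch_count(tree, states).changes

    # loss-free: one gain per maximal all-positive clade (root assumed absent)
    gain_clades = _maximal_state_clades(tree.seed_node, states, 1)
    loss_free_events = [(c, "gain") for c in gain_clades]

    # Dollo: single gain at the MRCA of the positive tips, then minimal losses
    if len(positives) == len(states):
        mrca = tree.seed_node
    else:
        mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in positives])
    loss_clades = _maximal_state_clades(mrca, states, 0)
    dollo_events = [(_clade(mrca), "gain")] + [(c, "loss") for c in loss_clades]

    return ScenarioTable(
        dollo_gains=1,
        dollo_losses=len(loss_clades),
        loss_free_gains=len(gain_clades),
        fitch_changes=fitch,
        dollo_events=dollo_events,
        loss_free_events=loss_free_events,
    )


@dataclass
class LgtFlagResult:
    evaluable: bool
    flagged: bool = False
    p_value: float = float("nan")
    spr: SprResult | None = None
    n_shared_taxa: int = 0


def lgt_flag(
    gene_tree: dendropy.Tree,
    reference_tree: dendropy.Tree,
    scores: PerSiteScoreMatrix,
    alpha: float = 0.001,
    reference_id: str | None = None,
    seed: int = 0,
    n_reps: int = 1000,
    scale_factors=DEFAULT_SCALES,
    exact_leaf_limit: int = 8,
) -> LgtFlagResult:
    """Flag a gene as a lateral-transfer candidate by topology-test rejection.

    The AU test is run on the per-site scores (computed on the gene alignment
    for both the gene topology and the reference topology); the gene is
    flagged iff the reference topology's AU p-value falls below ``alpha``.
    The SPR distance between the two trees on their shared taxa is reported
    as a companion summary.  Fewer than 4 shared taxa -> not evaluable.
    """
    shared = tip_labels(gene_tree) & tip_labels(reference_tree)
    if len(shared) < 4:
        return LgtFlagResult(evaluable=False, n_shared_taxa=len(shared))
    ref_id = reference_id or scores.topology_ids[0]
    if ref_id not in scores.topology_ids:
        raise ValueError(f"reference topology {ref_id!r} not in score matrix")
    results = au_test(scores, scale_factors=scale_factors, n_reps=n_reps, seed=seed)
    p = results[ref_id].p_value
    spr = spr_distance(
        restrict_tree(gene_tree, shared),
        restrict_tree(reference_tree, shared),
        exact_leaf_limit=exact_leaf_limit,
    )
    return LgtFlagResult(
        evaluable=True,
        flagged=p < alpha,
        p_value=p,
        spr=spr,
        n_shared_taxa=len(shared),
    )
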