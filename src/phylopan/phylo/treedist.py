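"""Topological comparison of unrooted trees: splits, RF, SPR, consensus networks.

Splits (bipartitions of the taxon set) are represented canonically as the
frozenset of labels on the side containing the lexicographically smallest
taxon, which makes split sets directly comparable across trees and usable as
hash keys.  The SPR distance is computed exactly for small trees by
breadth-first search over the SPR graph with canonical-topology
deduplication; beyond the exact limit, certified bounds are reported (a
greedy leaf-deletion agreement bound from above, the trivial bound from
below).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy

Split = frozenset


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string, preserving underscores in labels."""
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def tip_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _canonical(block: frozenset, taxa: frozenset) -> Split:
    smallest = min(taxa)
    return Split(block) if smallest in block else Split(taxa - block)


def tree_splits(tree: dendropy.Tree, include_trivial: bool = False) -> set:
    """Canonical splits of a tree (nontrivial only unless requested)."""
    taxa = tip_labels(tree)
    n = len(taxa)
    splits = set()
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        block = frozenset(l.taxon.label for l in node.leaf_iter())
        size = len(block)
        if 2 <= size <= n - 2:
            splits.add(_canonical(block, taxa))
        elif include_trivial and (size == 1 or size == n - 1):
            splits.add(_canonical(block, taxa))
    if include_trivial:
        for label in taxa:
            splits.add(_canonical(frozenset([label]), taxa))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: splits present in exactly one tree."""
    taxa1, taxa2 = tip_labels(t1), tip_labels(t2)
    if taxa1 != taxa2:
        raise ValueError("trees must share an identical taxon set")
    return len(tree_splits(t1) ^ tree_splits(t2))


def restrict_tree(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Copy of the tree restricted to a taxon subset (unifurcations suppressed)."""
    taxa = set(taxa)
    clone = dendropy.Tree(tree)
    clone.retain_taxa_with_labels(taxa)
    clone.suppress_unifurcations()
    return clone


# ---------------------------------------------------------------------------
# SPR distance
# ---------------------------------------------------------------------------


def _tree_to_adjacency(tree: dendropy.Tree):
    """Unrooted adjacency map {node_id: set(node_id)} plus leaf labels."""
    ids: dict = {}
    adj: dict[int, set[int]] = {}
    labels: dict[int, str] = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adj[ids[node]] = set()
        return ids[node]

    for node in tree.preorder_node_iter():
        i = nid(node)
        if node.is_leaf():
            labels[i] = node.taxon.label
        for child in node.child_nodes():
            j = nid(child)
            adj[i].add(j)
            adj[j].add(i)
    # unroot: splice out a degree-2 seed node
    seed = ids[tree.seed_node]
    if len(adj[seed]) == 2:
        a, b = sorted(adj[seed])
        adj[a].discard(seed)
        adj[b].discard(seed)
        adj[a].add(b)
        adj[b].add(a)
        del adj[seed]
    return adj, labels


def _adjacency_splits(adj, labels) -> frozenset:
    """Canonical nontrivial split set of an unrooted adjacency topology."""
    taxa = frozenset(labels.values())
    n = len(taxa)
    if n < 4:
        return frozenset()
    root = next(i for i in adj if i in labels)
    below: dict[int, frozenset] = {}
    order = []
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    splits = set()
    for node, parent in reversed(order):
        if node in labels:
            below[node] = frozenset([labels[node]])
        else:
            block = frozenset().union(*(below[c] for c in adj[node] if c != parent))
            below[node] = block
            if 2 <= len(block) <= n - 2:
                splits.add(_canonical(block, taxa))
    return frozenset(splits)


def _component(adj, start: int, blocked: frozenset) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if frozenset((node, nb)) == blocked or nb in seen:
                continue
            seen.add(nb)
            stack.append(nb)
    return seen


def _spr_neighbors(adj, labels):
    """All adjacency topologies one unrooted SPR move away."""
    next_id = max(adj) + 1
    edges = {frozenset((u, v)) for u in adj for v in adj[u]}
    for edge in edges:
        for u, v in ((min(edge), max(edge)), (max(edge), min(edge))):
            # prune the component on v's side; u must be internal
            if u in labels:
                continue
            x, y = sorted(adj[u] - {v})
            remaining = _component(adj, u, frozenset((u, v))) - {u}
            sub_edges = {
                frozenset((p, q))
                for p in remaining
                for q in adj[p]
                if q in remaining and frozenset((p, q)) != frozenset((u, v))
            }
            for redge in sub_edges:
                p, q = sorted(redge)
                if {p, q} == {x, y}:
                    continue  # regraft in place: original topology
                new = {node: set(nbs) for node, nbs in adj.items()}
                # detach and suppress u
                new[u].discard(v)
                new[v].discard(u)
                del new[u]
                new[x].discard(u)
                new[y].discard(u)
                new[x].add(y)
                new[y].add(x)
                # regraft v onto subdivided edge (p, q)
                w = next_id
                new[p].discard(q)
                new[q].discard(p)
                new[w] = {p, q, v}
                new[p].add(w)
                new[q].add(w)
                new[v].add(w)
                yield new


def _restricted_split_set(splits, taxa_keep: frozenset) -> frozenset:
    n = len(taxa_keep)
    out = set()
    for block in splits:
        sub = block & taxa_keep
        if 2 <= len(sub) <= n - 2:
            out.add(_canonical(frozenset(sub), taxa_keep))
    return frozenset(out)


def _leaf_deletion_upper_bound(splits1, splits2, taxa: frozenset) -> int:
    """Greedy agreement-by-leaf-deletion bound: if removing k leaves makes the
    trees identical, they are at most k SPR moves apart (each deleted leaf can
    be re-placed with one move)."""
    keep = frozenset(taxa)
    removed = 0
    while _restricted_split_set(splits1, keep) != _restricted_split_set(splits2, keep):
        best = None
        for leaf in sorted(keep):
            trial = keep - {leaf}
            rf = len(
                _restricted_split_set(splits1, trial)
                ^ _restricted_split_set(splits2, trial)
            )
            if best is None or rf < best[0]:
                best = (rf, leaf)
        keep = keep - {best[1]}
        removed += 1
    return removed


@dataclass(frozen=True)
class SprResult:
    value: int
    exact: bool
    lower: int
    upper: int


def spr_distance(
    t1: dendropy.Tree, t2: dendropy.Tree, exact_leaf_limit: int = 8
) -> SprResult:
    """Unrooted SPR distance between two binary trees on the same taxa.

    Exact (BFS over the SPR graph) up to ``exact_leaf_limit`` leaves;
    otherwise returns the greedy leaf-deletion upper bound as the value with
    ``exact=False`` and certified ``(lower, upper)`` bounds.
    """
    taxa1, taxa2 = tip_labels(t1), tip_labels(t2)
    if taxa1 != taxa2:
        raise ValueError("trees must share an identical taxon set")
    adj1, labels1 = _tree_to_adjacency(t1)
    adj2, labels2 = _tree_to_adjacency(t2)
    start = _adjacency_splits(adj1, labels1)
    goal = _adjacency_splits(adj2, labels2)
    if start == goal:
        return SprResult(0, True, 0, 0)
    upper = _leaf_deletion_upper_bound(
        tree_splits(t1), tree_splits(t2), frozenset(taxa1)
    )
    if upper == 1:
        return SprResult(1, True, 1, 1)
    if len(taxa1) > exact_leaf_limit:
        return SprResult(upper, False, 1, upper)
    # breadth-first search with canonical-topology visited set
    frontier = [adj1]
    visited = {start}
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for adj in frontier:
            for neighbor in _spr_neighbors(adj, labels1):
                key = _adjacency_splits(neighbor, labels1)
                if key in visited:
                    continue
                if key == goal:
                    return SprResult(depth, True, depth, depth)
                visited.add(key)
                nxt.append(neighbor)
        frontier = nxt
    raise RuntimeError("SPR search exhausted without reaching the target topology")


# ---------------------------------------------------------------------------
# Consensus networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightedSplit:
    block: frozenset
    count: int
    trivial: bool


@dataclass
class SplitSystem:
    """Splits retained from a collection of gene trees, with occurrence counts."""

    taxa: frozenset
    n_trees: int
    splits: list[WeightedSplit]

    def blocks(self) -> set:
        return {s.block for s in self.splits}

    def incompatible_pairs(self) -> list[tuple[frozenset, frozenset]]:
        """Pairs of retained splits that cannot coexist on a single tree."""
        out = []
        nontrivial = [s.block for s in self.splits if not s.trivial]
        for i, a in enumerate(nontrivial):
            ca = self.taxa - a
            for b in nontrivial[i + 1 :]:
                cb = self.taxa - b
                if a & b and a & cb and ca & b and ca & cb:
                    out.append((a, b))
        return out

    @property
    def is_compatible(self) -> bool:
        return not self.incompatible_pairs()


def consensus_network_splits(gene_trees, threshold: float) -> SplitSystem:
    """Splits occurring in at least ``threshold`` fraction of the input trees.

    The threshold is inclusive; 0 retains every observed split.  Trivial
    splits (single taxa) occur in every tree and are flagged.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("at least one gene tree is required")
    taxa = tip_labels(gene_trees[0])
    counts: Counter = Counter()
    for tree in gene_trees:
        if tip_labels(tree) != taxa:
            raise ValueError("gene trees must share one taxon set")
        for split in tree_splits(tree, include_trivial=True):
            counts[split] += 1
    n = len(gene_trees)
    retained = [
        WeightedSplit(block=b, count=c, trivial=min(len(b), len(taxa - b)) == 1)
        for b, c in counts.items()
        if c >= threshold * n
    ]
    retained.sort(key=lambda s: (-s.count, sorted(s.block)))
    return SplitSystem(taxa=taxa, n_trees=n, splits=retained)
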