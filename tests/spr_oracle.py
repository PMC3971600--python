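"""Independent SPR-distance oracle used by the tests.

Works entirely on declarative split sets, with no tree surgery:

* every unrooted binary topology on a small taxon set is enumerated by
  recursive leaf insertion, each topology represented by its edge blocks
  (subsets not containing a fixed reference taxon);
* two distinct topologies are SPR-adjacent iff some subtree S (an edge block
  of both trees, possibly a single leaf) can account for the difference: S
  has the same rooted shape (identical clade set relative to its attachment)
  in both trees, and deleting S leaves identical unrooted topologies;
* the SPR distance is a breadth-first search over that adjacency relation.
"""

from __future__ import annotations

from itertools import combinations


def enumerate_topologies(taxa: list[str]) -> dict[frozenset, frozenset]:
    """All unrooted binary topologies on ``taxa`` (3 <= n).

    Returns {nontrivial-split-set key: edge-block set}.  Blocks never contain
    ``taxa[0]`` (the reference taxon).
    """
    z, rest = taxa[0], taxa[1:]
    a, b = rest[0], rest[1]
    start = frozenset(
        {frozenset([a]), frozenset([b]), frozenset([a, b])}
    )
    topologies = [start]
    for x in rest[2:]:
        nxt = []
        for edges in topologies:
            for e in edges:
                new_edges = set()
                for block in edges:
                    new_edges.add(block | {x} if e < block else block)
                new_edges.add(e | {x})
                new_edges.add(frozenset([x]))
                nxt.append(frozenset(new_edges))
        topologies = nxt
    n = len(taxa)
    out = {}
    for edges in topologies:
        key = frozenset(b for b in edges if 2 <= len(b) <= n - 2)
        out[key] = edges
    return out


def _restrict(splits: frozenset, keep: frozenset, reference: str) -> frozenset:
    m = len(keep)
    out = set()
    for block in splits:
        sub = frozenset(block & keep)
        if not (2 <= len(sub) <= m - 2):
            continue
        if reference in sub:
            sub = frozenset(keep - sub)
        out.add(sub)
    return frozenset(out)


def _clades_within(edges: frozenset, s: frozenset, taxa: frozenset) -> frozenset:
    """Rooted shape of subtree S: its proper clades relative to the attachment."""
    out = set()
    for block in edges:
        comp = frozenset(taxa - block)
        if block < s:
            out.add(block)
        elif comp < s:
            out.add(comp)
    return frozenset(out)


def spr_adjacent(
    key1: frozenset, edges1: frozenset, key2: frozenset, edges2: frozenset,
    taxa: frozenset,
) -> bool:
    if key1 == key2:
        return False
    reference = min(taxa)
    candidates = set()
    for block in edges1 | {frozenset([reference])}:
        candidates.add(block)
        candidates.add(frozenset(taxa - block))
    subtrees2 = {b for b in edges2} | {frozenset(taxa - b) for b in edges2}
    subtrees2 |= {frozenset([reference])}
    for s in candidates:
        if not s or len(s) >= len(taxa):
            continue
        if len(s) > 1 and s not in subtrees2:
            continue
        # the pruned subtree rides along rooted at its attachment point
        if _clades_within(edges1, s, taxa) != _clades_within(edges2, s, taxa):
            continue
        comp = frozenset(taxa - s)
        ref_c = min(comp)
        if _restrict(key1, comp, ref_c) != _restrict(key2, comp, ref_c):
            continue
        return True
    return False


def oracle_spr_distance(key1: frozenset, key2: frozenset, taxa: list[str]) -> int:
    """Exact SPR distance by BFS over the full topology space."""
    space = enumerate_topologies(sorted(taxa))
    if key1 not in space or key2 not in space:
        raise ValueError("topology not on the given taxon set")
    if key1 == key2:
        return 0
    taxon_set = frozenset(taxa)
    frontier = [key1]
    seen = {key1}
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for current in frontier:
            for other, other_edges in space.items():
                if other in seen:
                    continue
                if spr_adjacent(current, space[current], other, other_edges, taxon_set):
                    if other == key2:
                        return depth
                    seen.add(other)
                    nxt.append(other)
        frontier = nxt
    raise RuntimeError("disconnected SPR graph (impossible)")


def splits_key(tree, taxa: list[str]) -> frozenset:
    """Canonical oracle key (reference-taxon-free nontrivial blocks)."""
    from phylopan.phylo import tree_splits

    reference = sorted(taxa)[0]
    taxon_set = frozenset(taxa)
    out = set()
    for block in tree_splits(tree):
        if reference in block:
            block = frozenset(taxon_set - block)
        out.add(block)
    return frozenset(out)
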