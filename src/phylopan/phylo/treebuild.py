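"""Distance-based tree building: neighbor joining and split-support bootstrap."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment, DistanceResult, jc69_distance_matrix
from .treedist import _canonical, read_tree, tree_splits


def neighbor_joining(dist) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Accepts a pandas DataFrame or a ``DistanceResult``.  Taxa are sorted
    lexicographically before agglomeration so the result is invariant to the
    input row order.  Additive matrices are recovered exactly (up to the
    unrooted topology and branch lengths).
    """
    if isinstance(dist, DistanceResult):
        dist = dist.matrix
    if not isinstance(dist, pd.DataFrame):
        raise ValueError("expected a DataFrame or DistanceResult")
    if len(dist) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dist.index)
    values = dist.loc[order, order].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("distances must be finite")
    sk_tree = _skbio_nj(SkbioDistanceMatrix(values, order))
    # NJ can yield tiny negative lengths on noisy input; clamp to zero
    for node in sk_tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return read_tree(str(sk_tree))


@dataclass
class BootstrapResult:
    """NJ tree on the full alignment with per-split bootstrap support."""

    tree: dendropy.Tree
    supports: dict  # canonical split -> support fraction
    n_reps: int


def bootstrap_trees(
    aln: Alignment, n_reps: int = 100, seed: int = 0
) -> BootstrapResult:
    """Site-resampling bootstrap of the NJ tree.

    Columns are resampled with replacement ``n_reps`` times; support for each
    split of the full-alignment NJ tree is the fraction of replicate trees
    containing it.  Supports are written into the internal node labels of the
    returned tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    main = neighbor_joining(jc69_distance_matrix(aln))
    counts: Counter = Counter()
    n = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n, size=n)
        seqs = ["".join(s[j] for j in cols) for s in aln.seqs]
        rep = Alignment(ids=list(aln.ids), seqs=seqs)
        rep_tree = neighbor_joining(jc69_distance_matrix(rep))
        for split in tree_splits(rep_tree):
            counts[split] += 1
    supports = {s: counts.get(s, 0) / n_reps for s in tree_splits(main)}
    taxa = frozenset(l.taxon.label for l in main.leaf_node_iter())
    for node in main.postorder_internal_node_iter():
        if node is main.seed_node:
            continue
        block = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(block) <= len(taxa) - 2:
            node.label = f"{supports[_canonical(block, taxa)]:.2f}"
    return BootstrapResult(tree=main, supports=supports, n_reps=n_reps)


def select_representative_16s(seqs_per_genome) -> dict:
    """One marker-gene copy per genome: the longest, ties broken by smallest id.

    ``seqs_per_genome`` maps genome id -> {sequence id: sequence}; returns
    genome id -> (sequence id, sequence).
    """
    out = {}
    for genome, seqs in seqs_per_genome.items():
        if not seqs:
            raise ValueError(f"no sequences for genome {genome!r}")
        best_id = min(seqs, key=lambda sid: (-len(seqs[sid]), sid))
        out[genome] = (best_id, seqs[best_id])
    return out
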