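"""Per-site log-likelihoods under a symmetric k-state substitution model.

Felsenstein's pruning algorithm with the Jukes-Cantor model generalized to k
states (k = 4 for nucleotides, 20 for proteins): along a branch of length t
(expected substitutions per site),

    P(stay)   = 1/k + (k-1)/k * exp(-k t / (k-1))
    P(switch) = 1/k - 1/k     * exp(-k t / (k-1))    (per target state)

with uniform equilibrium frequencies 1/k at the root.  Gaps and unknown
symbols are treated as missing data.  The total likelihood is invariant to
the rooting, so unrooted trees can be evaluated from any internal node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import GAP_CHARS, Alignment


def jc_transition_matrix(t: float, k: int) -> np.ndarray:
    if t < 0:
        raise ValueError("branch length must be non-negative")
    decay = np.exp(-k * t / (k - 1))
    same = 1.0 / k + (k - 1) / k * decay
    diff = 1.0 / k - 1.0 / k * decay
    out = np.full((k, k), diff)
    np.fill_diagonal(out, same)
    return out


def felsenstein_per_site_loglik(
    tree: dendropy.Tree, aln: Alignment, alphabet: str | None = None
) -> np.ndarray:
    """Vector of per-site log-likelihoods of the alignment on the tree."""
    if alphabet is None:
        alphabet = "ACGT" if aln.is_nucleotide() else "ACDEFGHIKLMNPQRSTVWY"
    k = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(aln.ids):
        raise ValueError("tree tips and alignment rows must match")
    n_sites = aln.n_sites

    def tip_partial(seq: str) -> np.ndarray:
        partial = np.zeros((n_sites, k))
        for j, c in enumerate(seq):
            if c in index:
                partial[j, index[c]] = 1.0
            else:  # gap or ambiguity: missing data
                partial[j, :] = 1.0
        return partial

    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = tip_partial(aln.row(node.taxon.label))
            continue
        acc = np.ones((n_sites, k))
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise ValueError("every branch needs a length")
            p = jc_transition_matrix(t, k)
            acc *= partials.pop(id(child)) @ p.T
        partials[id(node)] = acc
    root = partials[id(tree.seed_node)]
    site_lik = root.mean(axis=1)  # uniform root frequencies 1/k
    if (site_lik <= 0).any():
        raise ValueError("zero site likelihood (conflicting data?)")
    return np.log(site_lik)


@dataclass
class PerSiteScoreMatrix:
    """Candidate topologies x sites matrix of per-site log-likelihoods."""

    topology_ids: list[str]
    scores: np.ndarray  # shape (n_topologies, n_sites)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if len(self.topology_ids) != self.scores.shape[0]:
            raise ValueError("one row of scores per topology")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @property
    def n_sites(self) -> int:
        return self.scores.shape[1]

    def totals(self) -> dict[str, float]:
        return dict(zip(self.topology_ids, self.scores.sum(axis=1)))

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.scores.T,
            columns=self.topology_ids,
        )
        frame.index.name = "site"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PerSiteScoreMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="site")
        return cls(topology_ids=list(frame.columns), scores=frame.to_numpy().T)


def per_site_scores_for_topologies(
    trees, aln: Alignment, topology_ids=None
) -> PerSiteScoreMatrix:
    """Evaluate one alignment under several candidate topologies."""
    trees = list(trees)
    ids = list(topology_ids) if topology_ids else [f"T{i}" for i in range(len(trees))]
    rows = [felsenstein_per_site_loglik(t, aln) for t in trees]
    return PerSiteScoreMatrix(topology_ids=ids, scores=np.vstack(rows))
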