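"""Pangenome presence/absence analysis.

The central object is the genomes x gene-clusters copy-count matrix.  On top
of it this module provides

* the normalized Hamming gene-content distance
  ``d(x, y) = (A + B - 2S) / (A + B)`` where ``A`` and ``B`` are the two
  genomes' total gene counts and ``S`` sums, per cluster, the smaller of the
  two copy counts (so in-paralogs are only credited up to the partner's copy
  number);
* hierarchical clustering of genomes on that distance;
* group-specific marker detection: a cluster is specific to group A versus
  group B if it is present (copy count >= 1) in at least ``presence_frac`` of
  A and absent from at least ``absence_frac`` of B (both thresholds
  inclusive, evaluated with exact rational arithmetic).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .homolog import GeneCluster


def presence_matrix(
    clusters: Iterable[GeneCluster], genomes: Sequence[str]
) -> pd.DataFrame:
    """Genomes x clusters copy-count matrix (rows ordered as ``genomes``)."""
    genomes = list(genomes)
    known = set(genomes)
    clusters = list(clusters)
    data = np.zeros((len(genomes), len(clusters)), dtype=int)
    index = {g: i for i, g in enumerate(genomes)}
    for j, cluster in enumerate(clusters):
        for genome_id, count in cluster.copy_counts().items():
            if genome_id not in known:
                raise ValueError(
                    f"cluster {cluster.cluster_id} references unknown genome {genome_id!r}"
                )
            data[index[genome_id], j] = count
    return pd.DataFrame(data, index=genomes, columns=[c.cluster_id for c in clusters])


def normalized_hamming(x, y) -> float:
    """Normalized Hamming gene-content distance between two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("copy counts must be non-negative")
    a = x.sum()
    b = y.sum()
    if a + b == 0:
        raise ValueError("distance undefined: both genomes are empty")
    s = np.minimum(x, y).sum()
    return float((a + b - 2.0 * s) / (a + b))


def distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs normalized Hamming distances over a presence matrix."""
    values = matrix.to_numpy(dtype=float)
    n = len(matrix)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = normalized_hamming(values[i], values[j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Agglomerative clustering of genomes with a recorded leaf order."""

    linkage: np.ndarray
    labels: list[str]
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_groups: int) -> dict[str, int]:
        """Flat grouping with ``n_groups`` clusters (maxclust criterion)."""
        assignment = hierarchy.fcluster(self.linkage, n_groups, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = render(node.get_left())
            right = render(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return render(root) + ";"


def cluster_genomes(dist: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Hierarchically cluster genomes from a symmetric distance matrix.

    The default linkage is complete, matching the default of the R heatmap
    machinery classically used to display gene-content distances.
    """
    values = dist.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(values, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage=z, labels=list(dist.index), method=linkage)


@dataclass(frozen=True)
class GroupSpec:
    """Two disjoint genome groups and the presence/absence thresholds."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    presence_frac: float = 0.9
    absence_frac: float = 0.9
    # optional integer-count overrides (an alternative reading of the 90/90
    # rule counts genomes instead of fractions)
    min_present_count: int | None = None
    min_absent_count: int | None = None

    def __post_init__(self):
        if not self.group_a or not self.group_b:
            raise ValueError("groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")


def _meets(count: int, size: int, frac: float, min_count: int | None) -> bool:
    if min_count is not None:
        return count >= min_count
    f = Fraction(str(frac))
    return count * f.denominator >= f.numerator * size


def group_specific_clusters(
    matrix: pd.DataFrame, spec: GroupSpec
) -> tuple[list[str], list[str]]:
    """Clusters specific to group A (first list) and to group B (second).

    Presence means copy count >= 1.  Thresholds are inclusive and compared as
    exact rationals so that e.g. 9 of 10 genomes meets a 0.9 cutoff without
    floating-point surprises.
    """
    for g in (*spec.group_a, *spec.group_b):
        if g not in matrix.index:
            raise ValueError(f"genome {g!r} not in matrix")
    present = matrix.to_numpy() > 0
    idx = {g: i for i, g in enumerate(matrix.index)}
    rows_a = [idx[g] for g in spec.group_a]
    rows_b = [idx[g] for g in spec.group_b]
    na, nb = len(rows_a), len(rows_b)
    pres_a = present[rows_a].sum(axis=0)
    pres_b = present[rows_b].sum(axis=0)

    a_specific, b_specific = [], []
    for j, cluster_id in enumerate(matrix.columns):
        if _meets(int(pres_a[j]), na, spec.presence_frac, spec.min_present_count) and _meets(
            nb - int(pres_b[j]), nb, spec.absence_frac, spec.min_absent_count
        ):
            a_specific.append(cluster_id)
        if _meets(int(pres_b[j]), nb, spec.presence_frac, spec.min_present_count) and _meets(
            na - int(pres_a[j]), na, spec.absence_frac, spec.min_absent_count
        ):
            b_specific.append(cluster_id)
    return a_specific, b_specific


def core_clusters(matrix: pd.DataFrame) -> list[str]:
    """Clusters present (count >= 1) in every genome — the shared core."""
    present = matrix.to_numpy() > 0
    mask = present.all(axis=0)
    return [c for c, m in zip(matrix.columns, mask) if m]


def single_copy_core(matrix: pd.DataFrame) -> list[str]:
    """Core clusters present in exactly one copy in every genome."""
    values = matrix.to_numpy()
    mask = (values == 1).all(axis=0)
    return [c for c, m in zip(matrix.columns, mask) if m]


@dataclass(frozen=True)
class GenomeSizeSummary:
    mean: float
    min: int
    max: int
    n: int


def mean_genome_size(
    matrix: pd.DataFrame, subset: Sequence[str] | None = None
) -> GenomeSizeSummary:
    """Mean / min / max gene count (matrix row sums) over a genome subset."""
    if subset is None:
        subset = list(matrix.index)
    subset = list(subset)
    if not subset:
        raise ValueError("genome subset must be non-empty")
    missing = [g for g in subset if g not in matrix.index]
    if missing:
        raise ValueError(f"unknown genomes: {missing}")
    sums = matrix.loc[subset].sum(axis=1)
    return GenomeSizeSummary(
        mean=float(sums.mean()), min=int(sums.min()), max=int(sums.max()), n=len(subset)
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome")
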