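"""Single-linkage homolog clustering of protein sequences.

Genes are grouped into homologous families by building a graph with an edge
between two genes whenever their global alignment passes both a minimum
identity and a minimum mutual-coverage threshold (defaults 40% identity, 70%
of the length of both sequences), then taking connected components.  This is
the classic greedy pangenome clustering used to build presence/absence
matrices from draft genomes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .pairwise import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, align_pair

DEFAULT_MIN_IDENTITY = 0.40
DEFAULT_MIN_COVERAGE = 0.70


@dataclass
class GeneCluster:
    """One homologous gene family: members as (genome_id, gene_id) pairs."""

    cluster_id: str
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return [g for _, g in self.members]

    def copy_counts(self) -> dict[str, int]:
        """Per-genome copy count of this family."""
        counts: dict[str, int] = {}
        for genome_id, _ in self.members:
            counts[genome_id] = counts.get(genome_id, 0) + 1
        return counts


GeneRecords = Mapping[str, tuple[str, str]]  # gene_id -> (genome_id, protein)


def _as_gene_records(genes) -> dict[str, tuple[str, str]]:
    """Normalize input to ``{gene_id: (genome_id, protein)}``.

    Accepts that mapping directly, a ``{genome_id: {gene_id: protein}}``
    mapping, or an iterable of objects with ``genome_id`` and ``genes``
    attributes (synthetic genomes).
    """
    if isinstance(genes, Mapping):
        first = next(iter(genes.values()), None)
        if first is None:
            return {}
        if isinstance(first, tuple):
            return dict(genes)
        records: dict[str, tuple[str, str]] = {}
        for genome_id, gene_map in genes.items():
            for gene_id, seq in gene_map.items():
                if gene_id in records:
                    raise ValueError(f"duplicate gene id {gene_id!r}")
                records[gene_id] = (genome_id, seq)
        return records
    records = {}
    for genome in genes:
        for gene_id, gene in genome.genes.items():
            if gene_id in records:
                raise ValueError(f"duplicate gene id {gene_id!r}")
            seq = gene.protein if hasattr(gene, "protein") else gene
            records[gene_id] = (genome.genome_id, seq)
    return records


def qualifying_pairs(
    records: GeneRecords,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Iterable[tuple[str, str]]:
    """Yield gene-id pairs whose alignment passes both thresholds.

    A pair qualifies iff identity >= min_identity and the *smaller* of the two
    coverages >= min_coverage (the length criterion is applied to both
    sequences).  A cheap length-ratio bound skips alignments that cannot
    reach the coverage threshold: aligned columns never exceed min(len), so
    min-coverage <= min(len)/max(len).
    """
    ids = sorted(records)
    for i, a in enumerate(ids):
        genome_a, seq_a = records[a]
        for b in ids[i + 1 :]:
            genome_b, seq_b = records[b]
            la, lb = len(seq_a), len(seq_b)
            if min(la, lb) / max(la, lb) < min_coverage:
                continue
            m = align_pair(seq_a, seq_b, gap_open, gap_extend, id_a=a, id_b=b)
            if m.identity >= min_identity and min(m.coverage_a, m.coverage_b) >= min_coverage:
                yield a, b


def build_clusters(
    genes,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[GeneCluster]:
    """Cluster genes into families by single linkage over qualifying pairs.

    Clusters are connected components of the qualifying-pair graph, so two
    members of a cluster need not match each other directly (transitivity).
    Cluster ids are derived from the lexicographically smallest member gene id
    and clusters are returned in that order.
    """
    records = _as_gene_records(genes)
    graph = nx.Graph()
    graph.add_nodes_from(records)
    graph.add_edges_from(
        qualifying_pairs(records, min_identity, min_coverage, gap_open, gap_extend)
    )
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        cluster = GeneCluster(
            cluster_id=f"cl__{members[0]}",
            members=[(records[g][0], g) for g in members],
        )
        clusters.append(cluster)
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def clusters_to_frame(clusters: Iterable[GeneCluster]) -> pd.DataFrame:
    rows = [
        {"cluster_id": c.cluster_id, "genome_id": genome, "gene_id": gene}
        for c in clusters
        for genome, gene in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "genome_id", "gene_id"])


def write_cluster_table(clusters: Iterable[GeneCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def read_cluster_table(path: str | Path) -> list[GeneCluster]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, GeneCluster] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.cluster_id, GeneCluster(row.cluster_id)).members.append(
            (row.genome_id, row.gene_id)
        )
    return [out[k] for k in sorted(out)]
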