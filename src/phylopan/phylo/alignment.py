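"""Multiple sequence alignment container, entropy trimming, JC distances."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GAP_CHARS = set("-.")
NT_CHARS = set("ACGTUN")


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment (nucleotide or protein)."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        self.seqs = [s.upper() for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def row(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def is_nucleotide(self) -> bool:
        observed = set("".join(self.seqs)) - GAP_CHARS
        return bool(observed) and observed <= NT_CHARS

    @property
    def alphabet_size(self) -> int:
        return 4 if self.is_nucleotide() else 20

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    def subset(self, keep_ids) -> "Alignment":
        keep = [i for i in self.ids if i in set(keep_ids)]
        return Alignment(ids=keep, seqs=[self.row(i) for i in keep])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])

    @classmethod
    def from_phylip(cls, path: str | Path) -> "Alignment":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "phylip-relaxed")
        return cls(ids=[r.id for r in aln], seqs=[str(r.seq) for r in aln])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class TrimResult:
    alignment: Alignment
    column_map: list[int]  # retained column -> original column index
    empty: bool = False


def column_entropies(aln: Alignment) -> np.ndarray:
    """Per-column Shannon entropy over non-gap symbols, normalized to [0, 1].

    Normalization divides by log2 of the alphabet size (4 for nucleotide,
    20 for protein), so a uniform column scores 1 and an invariant column 0.
    All-gap columns are assigned entropy 0.
    """
    arr = aln.to_array()
    k = aln.alphabet_size
    out = np.zeros(aln.n_sites)
    for j in range(aln.n_sites):
        col = [c for c in arr[:, j] if c not in GAP_CHARS]
        if not col:
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log2(p)).sum()
        out[j] = h / np.log2(k)
    return out


def gap_fractions(aln: Alignment) -> np.ndarray:
    arr = aln.to_array()
    return np.mean(np.isin(arr, list(GAP_CHARS)), axis=0)


def trim_alignment(
    aln: Alignment, entropy_max: float = 0.7, gap_max: float = 1.0
) -> TrimResult:
    """Drop columns with normalized entropy > entropy_max or gap fraction > gap_max."""
    if aln.n_sites == 0:
        raise ValueError("empty alignment")
    entropy = column_entropies(aln)
    gaps = gap_fractions(aln)
    keep = [j for j in range(aln.n_sites) if entropy[j] <= entropy_max and gaps[j] <= gap_max]
    if not keep:
        warnings.warn("trimming removed every column", stacklevel=2)
        return TrimResult(
            alignment=Alignment(ids=list(aln.ids), seqs=["" for _ in aln.ids]),
            column_map=[],
            empty=True,
        )
    seqs = ["".join(s[j] for j in keep) for s in aln.seqs]
    return TrimResult(alignment=Alignment(ids=list(aln.ids), seqs=seqs), column_map=keep)


def jc_correct(p: float, k: int = 4) -> float:
    """Jukes-Cantor distance from a proportion of differing sites (k states)."""
    ratio = (k - 1) / k
    return -ratio * np.log(1.0 - p / ratio)


@dataclass
class DistanceResult:
    matrix: pd.DataFrame
    saturated: set[tuple[str, str]] = field(default_factory=set)
    missing: set[tuple[str, str]] = field(default_factory=set)


def jc69_distance_matrix(
    aln: Alignment, alphabet_size: int | None = None, max_distance: float = 5.0
) -> DistanceResult:
    """Pairwise JC distances over shared non-gap sites.

    ``p >= (k-1)/k`` saturates the correction; such pairs are capped at
    ``max_distance`` and flagged, as are pairs with no overlapping sites.
    """
    k = alphabet_size or aln.alphabet_size
    ratio = (k - 1) / k
    arr = aln.to_array()
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(aln)
    out = np.zeros((n, n))
    saturated, missing = set(), set()
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~is_gap[i] & ~is_gap[j]
            total = int(shared.sum())
            pair = (aln.ids[i], aln.ids[j])
            if total == 0:
                missing.add(pair)
                out[i, j] = out[j, i] = max_distance
                continue
            p = float((arr[i, shared] != arr[j, shared]).mean())
            if p >= ratio:
                saturated.add(pair)
                d = max_distance
            else:
                d = min(jc_correct(p, k), max_distance)
            out[i, j] = out[j, i] = d
    return DistanceResult(
        matrix=pd.DataFrame(out, index=aln.ids, columns=aln.ids),
        saturated=saturated,
        missing=missing,
    )
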