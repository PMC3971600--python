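"""Pairwise protein alignment scoring shared by clustering and homology screening.

Two scoring modes are used in the pipeline:

* end-gap-free global alignment (homolog clustering) — every residue of both
  sequences is either aligned or in a terminal gap, so identity and mutual
  coverage can be read off one alignment;
* Smith-Waterman local alignment (trait/read screening) — the natural score
  for Karlin-Altschul style e-values.

Both use BLOSUM62 with affine gaps (default open -11, extend -1).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PairwiseMatch:
    """Identity/coverage summary of one end-gap-free global alignment.

    ``identity`` is identical residue pairs divided by aligned (residue-residue)
    columns; gap columns are excluded from the denominator.  ``coverage_x`` is
    the number of residues of ``x`` aligned against a residue of the partner,
    divided by ``len(x)`` — terminal and internal gaps both reduce it.
    """

    seq_a: str
    seq_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    score: float


@lru_cache(maxsize=8)
def _global_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # end gaps are free: global in extent, local in penalty
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


@lru_cache(maxsize=8)
def _local_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    return seq


def align_pair(
    seq_a: str,
    seq_b: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseMatch:
    """Globally align two protein sequences and report identity and coverage."""
    sa = _check_protein(seq_a, "seq_a")
    sb = _check_protein(seq_b, "seq_b")
    aligner = _global_aligner(gap_open, gap_extend)
    alignment = aligner.align(sa, sb)[0]
    counts = alignment.counts()
    aligned = counts.aligned  # residue-residue columns
    identity = counts.identities / aligned if aligned else 0.0
    return PairwiseMatch(
        seq_a=id_a,
        seq_b=id_b,
        identity=identity,
        coverage_a=aligned / len(sa),
        coverage_b=aligned / len(sb),
        score=float(alignment.score),
    )


def local_score(
    query: str,
    subject: str,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, float]:
    """Smith-Waterman score and identity of the best local alignment.

    Returns ``(score, identity)`` where identity is over the local alignment's
    residue-pair columns (0.0 when the best local score is not positive).
    """
    q = _check_protein(query, "query")
    s = _check_protein(subject, "subject")
    aligner = _local_aligner(gap_open, gap_extend)
    alignments = aligner.align(q, s)
    try:
        best = alignments[0]
    except IndexError:  # no positive-scoring local alignment
        return 0.0, 0.0
    counts = best.counts()
    identity = counts.identities / counts.aligned if counts.aligned else 0.0
    return float(best.score), identity
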