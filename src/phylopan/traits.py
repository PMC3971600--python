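"""Threshold homology screening for named trait genes.

Proteomes are searched against small curated reference databases (butyrate
kinase, butyryl-CoA:acetate CoA-transferase, sporulation gene families) with
a Smith-Waterman score converted to an e-value by a Karlin-Altschul style
formula, E = K * m * n * exp(-lambda * S), where m is the query length and n
the total residue count of the database.  Default (lambda, K) are the
published gapped-BLOSUM62 constants for open/extend 11/1; a per-database
Gumbel calibration on shuffled-sequence score maxima can replace them and is
stored with the database so results stay reproducible.

Screens differ by trait: butyrate-gene screening uses an e-value cutoff of
1e-30 plus a 70% identity floor; sporulation screening uses the e-value
cutoff alone.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import gumbel_r

from .pairwise import local_score

# gapped BLOSUM62 Karlin-Altschul parameters (open 11 / extend 1)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

BUTYRATE_EVALUE_MAX = 1e-30
BUTYRATE_IDENTITY_MIN = 0.70
SPORULATION_EVALUE_MAX = 1e-30

_EVALUE_FLOOR = 1e-300


@dataclass
class ReferenceDB:
    """A labeled reference protein set for one trait."""

    trait: str
    sequences: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("reference database must be non-empty")

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def evalue(self, score: float, query_length: int) -> float:
        """Karlin-Altschul e-value with database-size correction."""
        log_e = (
            math.log(self.karlin_k)
            + math.log(query_length)
            + math.log(self.total_residues)
            - self.karlin_lambda * score
        )
        if log_e < math.log(_EVALUE_FLOOR):
            return _EVALUE_FLOOR
        return math.exp(log_e)

    def calibrate(self, seed: int = 0, n_queries: int = 50, query_length: int | None = None) -> None:
        """Refit (lambda, K) from shuffled-sequence maximum-score statistics.

        Random shuffles of the database's own sequences are searched against
        the database; the per-query maximum local scores are fit to a Gumbel
        distribution whose exponential tail gives lambda = 1/beta and
        K = exp(mu/beta) / (m * n).
        """
        rng = np.random.default_rng(seed)
        pool = sorted(self.sequences.values(), key=len)
        maxima = []
        lengths = []
        for i in range(n_queries):
            template = pool[i % len(pool)]
            letters = list(template)
            rng.shuffle(letters)
            query = "".join(letters)
            if query_length:
                query = (query * (query_length // len(query) + 1))[:query_length]
            best = max(local_score(query, s)[0] for s in self.sequences.values())
            maxima.append(best)
            lengths.append(len(query))
        mu, beta = gumbel_r.fit(maxima)
        self.karlin_lambda = 1.0 / beta
        self.karlin_k = math.exp(mu / beta) / (
            float(np.mean(lengths)) * self.total_residues
        )

    @classmethod
    def from_fasta(cls, trait: str, fasta: str | Path, labels_tsv: str | Path | None = None):
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        labels = {}
        if labels_tsv is not None:
            frame = pd.read_csv(labels_tsv, sep="\t", dtype=str)
            labels = dict(zip(frame.iloc[:, 0], frame.iloc[:, -1]))
        return cls(trait=trait, sequences=sequences, labels=labels)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    evalue: float


def search(
    queries: Mapping[str, str],
    db: ReferenceDB,
    evalue_max: float = BUTYRATE_EVALUE_MAX,
    identity_min: float | None = BUTYRATE_IDENTITY_MIN,
) -> list[SearchHit]:
    """All query/subject hits passing the e-value (and optional identity) cutoffs.

    Hits are sorted by ascending e-value, then descending score, then ids.
    An empty proteome yields an empty result.
    """
    hits = []
    for query_id in sorted(queries):
        qseq = queries[query_id]
        for subject_id in sorted(db.sequences):
            score, identity = local_score(qseq, db.sequences[subject_id])
            if score <= 0:
                continue
            evalue = db.evalue(score, len(qseq))
            if evalue > evalue_max:
                continue
            if identity_min is not None and identity < identity_min:
                continue
            hits.append(SearchHit(query_id, subject_id, score, identity, evalue))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.query_id, h.subject_id))
    return hits


@dataclass
class TraitMatrix:
    """Genomes x trait genes boolean presence with per-cell best-hit provenance."""

    table: pd.DataFrame  # bool
    provenance: dict[tuple[str, str], SearchHit] = field(default_factory=dict)

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def traits(self) -> list[str]:
        return list(self.table.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.table.astype(int).to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="genome")
        return cls(table=frame.astype(int).astype(bool))


def load_table1_fixture() -> TraitMatrix:
    """Packaged butyrate-pathway presence/absence table for the 30 genomes."""
    ref = resources.files("phylopan") / "data" / "table1_butyrate.tsv"
    with resources.as_file(ref) as path:
        return TraitMatrix.from_tsv(path)


def trait_table(
    genomes: Mapping[str, Mapping[str, str]],
    dbs: Mapping[str, ReferenceDB],
    thresholds: Mapping[str, tuple[float, float | None]] | None = None,
) -> TraitMatrix:
    """Screen each proteome against each trait database.

    ``genomes`` maps genome id to proteome (or is an iterable of
    ``(genome_id, proteome)`` pairs).  ``thresholds`` maps a trait name to
    ``(evalue_max, identity_min)``; identity_min may be None to disable the
    identity floor (the sporulation screen).  A cell is true iff at least one
    hit passes; the best hit is recorded as provenance.
    """
    pairs = list(genomes.items()) if isinstance(genomes, Mapping) else list(genomes)
    genome_ids = [g for g, _ in pairs]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids")
    traits = list(dbs)
    data = pd.DataFrame(False, index=genome_ids, columns=traits)
    provenance: dict[tuple[str, str], SearchHit] = {}
    for genome_id, proteome in pairs:
        for trait, db in dbs.items():
            evalue_max, identity_min = (
                thresholds[trait]
                if thresholds and trait in thresholds
                else (BUTYRATE_EVALUE_MAX, BUTYRATE_IDENTITY_MIN)
            )
            hits = search(proteome, db, evalue_max, identity_min)
            if hits:
                data.loc[genome_id, trait] = True
                provenance[(genome_id, trait)] = hits[0]
    return TraitMatrix(table=data, provenance=provenance)


@dataclass(frozen=True)
class TraitCounts:
    per_trait: dict[str, int]
    any_of_group: dict[str, int]
    all_of_group: dict[str, int]


def trait_counts(
    matrix: TraitMatrix, groups: Mapping[str, Sequence[str]] | None = None
) -> TraitCounts:
    """Positive-genome counts per trait and per named trait group."""
    table = matrix.table
    per_trait = {t: int(table[t].sum()) for t in table.columns}
    any_of, all_of = {}, {}
    for name, members in (groups or {}).items():
        unknown = [t for t in members if t not in table.columns]
        if unknown:
            raise ValueError(f"unknown traits in group {name!r}: {unknown}")
        sub = table[list(members)]
        any_of[name] = int(sub.any(axis=1).sum())
        all_of[name] = int(sub.all(axis=1).sum())
    return TraitCounts(per_trait=per_trait, any_of_group=any_of, all_of_group=all_of)


@dataclass(frozen=True)
class AbsenceProfile:
    no_homolog_anywhere: list[str]
    group_discriminating: list[str]


def sporulation_absence_profile(
    matrix: TraitMatrix,
    reference_genes: Sequence[str],
    majority_group: Sequence[str],
    absent_group: Sequence[str],
) -> AbsenceProfile:
    """Two absence filters over a sporulation-gene presence matrix.

    * genes from the reference list with no homolog in any screened genome;
    * genes present in a strict majority (> half) of ``majority_group`` and
      completely absent (zero positives) from ``absent_group``.
    """
    table = matrix.table
    no_homolog = [
        g for g in reference_genes if g not in table.columns or not table[g].any()
    ]
    discriminating = []
    maj = table.loc[list(majority_group)]
    absent = table.loc[list(absent_group)]
    for gene in table.columns:
        if gene not in reference_genes:
            continue
        if maj[gene].sum() * 2 > len(majority_group) and absent[gene].sum() == 0:
            discriminating.append(gene)
    return AbsenceProfile(no_homolog_anywhere=no_homolog, group_discriminating=discriminating)


def translate_six_frames(nucleotide: str) -> list[str]:
    """All six reading-frame translations (stops rendered as '*')."""
    seq = Seq(nucleotide.upper().replace("U", "T"))
    frames = []
    for strand in (seq, seq.reverse_complement()):
        for offset in range(3):
            sub = strand[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 3:
                frames.append(str(sub.translate()))
    return frames


def search_nucleotide(
    queries: Mapping[str, str],
    db: ReferenceDB,
    evalue_max: float = BUTYRATE_EVALUE_MAX,
    identity_min: float | None = None,
) -> list[SearchHit]:
    """TBlastN-style screen: six-frame translate nucleotide queries, then search."""
    translated = {}
    for query_id, nt in queries.items():
        for i, frame in enumerate(translate_six_frames(nt)):
            translated[f"{query_id}|frame{i}"] = frame
    hits = search(translated, db, evalue_max, identity_min)
    merged = [
        SearchHit(h.query_id.rsplit("|frame", 1)[0], h.subject_id, h.score, h.identity, h.evalue)
        for h in hits
    ]
    best: dict[tuple[str, str], SearchHit] = {}
    for h in merged:
        key = (h.query_id, h.subject_id)
        if key not in best or (h.evalue, -h.score) < (best[key].evalue, -best[key].score):
            best[key] = h
    out = list(best.values())
    out.sort(key=lambda h: (h.evalue, -h.score, h.query_id, h.subject_id))
    return out
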