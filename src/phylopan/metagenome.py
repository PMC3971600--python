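"""Metagenome read screening and habitat comparison.

Reads are translated in six frames and searched against a trait-gene
database alongside a decoy (off-target) database; a read is retained only if
its best hit over both databases is a trait gene passing the e-value cutoff
(competitive decoy filtering — the rule used to drop reads better explained
by non-target genomes).  Per-sample relative abundances of retained reads
are then compared between habitats with two-sided Welch's t-tests and
Bonferroni correction, and per-read taxonomic classifications can be
aggregated into per-habitat abundance summaries.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pairwise import local_score
from .traits import ReferenceDB, translate_six_frames

DEFAULT_READ_EVALUE_MAX = 1e-10
DEFAULT_POSTERIOR_MIN = 0.7


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    target_db: str | None  # "trait" | "decoy" | None
    target_gene: str | None
    evalue: float
    score: float

    @property
    def retained(self) -> bool:
        return self.target_db == "trait"


def _best_hit(frames: Sequence[str], db: ReferenceDB):
    """Best (score, identity, subject) of any frame against any db sequence."""
    best = None
    for frame in frames:
        if not frame:
            continue
        for subject_id in sorted(db.sequences):
            score, identity = local_score(frame, db.sequences[subject_id])
            if score <= 0:
                continue
            key = (-score, subject_id)
            if best is None or key < best[0]:
                best = (key, score, identity, subject_id, len(frame))
    return best


def assign_reads(
    reads: Mapping[str, str],
    trait_db: ReferenceDB,
    decoy_db: ReferenceDB,
    evalue_max: float = DEFAULT_READ_EVALUE_MAX,
) -> list[ReadAssignment]:
    """Competitively assign nucleotide reads to trait genes or decoys.

    Ties in score between databases are broken by lexicographic target gene
    id, so the result is independent of read and database iteration order.
    """
    assignments = []
    for read_id in sorted(reads):
        frames = translate_six_frames(reads[read_id])
        candidates = []
        for db_name, db in (("trait", trait_db), ("decoy", decoy_db)):
            hit = _best_hit(frames, db)
            if hit is None:
                continue
            _, score, identity, subject_id, qlen = hit
            evalue = db.evalue(score, qlen)
            candidates.append((-score, subject_id, db_name, evalue))
        candidates.sort()
        if not candidates or candidates[0][3] > evalue_max:
            assignments.append(ReadAssignment(read_id, None, None, float("inf"), 0.0))
            continue
        neg_score, subject_id, db_name, evalue = candidates[0]
        assignments.append(
            ReadAssignment(read_id, db_name, subject_id, evalue, -neg_score)
        )
    return assignments


@dataclass
class SampleTraitCounts:
    """Retained trait-read counts and relative abundance for one sample."""

    sample_id: str
    habitat: str
    gene_counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0

    @property
    def retained_reads(self) -> int:
        return sum(self.gene_counts.values())

    @property
    def relative_abundance(self) -> float:
        if self.total_reads == 0:
            raise ValueError("sample has no reads")
        return self.retained_reads / self.total_reads


def count_sample(
    assignments: Sequence[ReadAssignment],
    sample_id: str,
    habitat: str,
    total_reads: int | None = None,
) -> SampleTraitCounts:
    """Summarize retained assignments into per-gene counts for one sample."""
    counts: dict[str, int] = {}
    for a in assignments:
        if a.retained:
            counts[a.target_gene] = counts.get(a.target_gene, 0) + 1
    return SampleTraitCounts(
        sample_id=sample_id,
        habitat=habitat,
        gene_counts=counts,
        total_reads=total_reads if total_reads is not None else len(assignments),
    )


@dataclass(frozen=True)
class HabitatComparison:
    habitat_a: str
    habitat_b: str
    t_statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    mean_difference: float
    evaluable: bool = True


def compare_habitats(
    samples: Sequence[SampleTraitCounts],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[HabitatComparison]:
    """Welch's t-test on per-sample relative abundances for each habitat pair.

    Two-sided p-values, Welch-Satterthwaite degrees of freedom, and
    Bonferroni adjustment over the number of pairs tested.  Pairs where a
    habitat has fewer than two samples are reported as not evaluable.
    """
    by_habitat: dict[str, list[float]] = {}
    for s in samples:
        by_habitat.setdefault(s.habitat, []).append(s.relative_abundance)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(by_habitat), 2))
    out = []
    n_tests = len(pairs)
    for ha, hb in pairs:
        a = np.asarray(by_habitat.get(ha, ()), dtype=float)
        b = np.asarray(by_habitat.get(hb, ()), dtype=float)
        if len(a) < 2 or len(b) < 2:
            out.append(
                HabitatComparison(ha, hb, float("nan"), float("nan"), float("nan"),
                                  float("nan"), float("nan"), evaluable=False)
            )
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        p_raw = float(res.pvalue)
        out.append(
            HabitatComparison(
                habitat_a=ha,
                habitat_b=hb,
                t_statistic=float(res.statistic),
                df=float(res.df),
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * n_tests),
                mean_difference=float(a.mean() - b.mean()),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[HabitatComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "habitat_a": c.habitat_a,
                "habitat_b": c.habitat_b,
                "t": c.t_statistic,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "mean_difference": c.mean_difference,
                "evaluable": c.evaluable,
            }
            for c in comparisons
        ]
    )


@dataclass
class AbundanceSummary:
    per_sample: pd.DataFrame  # sample_id, habitat, percent (NaN if undefined)
    per_habitat: pd.DataFrame  # q25/median/q75/min/max/mean per habitat
    undefined_samples: list[str] = field(default_factory=list)


def habitat_abundance_summary(
    classifications: pd.DataFrame,
    target_taxon: str,
    posterior_min: float = DEFAULT_POSTERIOR_MIN,
    rank: str | None = None,
) -> AbundanceSummary:
    """Per-sample percent abundance of a taxon among classified reads.

    ``classifications`` needs columns sample_id, habitat, read_id, taxon,
    posterior (and optionally rank, filtered when ``rank`` is given).  A read
    is classified iff its posterior is strictly above ``posterior_min``; the
    percentage denominator is the classified reads of the sample.  Samples
    with zero classified reads are flagged undefined and excluded from the
    per-habitat summary.
    """
    df = classifications.copy()
    required = {"sample_id", "habitat", "read_id", "taxon", "posterior"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if ((df["posterior"] < 0) | (df["posterior"] > 1)).any():
        raise ValueError("posteriors must be in [0, 1]")
    if rank is not None:
        df = df[df["rank"] == rank]
    rows = []
    undefined = []
    for (sample_id, habitat), group in df.groupby(["sample_id", "habitat"], sort=True):
        classified = group[group["posterior"] > posterior_min]
        if classified.empty:
            undefined.append(sample_id)
            rows.append({"sample_id": sample_id, "habitat": habitat, "percent": np.nan})
            continue
        hits = (classified["taxon"] == target_taxon).sum()
        rows.append(
            {
                "sample_id": sample_id,
                "habitat": habitat,
                "percent": 100.0 * hits / len(classified),
            }
        )
    per_sample = pd.DataFrame(rows, columns=["sample_id", "habitat", "percent"])
    defined = per_sample.dropna(subset=["percent"])
    per_habitat = (
        defined.groupby("habitat")["percent"]
        .agg(
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
            min="min",
            max="max",
            mean="mean",
            n_samples="count",
        )
        .reset_index()
    )
    return AbundanceSummary(
        per_sample=per_sample, per_habitat=per_habitat, undefined_samples=undefined
    )
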