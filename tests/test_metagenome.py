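"""Read assignment with decoy competition; Welch comparisons; abundance summaries."""

import numpy as np
import pandas as pd
import pytest

from phylopan import metagenome, traits

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(n, rng):
    return "".join(rng.choice(list(AA), size=n))


def _reverse_translate(protein, rng):
    from phylopan.synth import _CODONS

    return "".join(
        _CODONS[c][int(rng.integers(len(_CODONS[c])))] for c in protein
    )


@pytest.fixture(scope="module")
def screen():
    rng = np.random.default_rng(0)
    trait_prot = _random_protein(200, rng)
    decoy_prot = _random_protein(200, rng)
    trait_db = traits.ReferenceDB("spor", {"sporA": trait_prot})
    decoy_db = traits.ReferenceDB("decoy", {"off_target": decoy_prot})
    trait_nt = _reverse_translate(trait_prot, rng)
    decoy_nt = _reverse_translate(decoy_prot, rng)
    return trait_db, decoy_db, trait_nt, decoy_nt


class TestAssignReads:
    def test_trait_read_is_retained(self, screen):
        trait_db, decoy_db, trait_nt, _ = screen
        reads = {"r1": trait_nt[30:150]}
        (a,) = metagenome.assign_reads(reads, trait_db, decoy_db)
        assert a.retained and a.target_gene == "sporA"

    def test_decoy_read_is_removed(self, screen):
        trait_db, decoy_db, _, decoy_nt = screen
        reads = {"r1": decoy_nt[30:150]}
        (a,) = metagenome.assign_reads(reads, trait_db, decoy_db)
        assert not a.retained and a.target_db == "decoy"

    def test_random_read_matches_nothing(self, screen):
        trait_db, decoy_db, _, _ = screen
        rng = np.random.default_rng(9)
        reads = {"r1": "".join(rng.choice(list("ACGT"), size=120))}
        (a,) = metagenome.assign_reads(reads, trait_db, decoy_db)
        assert a.target_db is None

    def test_score_tie_broken_by_lexicographic_gene_id(self):
        # identical sequence planted in both dbs under different ids
        rng = np.random.default_rng(3)
        prot = _random_protein(150, rng)
        nt = _reverse_translate(prot, rng)
        trait_db = traits.ReferenceDB("spor", {"a_gene": prot})
        decoy_db = traits.ReferenceDB("decoy", {"b_gene": prot})
        (kept,) = metagenome.assign_reads({"r": nt[:120]}, trait_db, decoy_db)
        assert kept.retained  # a_gene < b_gene
        trait_db2 = traits.ReferenceDB("spor", {"b_gene": prot})
        decoy_db2 = traits.ReferenceDB("decoy", {"a_gene": prot})
        (dropped,) = metagenome.assign_reads({"r": nt[:120]}, trait_db2, decoy_db2)
        assert not dropped.retained

    def test_empty_read_set_is_empty_result(self, screen):
        trait_db, decoy_db, _, _ = screen
        assert metagenome.assign_reads({}, trait_db, decoy_db) == []

    def test_count_sample_aggregates_retained_reads(self, screen):
        trait_db, decoy_db, trait_nt, decoy_nt = screen
        reads = {
            "r1": trait_nt[:120],
            "r2": trait_nt[60:180],
            "r3": decoy_nt[:120],
        }
        assignments = metagenome.assign_reads(reads, trait_db, decoy_db)
        sample = metagenome.count_sample(assignments, "s1", "gut")
        assert sample.gene_counts == {"sporA": 2}
        assert sample.relative_abundance == pytest.approx(2 / 3)


def _samples(values_by_habitat):
    out = []
    for habitat, values in values_by_habitat.items():
        for i, v in enumerate(values):
            out.append(
                metagenome.SampleTraitCounts(
                    sample_id=f"{habitat}{i}",
                    habitat=habitat,
                    gene_counts={"g": int(round(v * 1000))},
                    total_reads=1000,
                )
            )
    return out


class TestCompareHabitats:
    def test_identical_groups_are_null(self):
        comps = metagenome.compare_habitats(
            _samples({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        )
        (c,) = comps
        assert c.t_statistic == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    def test_welch_closed_form_example(self):
        # groups {1,2,3,4} and {5,6,7,8} (scaled): mean diff -4, per-group
        # s^2 = 5/3, so t = -4 / sqrt(2 * (5/3) / 4) = -4.3818 with
        # Welch-Satterthwaite df = 6 and two-sided p = 0.004659
        comps = metagenome.compare_habitats(
            _samples({"a": [0.001, 0.002, 0.003, 0.004],
                      "b": [0.005, 0.006, 0.007, 0.008]})
        )
        (c,) = comps
        assert c.t_statistic == pytest.approx(-4.0 / np.sqrt(5.0 / 6.0), abs=1e-9)
        assert c.df == pytest.approx(6.0)
        assert c.p_raw == pytest.approx(0.004659, abs=1e-5)
        assert c.p_adjusted == c.p_raw  # single comparison

    def test_bonferroni_never_decreases_p(self):
        comps = metagenome.compare_habitats(
            _samples({
                "a": [0.01, 0.02, 0.03],
                "b": [0.04, 0.05, 0.06],
                "c": [0.02, 0.03, 0.04],
            })
        )
        assert len(comps) == 3
        for c in comps:
            assert c.p_raw <= c.p_adjusted <= 1.0
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 3))

    def test_sign_symmetry(self):
        samples = _samples({"a": [0.01, 0.02], "b": [0.05, 0.09]})
        (ab,) = metagenome.compare_habitats(samples, pairs=[("a", "b")])
        (ba,) = metagenome.compare_habitats(samples, pairs=[("b", "a")])
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.mean_difference == pytest.approx(-ba.mean_difference)
        assert ab.p_raw == pytest.approx(ba.p_raw)

    def test_underpowered_pair_is_not_evaluable(self):
        comps = metagenome.compare_habitats(
            _samples({"a": [0.1], "b": [0.2, 0.3]})
        )
        (c,) = comps
        assert not c.evaluable and np.isnan(c.p_raw)

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            a = rng.normal(0.05, 0.01, size=8).clip(0, 1)
            b = rng.normal(0.05, 0.01, size=8).clip(0, 1)
            comps = metagenome.compare_habitats(
                _samples({"a": a.tolist(), "b": b.tolist()})
            )
            rejections += comps[0].p_raw < 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_reps)


class TestAbundanceSummary:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "habitat", "read_id", "taxon", "posterior"]
        )

    def test_fraction_of_classified_reads(self):
        rows = []
        for i in range(200):
            taxon = "target_family" if i < 50 else "other"
            rows.append(("s1", "gut", f"r{i}", taxon, 0.9))
        summary = metagenome.habitat_abundance_summary(
            self._frame(rows), "target_family"
        )
        assert summary.per_sample.loc[0, "percent"] == pytest.approx(25.0)

    def test_strictly_sub_threshold_posteriors_leave_sample_undefined(self):
        rows = [("s1", "gut", f"r{i}", "target_family", 0.7) for i in range(10)]
        summary = metagenome.habitat_abundance_summary(
            self._frame(rows), "target_family"
        )
        assert summary.undefined_samples == ["s1"]
        assert np.isnan(summary.per_sample.loc[0, "percent"])

    def test_per_habitat_quartiles(self):
        rows = []
        for s, pct in (("s1", 10), ("s2", 20), ("s3", 30)):
            for i in range(100):
                taxon = "target_family" if i < pct else "other"
                rows.append((s, "gut", f"{s}r{i}", taxon, 0.95))
        summary = metagenome.habitat_abundance_summary(
            self._frame(rows), "target_family"
        )
        row = summary.per_habitat.iloc[0]
        assert (row["min"], row["median"], row["max"]) == (10.0, 20.0, 30.0)
        assert row["mean"] == pytest.approx(20.0)

    def test_bad_posterior_rejected(self):
        frame = self._frame([("s1", "gut", "r1", "x", 1.5)])
        with pytest.raises(ValueError, match="posterior"):
            metagenome.habitat_abundance_summary(frame, "x")
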