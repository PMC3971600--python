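"""Generator behavior: tree shape, event calibration, truth-log replay, reads."""

import numpy as np
import pytest

from phylopan import synth
from phylopan.phylo import read_tree


def _two_taxon_tree(length: float = 2.0) -> synth.SpeciesTree:
    tree = read_tree(f"(A:{length},B:{length});")
    return synth.SpeciesTree(tree=tree, habitat_map={"A": "gut", "B": "gut"})


class TestSpeciesTree:
    def test_two_taxa_is_a_cherry(self):
        st = synth.simulate_species_tree(2, seed=0)
        assert len(st.tip_order) == 2
        lengths = [
            n.edge.length
            for n in st.tree.preorder_node_iter()
            if n is not st.tree.seed_node
        ]
        assert len(lengths) == 2 and all(l > 0 for l in lengths)

    def test_seed_determinism(self):
        a = synth.simulate_species_tree(30, seed=1).newick()
        b = synth.simulate_species_tree(30, seed=1).newick()
        assert a == b
        assert a != synth.simulate_species_tree(30, seed=2).newick()

    def test_internal_node_count_identity(self):
        # a rooted binary tree on n tips always has n - 1 internal nodes
        st = synth.simulate_species_tree(100, birth_rate=1.0, seed=3)
        internal = sum(
            1 for n in st.tree.preorder_node_iter() if not n.is_leaf()
        )
        assert internal == 99

    def test_every_tip_has_a_habitat(self):
        st = synth.simulate_species_tree(13, seed=4)
        assert set(st.habitat_map) == set(st.tip_order)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_species_tree(1)
        with pytest.raises(ValueError):
            synth.simulate_species_tree(5, birth_rate=0.0)


class TestGeneContent:
    def test_no_events_means_root_content_everywhere(self):
        st = synth.simulate_species_tree(6, seed=5)
        genomes, truth = synth.simulate_gene_content(
            st, n_families=20, gain_rate=0.0, loss_rate=0.0, seed=6, paralog_rate=0.0
        )
        for g in genomes:
            assert g.families == truth.root_content

    def test_loss_event_draws_are_poisson_calibrated(self):
        # branch length 2 x loss rate 0.5 -> mean event draws 1.0 per family
        st = _two_taxon_tree(length=2.0)
        draws = []
        for seed in range(5):
            _, truth = synth.simulate_gene_content(
                st, n_families=200, gain_rate=0.0, loss_rate=0.5, seed=seed,
                root_fraction=1.0, paralog_rate=0.0,
            )
            branch = frozenset({"A"})
            for family in truth.root_content:
                events = [
                    e for e in truth.events.get(family, [])
                    if e.kind == "loss" and e.branch == branch
                ]
                draws.append(events[0].draws if events else 0)
        mean = np.mean(draws)
        se = np.sqrt(1.0 / len(draws))  # Poisson(1) has unit variance
        assert abs(mean - 1.0) <= 3 * se

    def test_forced_habitat_loss_removes_families_from_target_tips(self, small_study):
        stree, genomes, truth = small_study
        for g in genomes:
            if g.habitat in ("rumen", "oral"):
                assert not (g.families & truth.habitat_loss_set)

    def test_habitat_loss_families_survive_in_other_habitats(self, small_study):
        stree, genomes, truth = small_study
        gut = [g for g in genomes if g.habitat == "gut"]
        present_somewhere = set().union(*(g.families for g in gut))
        assert truth.habitat_loss_set <= present_somewhere

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_truth_log_replay_reproduces_every_genome(self, seed):
        st = synth.simulate_species_tree(7, seed=seed, habitats=("gut", "oral"),
                                         habitat_weights=(0.7, 0.3))
        genomes, truth = synth.simulate_gene_content(
            st, n_families=40, gain_rate=0.8, loss_rate=0.2,
            lgt=synth.LgtConfig(n_families=4, rate=1.5), seed=seed + 1,
        )
        replayed = truth.replay(st)
        for g in genomes:
            assert replayed[g.genome_id] == g.families

    def test_lgt_events_name_extant_donors(self, small_study):
        stree, genomes, truth = small_study
        clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in stree.tree.preorder_node_iter()
            if n is not stree.tree.seed_node
        }
        n_lgt = 0
        for family in truth.lgt_set:
            for e in truth.events.get(family, []):
                if e.kind == "lgt":
                    n_lgt += 1
                    assert e.donor in clades
        assert n_lgt >= 1

    def test_unknown_habitat_rejected(self):
        st = synth.simulate_species_tree(5, seed=1, habitats=("gut",),
                                         habitat_weights=(1.0,))
        with pytest.raises(ValueError, match="unknown habitat"):
            synth.simulate_gene_content(
                st, n_families=10,
                habitat_loss=synth.HabitatLoss(("moon",), 2.0, 2),
            )


class TestSequences:
    def test_zero_branch_preserves_sequence(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 20, size=500)
        assert (synth._evolve(seq, 0.0, 20, rng) == seq).all()

    def test_divergence_matches_closed_form(self):
        # two tips at total path 0.1 under the symmetric 20-state model
        st = _two_taxon_tree(length=0.05)
        genomes, truth = synth.simulate_gene_content(
            st, n_families=1, gain_rate=0, loss_rate=0, seed=0,
            root_fraction=1.0, paralog_rate=0.0,
        )
        synth.simulate_sequences(genomes, st, truth, site_count=10000, seed=1,
                                 tree_height=None)
        a = next(iter(genomes[0].genes.values())).protein
        b = next(iter(genomes[1].genes.values())).protein
        p = np.mean([x != y for x, y in zip(a, b)])
        k, t = 20, 0.1
        expected = (k - 1) / k * (1 - np.exp(-k * t / (k - 1)))
        se = np.sqrt(expected * (1 - expected) / 10000)
        assert abs(p - expected) <= 3 * se

    def test_cross_family_identity_near_random_baseline(self, small_study):
        _, genomes, _ = small_study
        genome = genomes[0]
        by_family = {}
        for gene in genome.genes.values():
            by_family.setdefault(gene.family_id, gene.protein)
        proteins = list(by_family.values())[:8]
        matches = []
        for i in range(len(proteins)):
            for j in range(i + 1, len(proteins)):
                a, b = proteins[i], proteins[j]
                n = min(len(a), len(b))
                matches.append(np.mean([a[x] == b[x] for x in range(n)]))
        assert abs(np.mean(matches) - 0.05) < 0.03

    def test_nucleotide_back_translates_to_protein(self, small_study):
        _, genomes, _ = small_study
        from Bio.Seq import Seq

        gene = next(iter(genomes[0].genes.values()))
        assert str(Seq(gene.nucleotide).translate()) == gene.protein


class TestMetagenome:
    def test_error_free_reads_are_exact_substrings(self, small_study):
        _, genomes, _ = small_study
        mg = synth.simulate_metagenome(
            genomes, "gut", n_reads=50, read_length=60,
            error_rate=0.0, background_fraction=0.0, seed=0,
        )
        genes = {
            (g.genome_id, gid): gene.nucleotide
            for g in genomes
            for gid, gene in g.genes.items()
        }
        for read in mg.reads:
            assert read.sequence in genes[(read.source_genome, read.source_gene)]

    def test_background_fraction_is_binomial(self, small_study):
        _, genomes, _ = small_study
        mg = synth.simulate_metagenome(
            genomes, "gut", n_reads=1000, read_length=60,
            background_fraction=0.3, seed=1,
        )
        n_bg = sum(1 for r in mg.reads if r.source_gene == "background")
        se = np.sqrt(1000 * 0.3 * 0.7)
        assert abs(n_bg - 300) <= 3 * se

    def test_fastq_bytes_reproducible(self, small_study, tmp_path):
        _, genomes, _ = small_study
        paths = []
        for name in ("a.fastq", "b.fastq"):
            mg = synth.simulate_metagenome(
                genomes, "gut", n_reads=30, read_length=60, seed=9
            )
            path = tmp_path / name
            mg.to_fastq(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_overlong_read_length_rejected(self, small_study):
        _, genomes, _ = small_study
        with pytest.raises(ValueError, match="read_length"):
            synth.simulate_metagenome(genomes, "gut", n_reads=5, read_length=10**6)


def test_write_simulation_outputs(tmp_path, small_study):
    stree, genomes, truth = small_study
    synth.write_simulation(tmp_path, stree, genomes, truth)
    assert (tmp_path / "species_tree.nwk").exists()
    assert (tmp_path / "truth.json").exists()
    assert (tmp_path / f"{genomes[0].genome_id}.faa").exists()
    table = (tmp_path / "genes.tsv").read_text().splitlines()
    assert table[0] == "genome_id\tgene_id\tfamily_id"
    assert len(table) - 1 == sum(len(g.genes) for g in genomes)
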