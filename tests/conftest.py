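import numpy as np
import pytest

from phylopan import synth


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down planted simulation shared by read-only tests.

    8 taxa over three habitats, 30 families including a forced habitat-loss
    set and an LGT set, with sequences.
    """
    stree = synth.simulate_species_tree(
        8, seed=11, habitats=("gut", "rumen", "oral"), habitat_weights=(0.6, 0.2, 0.2)
    )
    genomes, truth = synth.simulate_gene_content(
        stree,
        n_families=30,
        gain_rate=0.3,
        loss_rate=0.02,
        habitat_loss=synth.HabitatLoss(
            habitats=("rumen", "oral"), multiplier=np.inf, n_families=5
        ),
        lgt=synth.LgtConfig(n_families=3, rate=1.0),
        seed=12,
    )
    synth.simulate_sequences(genomes, stree, truth, site_count=(120, 160), seed=13)
    return stree, genomes, truth
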