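import numpy as np
import pytest

from thermolag.synthetic import (
    SimConfig,
    simulate_genomes,
    simulate_gene_content,
    simulate_ogt,
    simulate_tree,
)


@pytest.fixture(scope="session")
def std_sim():
    """One mid-sized synthetic study shared across read-only tests."""
    cfg = SimConfig(n_tips=100, seed=11)
    tree, taxonomy = simulate_tree(cfg)
    history = simulate_ogt(tree, cfg)
    bundles, truth = simulate_genomes(tree, history, cfg)
    matrix, events, gene_info = simulate_gene_content(tree, history, cfg)
    return {
        "config": cfg,
        "tree": tree,
        "taxonomy": taxonomy,
        "history": history,
        "bundles": bundles,
        "truth": truth,
        "gene_matrix": matrix,
        "gene_events": events,
        "gene_info": gene_info,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_yule_tree(n_tips: int, seed: int):
    return simulate_tree(SimConfig(n_tips=n_tips, seed=seed))[0]
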