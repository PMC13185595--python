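"""Tree simulation, taxonomy cuts, and OGT trait histories."""

import numpy as np
import pandas as pd
import pytest

from thermolag.synthetic import (
    InconsistentInputError,
    InvalidConfigError,
    SimConfig,
    lagged_ogt,
    simulate_gene_content,
    simulate_genomes,
    simulate_ogt,
    simulate_ogt_sources,
    simulate_tree,
    true_dogt,
    TraitHistory,
)
from thermolag.tree import Phylogeny


class TestSimulateTree:
    def test_binary_tree_node_count(self):
        tree, _ = simulate_tree(SimConfig(n_tips=8, seed=1))
        assert tree.n_tips == 8
        assert tree.n_nodes == 15  # n tips -> n-1 internal nodes

    def test_seeded_determinism_gives_identical_newick(self):
        cfg = SimConfig(n_tips=25, seed=5)
        assert simulate_tree(cfg)[0].to_newick() == simulate_tree(cfg)[0].to_newick()

    def test_branch_lengths_strictly_positive(self):
        tree, _ = simulate_tree(SimConfig(n_tips=50, seed=3))
        non_root = np.arange(tree.n_nodes) != tree.root
        assert (tree.lengths[non_root] > 0).all()

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_tips=2)

    def test_taxonomy_is_nested_across_ranks(self):
        """Every genus maps into exactly one family, family into one
        order, and so on up to phylum (brute-force grouping check)."""
        _, tax = simulate_tree(SimConfig(n_tips=200, seed=7))
        ranks = ["genus", "family", "order", "class", "phylum"]
        for lower, upper in zip(ranks, ranks[1:]):
            parents = tax.groupby(lower)[upper].nunique()
            assert (parents == 1).all()

    def test_taxonomy_consistent_with_topology(self):
        tree, tax = simulate_tree(SimConfig(n_tips=60, seed=9))
        # every genus is monophyletic: its MRCA subtends exactly its members
        for genus, grp in tax.groupby("genus"):
            tips = [tree.tip_index[s] for s in grp["species_id"]]
            assert sorted(tree.subtree_tips(tree.mrca(tips))) == sorted(tips)

    def test_newick_round_trip_preserves_distances(self):
        tree, _ = simulate_tree(SimConfig(n_tips=12, seed=2))
        back = Phylogeny.from_newick(tree.to_newick())
        order = [back.tip_index[lab] for lab in tree.tip_labels]
        D = back.patristic_matrix()[np.ix_(order, order)]
        np.testing.assert_allclose(D, tree.patristic_matrix(), atol=1e-9)


class TestSimulateOgt:
    def test_degenerate_diffusion_keeps_all_tips_at_root_value(self):
        cfg = SimConfig(n_tips=10, seed=4, bm_sigma=0.0, jump_prob=0.0)
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        vals = np.array(list(hist.tip_values.values()))
        assert np.allclose(vals, vals[0])
        assert not hist.jump_branches

    def test_seeded_repeat_identical(self):
        cfg = SimConfig(n_tips=30, seed=8)
        tree, _ = simulate_tree(cfg)
        a = simulate_ogt(tree, cfg).tip_values
        b = simulate_ogt(tree, cfg).tip_values
        assert a == b

    def test_certain_jumps_produce_large_true_dogt(self):
        cfg = SimConfig(n_tips=50, seed=6, jump_prob=1.0, jump_scale=20.0)
        tree, tax = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        assert len(hist.jump_branches) > 0
        td = true_dogt(tree, hist, tax)
        assert (td.abs() >= 10).any()

    def test_tip_variance_scales_with_bm_sigma(self):
        sds = {}
        for sigma in (2.0, 8.0):
            vals = []
            for seed in range(5):
                cfg = SimConfig(n_tips=60, seed=seed, bm_sigma=sigma, jump_prob=0.0)
                tree, _ = simulate_tree(cfg)
                hist = simulate_ogt(tree, cfg)
                vals.append(np.std(list(hist.tip_values.values())))
            sds[sigma] = np.mean(vals)
        assert sds[8.0] > 2.5 * sds[2.0]

    def test_values_clipped_to_biological_range(self):
        cfg = SimConfig(n_tips=40, seed=1, bm_sigma=40.0)
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        vals = np.array(list(hist.tip_values.values()))
        assert vals.min() >= 0.0 and vals.max() <= 105.0
        assert hist.clipped_nodes


class TestLagAndGenomes:
    def test_zero_halflife_recovers_current_ogt(self, std_sim):
        lag = lagged_ogt(std_sim["tree"], std_sim["history"], 0.0)
        for sp, v in std_sim["history"].tip_values.items():
            assert lag[sp] == pytest.approx(v)

    def test_rrna_gc_monotone_in_ogt(self):
        """With no lag, the hotter of two species gets the GC-richer 16S."""
        cfg = SimConfig(n_tips=3, seed=2, lag_halflife=0.0)
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        labs = tree.tip_labels
        hist.tip_values[labs[0]] = 10.0
        hist.tip_values[labs[1]] = 70.0
        bundles, _ = simulate_genomes(tree, hist, cfg)

        def gc(s):
            return sum(c in "GC" for c in s) / len(s)

        assert gc(bundles[labs[1]].rrna["16s"]) > gc(bundles[labs[0]].rrna["16s"])

    def test_emitted_gc_tracks_lagged_ogt(self, std_sim):
        bundles, truth = std_sim["bundles"], std_sim["truth"]
        gc = [
            sum(c in "GC" for c in bundles[s].rrna["16s"])
            / len(bundles[s].rrna["16s"])
            for s in truth["species_id"]
        ]
        r = np.corrcoef(gc, truth["ogt_lagged"])[0, 1]
        assert r > 0.8

    def test_missing_tip_in_history_rejected(self, std_sim):
        tree = std_sim["tree"]
        bad = TraitHistory({}, {}, {})
        with pytest.raises(InconsistentInputError):
            simulate_genomes(tree, bad, std_sim["config"])

    def test_species_ids_conserved_across_artifacts(self, std_sim):
        tree = std_sim["tree"]
        labels = set(tree.tip_labels)
        assert set(std_sim["bundles"]) == labels
        assert set(std_sim["truth"]["species_id"]) == labels
        assert set(std_sim["gene_matrix"].index) == labels
        assert set(std_sim["taxonomy"]["species_id"]) == labels


class TestGeneContent:
    def test_zero_rates_freeze_gene_states(self):
        cfg = SimConfig(n_tips=20, seed=3, gain_rate=0.0, loss_rate=0.0)
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        matrix, events, _ = simulate_gene_content(tree, hist, cfg)
        presence = (matrix >= 1).astype(int)
        assert (presence.nunique(axis=0) == 1).all()
        assert events.empty

    def test_seeded_repeat_identical(self):
        cfg = SimConfig(n_tips=30, seed=12)
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        a, _, _ = simulate_gene_content(tree, hist, cfg)
        b, _, _ = simulate_gene_content(tree, hist, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_strongly_coupled_gene_tops_the_pair_screen(self):
        """One strongly OGT-coupled gene among many jumps attains the
        smallest p in the extreme-pair screen."""
        from thermolag.genes import extract_extreme_pairs, fisher_screen

        cfg = SimConfig(
            n_tips=150, seed=21, jump_prob=0.15, coupling=6.0,
            n_genes=100, n_coupled_warm=1, n_coupled_cold=0,
        )
        tree, tax = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        matrix, _, info = simulate_gene_content(tree, hist, cfg)
        ogt = pd.Series(hist.tip_values)
        ogt.index.name = "species_id"
        pairs = extract_extreme_pairs(ogt, tax)
        res = fisher_screen(matrix, pairs.high_group, pairs.low_group)
        assert res.iloc[0]["gene"] == "G0001"


class TestOgtSources:
    def test_sources_contain_conventional_temperature_artifacts(self, std_sim):
        sources, meta = simulate_ogt_sources(
            std_sim["tree"], std_sim["history"], std_sim["config"]
        )
        assert len(sources) == 3
        pooled = pd.concat(sources)
        assert pooled["ogt"].isin([25.0, 28.0, 30.0, 37.0]).any()
        assert meta["completeness"].between(0, 100).all()
        assert meta["contamination"].between(0, 100).all()
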