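"""Ancestral reconstruction, dOGT, Mk model, phylogenetic signal."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_yule_tree
from oracles import mk_exhaustive_loglik, scp_numeric
from thermolag.phylo import (
    MissingTipError,
    UndefinedStatisticError,
    asr_mk,
    asr_squared_change,
    blomberg_k,
    compute_dogt,
    gene_event_shifts,
    trait_acf,
)
from thermolag.phylo import _mk_loglik
from thermolag.tree import Phylogeny


def cherry(l1=1.0, l2=1.0):
    return Phylogeny(np.array([2, 2, -1]), np.array([l1, l2, 0.0]), ["a", "b"])


class TestSquaredChange:
    def test_constant_tips_reconstruct_constant(self):
        tree = random_yule_tree(12, 1)
        res = asr_squared_change(tree, {lab: 25.0 for lab in tree.tip_labels})
        np.testing.assert_allclose(res.values, 25.0)
        assert res.objective == pytest.approx(0.0)

    def test_symmetric_cherry_averages(self):
        res = asr_squared_change(cherry(), {"a": 10.0, "b": 30.0})
        assert res.values[2] == pytest.approx(20.0)

    def test_unequal_branches_weight_the_closer_tip(self):
        # conductance 1/len: the tip on the short branch dominates
        res = asr_squared_change(cherry(1.0, 4.0), {"a": 10.0, "b": 30.0})
        assert res.values[2] == pytest.approx((10 / 1 + 30 / 4) / (1 + 1 / 4))

    def test_invariant_to_uniform_branch_rescaling(self):
        tree = random_yule_tree(15, 3)
        x = np.random.default_rng(0).normal(30, 10, tree.n_tips)
        a = asr_squared_change(tree, x)
        scaled = Phylogeny(tree.parent, tree.lengths * 7.0, tree.tip_labels)
        b = asr_squared_change(scaled, x)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_matches_numeric_minimizer_on_random_trees(self, rng):
        for _ in range(10):
            tree = random_yule_tree(int(rng.integers(3, 9)), int(rng.integers(1 << 20)))
            x = rng.normal(20, 10, tree.n_tips)
            mine = asr_squared_change(tree, x)
            np.testing.assert_allclose(
                mine.values, scp_numeric(tree, x), atol=1e-8
            )

    def test_missing_tip_named_in_error(self):
        tree = random_yule_tree(6, 5)
        with pytest.raises(MissingTipError, match=tree.tip_labels[2]):
            asr_squared_change(
                tree, {lab: 1.0 for lab in tree.tip_labels if lab != tree.tip_labels[2]}
            )


class TestDogt:
    def test_constant_trait_gives_zero_dogt(self):
        tree, tax = _tree_tax(80, 2)
        ogt = pd.Series(25.0, index=tree.tip_labels)
        table = compute_dogt(tree, ogt, tax)
        assert len(table) > 0
        np.testing.assert_allclose(table["dogt"], 0.0, atol=1e-9)

    def test_small_clades_skipped(self):
        tree, tax = _tree_tax(80, 2)
        ogt = pd.Series(25.0, index=tree.tip_labels)
        table = compute_dogt(tree, ogt, tax)
        assert (table["clade_size"] > 5).all()

    def test_engineered_cold_jump_detected_at_genus_rank(self):
        tree, tax = _tree_tax(120, 4)
        ogt = pd.Series(30.0, index=tree.tip_labels)
        genus_sizes = tax.groupby("genus")["species_id"].count()
        big = genus_sizes[genus_sizes > 6].index[0]
        victim = tax[tax["genus"] == big]["species_id"].iloc[0]
        ogt[victim] = 15.0
        table = compute_dogt(tree, ogt, tax)
        row = table[(table["rank"] == "genus") & (table["species_id"] == victim)]
        assert float(row["dogt"].iloc[0]) < -10.0

    def test_unknown_rank_rejected(self):
        tree, tax = _tree_tax(30, 2)
        with pytest.raises(ValueError):
            compute_dogt(tree, pd.Series(1.0, index=tree.tip_labels), tax, ranks=("tribe",))


def _tree_tax(n, seed):
    from thermolag.synthetic import SimConfig, simulate_tree

    return simulate_tree(SimConfig(n_tips=n, seed=seed))


class TestMk:
    def test_pruning_equals_exhaustive_state_sum(self, rng):
        for _ in range(6):
            tree = random_yule_tree(int(rng.integers(3, 6)), int(rng.integers(1 << 20)))
            states = rng.integers(0, 2, tree.n_tips)
            if states.min() == states.max():
                states[0] = 1 - states[0]
            a, b = rng.uniform(0.05, 2.0, 2)
            prior = np.array([b, a]) / (a + b)
            assert _mk_loglik(tree, states, a, b, prior) == pytest.approx(
                mk_exhaustive_loglik(tree, states, a, b, prior), abs=1e-10
            )

    def test_identical_tip_states_give_confident_root(self):
        res = asr_mk(cherry(), np.array([1, 1]), "ER")
        assert res.degenerate
        assert res.marginals[2][1] > 0.99

    def test_symmetric_conflict_gives_even_root(self):
        res = asr_mk(cherry(), np.array([0, 1]), "ER")
        assert res.marginals[2][0] == pytest.approx(0.5, abs=1e-6)

    def test_fitted_rate_beats_dense_grid(self, rng):
        tree = random_yule_tree(6, 77)
        states = np.array([0, 1, 1, 0, 1, 1])
        res = asr_mk(tree, states, "ER")
        grid = np.exp(np.linspace(np.log(1e-4), np.log(20), 50))
        for r in grid:
            prior = np.array([0.5, 0.5])
            assert res.log_likelihood >= _mk_loglik(tree, states, r, r, prior) - 1e-6

    def test_non_binary_states_rejected(self):
        with pytest.raises(ValueError):
            asr_mk(cherry(), np.array([0, 2]), "ER")

    def test_ard_rates_can_differ(self):
        tree = random_yule_tree(30, 9)
        rng = np.random.default_rng(4)
        states = (rng.random(30) < 0.8).astype(int)
        res = asr_mk(tree, states, "ARD")
        assert res.model == "ARD"
        assert res.q01 != res.q10


class TestEventShifts:
    def test_no_state_changes_gives_empty_summary(self):
        tree = random_yule_tree(10, 3)
        states = np.ones(10, dtype=int)
        mk = asr_mk(tree, states, "ER")
        anc = asr_squared_change(tree, np.full(10, 30.0))
        out = gene_event_shifts(tree, mk, anc, states, np.full(10, 30.0))
        assert out["n_gains"] == 0 and out["n_losses"] == 0
        assert out["events"].empty

    def test_single_loss_shift_is_child_minus_parent(self):
        tree = cherry()
        states = np.array([1, 0])
        ogt = np.array([25.0, 15.0])
        mk = asr_mk(tree, states, "ER")
        anc = asr_squared_change(tree, ogt)
        out = gene_event_shifts(tree, mk, anc, states, ogt)
        assert out["n_losses"] == 1
        assert out["loss_mean_shift"] == pytest.approx(15.0 - anc.values[2])

    def test_recovers_simulated_coupling_sign(self):
        """A gene whose loss is inflated on cooling branches shows a
        negative mean OGT shift across inferred loss events."""
        from thermolag.synthetic import SimConfig, simulate_gene_content, simulate_ogt, simulate_tree

        cfg = SimConfig(
            n_tips=150, seed=31, jump_prob=0.10, coupling=6.0,
            n_genes=30, n_coupled_warm=30, n_coupled_cold=0,
            gain_rate=0.02, loss_rate=0.02,
        )
        tree, _ = simulate_tree(cfg)
        hist = simulate_ogt(tree, cfg)
        matrix, events, _ = simulate_gene_content(tree, hist, cfg)
        ogt = pd.Series(hist.tip_values)
        anc = asr_squared_change(tree, ogt)
        shifts = []
        n_loss = 0
        for gene in matrix.columns:
            states = (matrix[gene] >= 1).astype(int).to_numpy()
            if states.min() == states.max():
                continue
            mk = asr_mk(tree, states, "ER")
            out = gene_event_shifts(tree, mk, anc, states, ogt)
            n_loss += out["n_losses"]
            if out["n_losses"]:
                shifts.append((out["loss_mean_shift"], out["n_losses"]))
        assert n_loss >= 10
        pooled = sum(s * n for s, n in shifts) / sum(n for _, n in shifts)
        assert pooled < 0


class TestSignal:
    def test_blomberg_k_affine_invariant(self):
        tree = random_yule_tree(40, 13)
        x = np.random.default_rng(2).normal(0, 1, 40)
        k0 = blomberg_k(tree, x)
        assert blomberg_k(tree, 3.0 * x + 7.0) == pytest.approx(k0, rel=1e-9)

    def test_white_noise_trait_has_weak_signal(self):
        tree = random_yule_tree(100, 17)
        rng = np.random.default_rng(5)
        ks = [blomberg_k(tree, rng.normal(0, 1, 100)) for _ in range(20)]
        assert np.mean(ks) < 0.5

    def test_matches_independent_reference_formula(self):
        """Direct GLS-ratio formula recomputed with explicit inverses."""
        tree = random_yule_tree(25, 19)
        x = np.random.default_rng(3).normal(30, 8, 25)
        C = tree.mrca_depth_matrix()
        Ci = np.linalg.inv(C)
        one = np.ones(25)
        a = (one @ Ci @ x) / (one @ Ci @ one)
        msr0 = ((x - a) @ (x - a)) / 24
        msr = ((x - a) @ Ci @ (x - a)) / 24
        expected = (np.trace(C) - 25 / (one @ Ci @ one)) / 24
        assert blomberg_k(tree, x) == pytest.approx((msr0 / msr) / expected, abs=1e-8)

    def test_matches_phytools_reference(self, tmp_path):
        """Cross-language check: K agrees with R phytools::phylosig."""
        import subprocess

        tree = random_yule_tree(30, 3)
        x = np.random.default_rng(0).normal(30, 8, 30)
        tree.write(tmp_path / "t.nwk")
        pd.DataFrame({"id": tree.tip_labels, "x": x}).to_csv(
            tmp_path / "x.tsv", sep="\t", index=False
        )
        rscript = (
            'suppressMessages(library(phytools));'
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            f'tab <- read.delim("{tmp_path}/x.tsv");'
            'x <- setNames(tab$x, tab$id)[tr$tip.label];'
            'cat(sprintf("%.12f", phylosig(tr, x, method="K")))'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        assert blomberg_k(tree, x) == pytest.approx(float(out.stdout), abs=1e-8)

    def test_constant_trait_undefined(self):
        tree = random_yule_tree(10, 23)
        with pytest.raises(UndefinedStatisticError):
            blomberg_k(tree, np.ones(10))
        with pytest.raises(UndefinedStatisticError):
            trait_acf(tree, np.ones(10), 2)

    def test_single_bin_equals_symmetrized_pearson(self):
        tree = random_yule_tree(20, 29)
        x = np.random.default_rng(7).normal(0, 1, 20)
        acf = trait_acf(tree, x, 1)
        iu = np.triu_indices(20, k=1)
        u = np.concatenate([x[iu[0]], x[iu[1]]])
        v = np.concatenate([x[iu[1]], x[iu[0]]])
        assert acf["correlation"].iloc[0] == pytest.approx(
            np.corrcoef(u, v)[0, 1], abs=1e-9
        )

    def test_brownian_trait_decorrelates_with_distance(self):
        tree = random_yule_tree(100, 37)
        C = tree.mrca_depth_matrix()
        L = np.linalg.cholesky(C + 1e-10 * np.eye(100))
        rng = np.random.default_rng(11)
        firsts, lasts = [], []
        for _ in range(10):
            x = L @ rng.normal(size=100)
            acf = trait_acf(tree, x, 5)
            firsts.append(acf["correlation"].iloc[0])
            lasts.append(acf["correlation"].iloc[-1])
        assert np.mean(firsts) > np.mean(lasts)

    def test_more_bins_than_pairs_rejected(self):
        tree = random_yule_tree(4, 41)
        with pytest.raises(ValueError):
            trait_acf(tree, np.array([1.0, 2.0, 3.0, 4.0]), 10)
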