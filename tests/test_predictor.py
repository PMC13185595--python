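"""Leave-one-phylum-out regression, metrics, and improvement analysis."""

import numpy as np
import pandas as pd
import pytest

from oracles import tukey_hsd_manual
from thermolag.predictor import (
    ModelSpec,
    PredictionResult,
    classify_psychrophiles,
    dogt_improvement,
    evaluate,
    lopo_folds,
    run_lopo,
)


def make_result(obs, pred, phylum=None):
    ids = [f"s{i}" for i in range(len(obs))]
    df = pd.DataFrame(
        {
            "observed": obs,
            "predicted": pred,
            "phylum": phylum or ["p1"] * len(obs),
        },
        index=pd.Index(ids, name="species_id"),
    )
    df["error"] = df["predicted"] - df["observed"]
    df["in_train_pool"] = True
    return PredictionResult(df, {}, 0.0)


def toy_dataset(n=120, n_phyla=3, n_inform=3, n_noise=10, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i:03d}" for i in range(n)]
    X = pd.DataFrame(
        rng.uniform(0, 1, (n, n_inform + n_noise)),
        index=pd.Index(ids, name="species_id"),
        columns=[f"f{j}" for j in range(n_inform + n_noise)],
    )
    w = np.array([30.0, -20.0, 10.0] + [0.0] * n_noise)
    y = pd.Series(X.to_numpy() @ w + 25.0, index=X.index)
    tax = pd.DataFrame(
        {
            "species_id": ids,
            "genus": [f"g{i % 20}" for i in range(n)],
            "phylum": [f"p{i % n_phyla}" for i in range(n)],
        }
    )
    return X, y, tax


class TestFolds:
    def test_one_fold_per_phylum_partitioning_species(self):
        phylum = pd.Series(
            ["pA"] * 3 + ["pB"] * 4 + ["pC"] * 2,
            index=[f"s{i}" for i in range(9)],
        )
        folds = lopo_folds(phylum)
        assert len(folds) == 3
        tests = [set(t) for _, t in folds]
        assert set().union(*tests) == set(phylum.index)
        for a in range(3):
            assert len(tests[a] & set(folds[a][0])) == 0
            for b in range(a + 1, 3):
                assert not tests[a] & tests[b]
            assert len(folds[a][0]) + len(folds[a][1]) == 9

    def test_single_phylum_rejected(self):
        with pytest.raises(ValueError):
            lopo_folds(pd.Series(["p"] * 5, index=[f"s{i}" for i in range(5)]))


class TestRunLopo:
    def test_recovers_exact_linear_signal(self):
        X, y, tax = toy_dataset()
        res = run_lopo(X, y, ModelSpec("lasso"), tax)
        assert res.cv_r2 > 0.99
        assert set(res.predictions.index) == set(X.index)

    def test_permuted_labels_have_no_predictable_signal(self):
        X, y, tax = toy_dataset(n=300, seed=1)
        rng = np.random.default_rng(2)
        scores = []
        for _ in range(10):
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            res = run_lopo(
                X, yp, ModelSpec("lasso", grid={"alpha": [0.01]}), tax
            )
            scores.append(res.cv_r2)
        assert np.mean(scores) <= 0.05

    def test_id_mismatch_rejected(self):
        X, y, tax = toy_dataset(n=30)
        with pytest.raises(ValueError):
            run_lopo(X, y.iloc[:10], ModelSpec("lasso"), tax)

    def test_gene_feature_set_requires_matrix(self):
        X, y, tax = toy_dataset(n=30)
        with pytest.raises(ValueError, match="gene matrix"):
            run_lopo(X, y, ModelSpec("lasso", feature_set="composition+genes"), tax)

    def test_aa2mer_subset_restricts_features(self):
        X, y, tax = toy_dataset(n=60)
        X = X.rename(columns={"f0": "aa2_AA", "f1": "aa2_AC"})
        res = run_lopo(X, y, ModelSpec("svr", grid={"C": [10], "epsilon": [0.1]},
                                       feature_set="aa2mer_only"), tax)
        cols = res.fold_gene_lists  # no genes involved
        assert cols == {p: [] for p in cols}
        # only the two 2-mer columns were available to the model
        assert res.predictions.shape[0] == 60

    def test_excluded_species_predicted_by_their_fold_model(self):
        X, y, tax = toy_dataset(n=90)
        pool = list(X.index[:60])
        res = run_lopo(X, y, ModelSpec("lasso"), tax, train_pool=pool)
        assert set(res.predictions.index) == set(X.index)
        assert (~res.predictions.loc[~res.predictions.index.isin(pool),
                                     "in_train_pool"]).all()

    def test_no_leakage_from_held_out_phylum(self, std_sim):
        """Mutating every held-out-phylum row leaves that fold's gene
        list and fitted coefficients unchanged."""
        from thermolag.features import build_feature_table, default_manifest

        tax = std_sim["taxonomy"]
        genes = std_sim["gene_matrix"]
        ogt = std_sim["truth"].set_index("species_id")["ogt"]
        sub = list(ogt.index)
        feats = pd.DataFrame(
            np.random.default_rng(0).uniform(0, 1, (len(sub), 12)),
            index=pd.Index(sub, name="species_id"),
            columns=[f"f{j}" for j in range(12)],
        )
        spec = ModelSpec("lasso", grid={"alpha": [0.004]},
                         feature_set="composition+genes")
        res = run_lopo(feats, ogt, spec, tax, gene_matrix=genes, top_k=10)
        target = sorted(res.fold_gene_lists)[0]
        held = tax.set_index("species_id")["phylum"] == target
        held_ids = held[held].index
        ogt2 = ogt.copy()
        ogt2.loc[held_ids] = 99.0
        genes2 = genes.copy()
        genes2.loc[held_ids] = 0
        feats2 = feats.copy()
        feats2.loc[held_ids] = 0.5
        res2 = run_lopo(feats2, ogt2, spec, tax, gene_matrix=genes2, top_k=10)
        assert res.fold_gene_lists[target] == res2.fold_gene_lists[target]
        pd.testing.assert_series_equal(
            res.fold_coefficients[target], res2.fold_coefficients[target]
        )

    def test_seeded_rerun_identical(self):
        X, y, tax = toy_dataset(n=60)
        a = run_lopo(X, y, ModelSpec("lasso"), tax)
        b = run_lopo(X, y, ModelSpec("lasso"), tax)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.chosen_params == b.chosen_params


class TestEvaluate:
    def test_perfect_predictions(self):
        res = make_result([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        m = evaluate(res)
        assert m["r2"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0)
        assert m["mae"] == pytest.approx(0.0)

    def test_mean_prediction_scores_zero_r2(self):
        res = make_result([10.0, 20.0, 30.0], [20.0, 20.0, 20.0])
        assert evaluate(res)["r2"] == pytest.approx(0.0)

    def test_hand_computed_errors(self):
        res = make_result([10.0, 20.0, 30.0], [12.0, 20.0, 28.0])
        m = evaluate(res)
        assert m["rmse"] == pytest.approx(np.sqrt(8 / 3))
        assert m["mae"] == pytest.approx(4 / 3)

    def test_class_maes_split_by_observed_ogt(self):
        res = make_result([10.0, 30.0, 70.0], [15.0, 30.0, 60.0])
        m = evaluate(res)
        assert m["mae_psychrophile"] == pytest.approx(5.0)
        assert m["mae_mesophile"] == pytest.approx(0.0)
        assert m["mae_thermophile"] == pytest.approx(10.0)


class TestPsychrophileClassification:
    def test_confusion_counts_match_brute_force(self):
        obs = [15.0, 25.0, 18.0, 30.0, 19.0, 50.0]
        pred = [18.0, 19.0, 25.0, 33.0, 12.0, 45.0]
        out = classify_psychrophiles(make_result(obs, pred))
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (2, 1, 1, 2)
        assert out["sensitivity"] == pytest.approx(2 / 3)
        assert out["false_positive_rate"] == pytest.approx(1 / 3)


class TestImprovement:
    @staticmethod
    def _dogt(values):
        s = pd.Series(values, index=[f"s{i}" for i in range(len(values))])
        s.index.name = "species_id"
        return s

    def test_identical_models_show_no_effect(self):
        obs = list(np.linspace(5, 80, 12))
        pred = [o + 2 for o in obs]
        a = make_result(obs, pred)
        b = make_result(obs, pred)
        dogt = self._dogt([-15] * 4 + [0] * 4 + [15] * 4)
        out = dogt_improvement(a, b, dogt)
        for g in ("dogt<=-10", "|dogt|<10", "dogt>=10"):
            assert out[f"mean_improvement[{g}]"] == pytest.approx(0.0)
        assert out["anova_F"] == pytest.approx(0.0)
        assert out["anova_p"] == pytest.approx(1.0)

    def test_uniform_one_degree_gain(self):
        obs = list(np.linspace(5, 80, 12))
        a = make_result(obs, [o + 2 for o in obs])
        b = make_result(obs, [o + 1 for o in obs])
        dogt = self._dogt([-15] * 4 + [0] * 4 + [15] * 4)
        out = dogt_improvement(a, b, dogt)
        for g in ("dogt<=-10", "|dogt|<10", "dogt>=10"):
            assert out[f"mean_improvement[{g}]"] == pytest.approx(1.0)

    def test_tiny_group_reported_as_undefined(self):
        obs = [10.0, 20.0, 30.0]
        a = make_result(obs, [12.0, 22.0, 32.0])
        b = make_result(obs, [11.0, 21.0, 31.0])
        out = dogt_improvement(a, b, self._dogt([-20, 0, 0]))
        assert np.isnan(out["mean_improvement[dogt<=-10]"])

    def test_tukey_matches_studentized_range_formula(self, rng):
        n = 60
        obs = list(np.linspace(5, 80, n))
        err_a = rng.normal(3, 1, n)
        err_b = rng.normal(2, 1, n)
        a = make_result(obs, list(np.array(obs) + err_a))
        b = make_result(obs, list(np.array(obs) + err_b))
        dvals = np.concatenate([[-15] * 20, [0] * 20, [15] * 20])
        out = dogt_improvement(a, b, self._dogt(dvals))
        imp = np.abs(err_a) - np.abs(err_b)
        # statsmodels orders groups by sorted label: <=-10, >=10, |.|<10
        samples = [imp[:20], imp[40:], imp[20:40]]
        manual = tukey_hsd_manual(samples)
        got = out["tukey"]
        assert got is not None and len(got) == 3
        for (_, _, diff, lo, hi), (_, row) in zip(manual, got.iterrows()):
            assert float(row["meandiff"]) == pytest.approx(diff, abs=1e-8)
            assert float(row["lower"]) == pytest.approx(lo, abs=1e-6)
            assert float(row["upper"]) == pytest.approx(hi, abs=1e-6)
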