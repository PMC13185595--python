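"""OGT regression under leave-one-phylum-out cross-validation.

Each fold holds out every species of one phylum, so the model is scored
on clades it has never seen. Feature min/max normalization and — for the
gene-augmented feature set — the OGT-associated gene list are re-derived
inside each training fold, so no information from the held-out phylum
leaks into model construction. Hyperparameters are chosen as the grid
value maximizing the overall cross-validated R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.svm import SVR
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .curation import thermal_class
from .features import minmax_normalize
from .genes import extract_extreme_pairs, fisher_screen, psychrophile_screen, select_top_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "PredictionResult",
    "lopo_folds",
    "run_lopo",
    "evaluate",
    "classify_psychrophiles",
    "dogt_improvement",
]

DEFAULT_GRIDS = {
    "lasso": {"alpha": [0.001, 0.002, 0.004, 0.006, 0.008, 0.01]},
    "svr": {"C": [0.1, 1, 10, 100], "epsilon": [0.001, 0.01, 0.1]},
}
FEATURE_SETS = ("composition", "composition+genes", "aa2mer_only")


@dataclass
class ModelSpec:
    family: str = "lasso"
    grid: dict | None = None
    feature_set: str = "composition"

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set: {self.feature_set!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not all(self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class PredictionResult:
    """Per-species observed/predicted OGT plus per-run fit metadata."""

    predictions: pd.DataFrame  # observed, predicted, phylum, error, in_train_pool
    chosen_params: dict
    cv_r2: float
    spec: ModelSpec = field(default_factory=ModelSpec)
    fold_gene_lists: dict[str, list[str]] = field(default_factory=dict)
    fold_coefficients: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def nonzero_coefficients(self) -> dict[str, int]:
        return {
            ph: int((c != 0).sum()) for ph, c in self.fold_coefficients.items()
        }


def lopo_folds(phylum: pd.Series) -> list[tuple[list[str], list[str]]]:
    """One (train ids, test ids) fold per phylum, in phylum-name order."""
    phyla = sorted(phylum.unique())
    if len(phyla) < 2:
        raise ValueError("leave-one-phylum-out needs at least 2 phyla")
    folds = []
    for p in phyla:
        test = sorted(phylum.index[phylum == p])
        train = sorted(phylum.index[phylum != p])
        folds.append((train, test))
    return folds


def _fold_gene_list(
    ogt_train: pd.Series,
    taxonomy: pd.DataFrame,
    gene_train: pd.DataFrame,
    top_k: int,
) -> list[str]:
    """Derive the OGT-associated gene list from training data only."""
    pairs = extract_extreme_pairs(ogt_train, taxonomy)
    res_pairs = None
    if len(pairs.pairs):
        res_pairs = fisher_screen(gene_train, pairs.high_group, pairs.low_group)
    try:
        res_psych = psychrophile_screen(gene_train, ogt_train)
    except ValueError:
        res_psych = None
    if res_pairs is None and res_psych is None:
        raise ValueError("no usable gene screen in this training fold")
    if res_pairs is None:
        res_pairs = res_psych
    if res_psych is None:
        res_psych = res_pairs
    k = min(top_k, len(res_pairs), len(res_psych))
    return select_top_genes(res_pairs, res_psych, k)


def _make_model(family: str, params: dict):
    if family == "lasso":
        return Lasso(max_iter=200000, **params)
    return SVR(**params)


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    points = [{}]
    for k in keys:
        points = [dict(p, **{k: v}) for p in points for v in grid[k]]
    return points


def run_lopo(
    features: pd.DataFrame,
    ogt: pd.Series,
    spec: ModelSpec,
    taxonomy: pd.DataFrame,
    train_pool: list[str] | None = None,
    gene_matrix: pd.DataFrame | None = None,
    top_k: int = 50,
    fixed_params: dict | None = None,
) -> PredictionResult:
    """Fit and score one model family under leave-one-phylum-out CV.

    ``train_pool`` restricts training (e.g. the mesophile-downsampled
    set); every species in ``features`` is still predicted once, by the
    model of its phylum's fold. The grid point maximizing R² over the
    training-pool species is selected and its predictions returned.
    ``fixed_params`` skips the grid search (used to keep the
    composition-model hyperparameters when adding gene features, for a
    like-for-like comparison).
    """
    ids = list(features.index)
    missing = [s for s in ids if s not in ogt.index]
    if missing:
        raise ValueError(f"species lack OGT values: {missing[:5]}")
    if spec.feature_set == "composition+genes" and gene_matrix is None:
        raise ValueError("feature_set 'composition+genes' requires a gene matrix")
    if spec.feature_set == "aa2mer_only":
        cols = [c for c in features.columns if c.startswith("aa2_")]
        features = features[cols]
    tax = taxonomy.set_index("species_id")
    phylum = tax.loc[ids, "phylum"]
    pool = set(train_pool) if train_pool is not None else set(ids)

    prepared = []
    for train, test in lopo_folds(phylum):
        train_fit = [s for s in train if s in pool]
        gene_list: list[str] = []
        Xtr = features.loc[train_fit]
        Xte = features.loc[test]
        if spec.feature_set == "composition+genes":
            gene_list = _fold_gene_list(
                ogt.loc[train_fit], taxonomy, gene_matrix.loc[train_fit], top_k
            )
            Xtr = pd.concat(
                [Xtr, gene_matrix.loc[train_fit, gene_list].astype(float)], axis=1
            )
            Xte = pd.concat(
                [Xte, gene_matrix.loc[test, gene_list].astype(float)], axis=1
            )
        Xtr_n, ref = minmax_normalize(Xtr)
        Xte_n, _ = minmax_normalize(Xte, reference=Xtr)
        prepared.append(
            {
                "phylum": phylum[test[0]],
                "train": train_fit,
                "test": test,
                "Xtr": Xtr_n.to_numpy(),
                "ytr": ogt.loc[train_fit].to_numpy(),
                "Xte": Xte_n.to_numpy(),
                "gene_list": gene_list,
                "columns": list(Xtr_n.columns),
            }
        )

    best = None
    grid = [dict(fixed_params)] if fixed_params is not None else _grid_points(spec.grid)
    for params in grid:
        preds = {}
        coefs = {}
        for fold in prepared:
            model = _make_model(spec.family, params)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(fold["Xtr"], fold["ytr"])
            yhat = model.predict(fold["Xte"])
            for sid, v in zip(fold["test"], yhat):
                preds[sid] = float(v)
            if spec.family == "lasso":
                coefs[fold["phylum"]] = pd.Series(
                    model.coef_, index=fold["columns"]
                )
        scored = [s for s in ids if s in pool]
        r2 = r2_score(
            ogt.loc[scored].to_numpy(), np.array([preds[s] for s in scored])
        )
        if best is None or r2 > best["r2"]:
            best = {"r2": r2, "params": params, "preds": preds, "coefs": coefs}

    pred_df = pd.DataFrame(
        {
            "observed": ogt.loc[ids].to_numpy(),
            "predicted": [best["preds"][s] for s in ids],
            "phylum": phylum.loc[ids].to_numpy(),
        },
        index=pd.Index(ids, name="species_id"),
    )
    pred_df["error"] = pred_df["predicted"] - pred_df["observed"]
    pred_df["in_train_pool"] = [s in pool for s in ids]
    return PredictionResult(
        predictions=pred_df,
        chosen_params=best["params"],
        cv_r2=float(best["r2"]),
        spec=spec,
        fold_gene_lists={f["phylum"]: f["gene_list"] for f in prepared},
        fold_coefficients=best["coefs"],
    )


# --------------------------------------------------------------------- #
#  Metrics
# --------------------------------------------------------------------- #
def evaluate(result: PredictionResult, subset: str = "all") -> dict:
    """R², RMSE and MAE overall plus MAE per thermal class.

    ``subset='downsampled'`` scores only species in the training pool;
    ``'all'`` scores every predicted species.
    """
    df = result.predictions
    if subset == "downsampled":
        df = df[df["in_train_pool"]]
    if len(df) < 2:
        raise ValueError("need at least 2 species to evaluate")
    obs = df["observed"].to_numpy()
    pred = df["predicted"].to_numpy()
    err = np.abs(pred - obs)
    out = {
        "r2": float(r2_score(obs, pred)),
        "rmse": float(np.sqrt(mean_squared_error(obs, pred))),
        "mae": float(err.mean()),
        "n": int(len(df)),
    }
    classes = thermal_class(obs)
    for cls in ("psychrophile", "mesophile", "other", "thermophile"):
        mask = classes == cls
        out[f"mae_{cls}"] = float(err[mask].mean()) if mask.any() else np.nan
        out[f"n_{cls}"] = int(mask.sum())
    return out


def classify_psychrophiles(result: PredictionResult, threshold: float = 20.0) -> dict:
    """Confusion summary of predicted-psychrophile calls (< 20 °C)."""
    df = result.predictions
    obs_cold = df["observed"] < threshold
    pred_cold = df["predicted"] < threshold
    tp = int((obs_cold & pred_cold).sum())
    fp = int((~obs_cold & pred_cold).sum())
    tn = int((~obs_cold & ~pred_cold).sum())
    fn = int((obs_cold & ~pred_cold).sum())
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "false_positive_rate": fp / (fp + tn) if fp + tn else np.nan,
    }


DOGT_GROUPS = ("dogt<=-10", "|dogt|<10", "dogt>=10")


def _dogt_group(d: np.ndarray) -> np.ndarray:
    return np.where(
        d <= -10, DOGT_GROUPS[0], np.where(d >= 10, DOGT_GROUPS[2], DOGT_GROUPS[1])
    )


def dogt_improvement(
    result_a: PredictionResult,
    result_b: PredictionResult,
    dogt: pd.Series,
) -> dict:
    """Prediction improvement of model B over model A, grouped by dOGT.

    Improvement per species is ``|error_a| - |error_b|`` (positive when B
    is closer). Groups are dOGT <= -10, |dOGT| < 10, dOGT >= 10; a
    one-way ANOVA F/p and all pairwise Tukey HSD differences over the
    groups are included (groups with < 2 members are undefined).
    """
    a = result_a.predictions
    b = result_b.predictions
    if set(a.index) != set(b.index):
        raise ValueError("both results must cover the same species")
    ids = [s for s in a.index if s in dogt.index]
    imp = (a.loc[ids, "error"].abs() - b.loc[ids, "error"].abs()).to_numpy()
    groups = _dogt_group(dogt.loc[ids].to_numpy())
    out: dict = {"n": len(ids)}
    samples = []
    names = []
    for g in DOGT_GROUPS:
        vals = imp[groups == g]
        out[f"mean_improvement[{g}]"] = (
            float(vals.mean()) if len(vals) >= 2 else np.nan
        )
        out[f"n[{g}]"] = int(len(vals))
        if len(vals) >= 2:
            samples.append(vals)
            names.append(g)
    if len(samples) >= 2:
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            # identical improvements everywhere: no group effect at all
            f, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*samples)
        out["anova_F"], out["anova_p"] = float(f), float(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tuk = pairwise_tukeyhsd(
                np.concatenate(samples),
                np.concatenate([[n] * len(s) for n, s in zip(names, samples)]),
            )
        g = list(tuk.groupsunique)
        pairs = [
            (g[i], g[j])
            for i in range(len(g))
            for j in range(i + 1, len(g))
        ]
        out["tukey"] = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "meandiff": tuk.meandiffs,
                "p-adj": tuk.pvalues,
                "lower": tuk.confint[:, 0],
                "upper": tuk.confint[:, 1],
                "reject": tuk.reject,
            }
        )
    else:
        out["anova_F"] = out["anova_p"] = np.nan
        out["tukey"] = None
    return out
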