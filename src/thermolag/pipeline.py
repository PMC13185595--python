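"""End-to-end orchestration: simulate -> curate -> featurize -> screen ->
predict -> evolve -> report, driven by one config and one seed.

The report quantifies the lag mechanism: how signed prediction error of
a composition-only model tracks recent OGT shifts (dOGT), how that
association fades at deeper taxonomic ranks, and how much gene
presence/absence features recover for recently shifted species.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import curation, io, phylo, predictor, synthetic
from .features import build_feature_table, default_manifest
from .genes import extract_extreme_pairs, fisher_screen, psychrophile_screen, select_top_genes
from .synthetic import SimConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_all",
    "error_vs_dogt_slopes",
    "improvement_curve",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (round-trips via YAML)."""

    seed: int = 0
    out_dir: str = "results/run"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    model_family: str = "lasso"
    top_k: int = 50
    pseudocount: float = 0.5
    use_curation: bool = True
    write_genomes: bool = False
    n_acf_bins: int = 10
    moving_window: float = 5.0
    n_bootstrap: int = 200

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------- #
#  Report statistics
# --------------------------------------------------------------------- #
def error_vs_dogt_slopes(
    result: predictor.PredictionResult, dogt_table: pd.DataFrame
) -> pd.DataFrame:
    """OLS of signed prediction error on dOGT*, one row per rank.

    Reports slope, intercept and the slope's 95 % CI, plus whether
    |slope| decreases monotonically from genus to phylum (the signature
    of composition catching up with OGT over longer timescales).
    """
    rows = []
    for rank in phylo.RANK_ORDER:
        sub = dogt_table[dogt_table["rank"] == rank].set_index("species_id")
        sub = sub[sub.index.isin(result.predictions.index)]
        if len(sub) < 3:
            continue
        err = result.predictions.loc[sub.index, "error"].to_numpy()
        X = sm.add_constant(sub["dogt"].to_numpy())
        fit = sm.OLS(err, X).fit()
        lo, hi = fit.conf_int()[1]
        rows.append(
            {
                "rank": rank,
                "slope": float(fit.params[1]),
                "intercept": float(fit.params[0]),
                "slope_ci_low": float(lo),
                "slope_ci_high": float(hi),
                "n": int(len(sub)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        mags = out["slope"].abs().to_numpy()
        out.attrs["monotone_decreasing"] = bool(np.all(np.diff(mags) <= 1e-12))
    return out


def improvement_curve(
    result_a: predictor.PredictionResult,
    result_b: predictor.PredictionResult,
    window: float = 5.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Moving average of per-species improvement along observed OGT.

    Fixed-width window (°C) moving average of |error_a| - |error_b| with
    a bootstrap 95 % CI.
    """
    a = result_a.predictions
    b = result_b.predictions.loc[a.index]
    imp = (a["error"].abs() - b["error"].abs()).to_numpy()
    obs = a["observed"].to_numpy()
    rng = np.random.default_rng(seed)
    grid = np.arange(np.floor(obs.min()), np.ceil(obs.max()) + 1.0)
    rows = []
    for c in grid:
        mask = np.abs(obs - c) <= window / 2
        n = int(mask.sum())
        if n < 3:
            continue
        vals = imp[mask]
        boots = np.array(
            [vals[rng.integers(0, n, n)].mean() for _ in range(n_bootstrap)]
        )
        rows.append(
            {
                "ogt_center": float(c),
                "mean_improvement": float(vals.mean()),
                "ci_low": float(np.quantile(boots, 0.025)),
                "ci_high": float(np.quantile(boots, 0.975)),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
#  Orchestration
# --------------------------------------------------------------------- #
def run_all(config: RunConfig) -> dict:
    """Execute every stage and emit the report bundle.

    Writes tables under ``config.out_dir`` and returns the report dict
    (also written as ``metrics.json`` + ``report.md``). Every stage's
    written inputs are hashed into the report for provenance.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = io.write_tsv(df, out / name, index=index)
        hashes[name] = io.file_sha256(p)

    # --- simulate ----------------------------------------------------- #
    try:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        tree, taxonomy = synthetic.simulate_tree(sim_cfg)
        history = synthetic.simulate_ogt(tree, sim_cfg)
        bundles, truth = synthetic.simulate_genomes(tree, history, sim_cfg)
        gene_matrix, events, gene_info = synthetic.simulate_gene_content(
            tree, history, sim_cfg
        )
        sources, meta = synthetic.simulate_ogt_sources(tree, history, sim_cfg)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    tree.write(out / "tree.nwk")
    hashes["tree.nwk"] = io.file_sha256(out / "tree.nwk")
    emit(taxonomy, "taxonomy.tsv")
    emit(truth, "ogt_truth.tsv")
    emit(gene_matrix, "gene_matrix.tsv", index=True)
    if config.write_genomes:
        io.write_bundles(bundles, out / "genomes")

    # --- curate -------------------------------------------------------- #
    try:
        if config.use_curation:
            merged = curation.merge_ogt_sources(sources)
            rec = merged.merge(meta, on="species_id").merge(
                taxonomy, on="species_id"
            )
            rec = curation.quality_filter(rec)
            kept = curation.downsample_mesophiles(rec)
            analysis = rec
            train_pool = list(kept["species_id"])
        else:
            analysis = truth.rename(columns={"ogt": "ogt"}).merge(
                taxonomy, on="species_id"
            )
            train_pool = list(analysis["species_id"])
        if len(analysis) < 10:
            raise ValueError("fewer than 10 species survive curation")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("curate", str(exc)) from exc
    emit(analysis, "curated.tsv")
    ogt = analysis.set_index("species_id")["ogt"]

    # --- featurize ----------------------------------------------------- #
    try:
        manifest = default_manifest()
        sub_bundles = {s: bundles[s] for s in ogt.index}
        features, drop_log = build_feature_table(
            sub_bundles, manifest, pseudocount=config.pseudocount
        )
    except Exception as exc:
        raise StageError("featurize", str(exc)) from exc
    emit(features, "features.tsv", index=True)
    emit(drop_log, "feature_drop_log.tsv")
    ogt = ogt.loc[features.index]
    train_pool = [s for s in train_pool if s in features.index]

    # --- evolve -------------------------------------------------------- #
    try:
        sub_tree = tree.prune_to(list(features.index))
        dogt_table = phylo.compute_dogt(sub_tree, ogt, taxonomy)
        k_all = phylo.blomberg_k(sub_tree, ogt)
        acf = phylo.trait_acf(sub_tree, ogt, config.n_acf_bins)
    except Exception as exc:
        raise StageError("evolve", str(exc)) from exc
    emit(dogt_table, "dogt.tsv")
    emit(acf, "trait_acf.tsv")

    # --- gene screens (whole-data report; per-fold lists are re-derived
    #     inside the predictor) ----------------------------------------- #
    try:
        pairs = extract_extreme_pairs(ogt, taxonomy)
        genes_sub = gene_matrix.loc[features.index]
        screen_pairs = fisher_screen(genes_sub, pairs.high_group, pairs.low_group)
        screen_psych = psychrophile_screen(genes_sub, ogt)
        k = min(config.top_k, len(screen_pairs), len(screen_psych))
        top_genes = select_top_genes(screen_pairs, screen_psych, k)
    except Exception as exc:
        raise StageError("genes", str(exc)) from exc
    emit(screen_pairs.head(100), "screen_pairs_top.tsv")
    emit(screen_psych.head(100), "screen_psychrophiles_top.tsv")

    # --- predict -------------------------------------------------------- #
    try:
        spec_a = predictor.ModelSpec(config.model_family, feature_set="composition")
        res_a = predictor.run_lopo(
            features, ogt, spec_a, taxonomy, train_pool=train_pool
        )
        spec_b = predictor.ModelSpec(
            config.model_family, feature_set="composition+genes"
        )
        res_b = predictor.run_lopo(
            features,
            ogt,
            spec_b,
            taxonomy,
            train_pool=train_pool,
            gene_matrix=gene_matrix,
            top_k=config.top_k,
            fixed_params=res_a.chosen_params,
        )
    except Exception as exc:
        raise StageError("predict", str(exc)) from exc
    emit(res_a.predictions, "predictions_composition.tsv", index=True)
    emit(res_b.predictions, "predictions_genes.tsv", index=True)

    # --- report --------------------------------------------------------- #
    genus_dogt = (
        dogt_table[dogt_table["rank"] == "genus"]
        .set_index("species_id")["dogt"]
    )
    slopes = error_vs_dogt_slopes(res_a, dogt_table)
    emit(slopes, "error_dogt_slopes.tsv")
    curve = improvement_curve(
        res_a, res_b, config.moving_window, config.n_bootstrap, config.seed
    )
    emit(curve, "improvement_curve.tsv")
    imp = predictor.dogt_improvement(res_a, res_b, genus_dogt)
    report = {
        "config": config.to_dict(),
        "n_species": int(len(features)),
        "n_train_pool": len(train_pool),
        "composition": {
            "chosen_params": res_a.chosen_params,
            "metrics_all": _round(predictor.evaluate(res_a, "all")),
            "metrics_downsampled": _round(predictor.evaluate(res_a, "downsampled")),
            "psychrophile_confusion": _round(
                predictor.classify_psychrophiles(res_a)
            ),
        },
        "composition_genes": {
            "chosen_params": res_b.chosen_params,
            "metrics_all": _round(predictor.evaluate(res_b, "all")),
            "metrics_downsampled": _round(predictor.evaluate(res_b, "downsampled")),
            "psychrophile_confusion": _round(
                predictor.classify_psychrophiles(res_b)
            ),
            "n_selected_genes": len(top_genes),
            "nonzero_coefficients": res_b.nonzero_coefficients,
        },
        "signal": {
            "blomberg_k": round(k_all, 6),
            "acf_first_bin": round(float(acf["correlation"].iloc[0]), 6),
            "acf_last_bin": round(float(acf["correlation"].iloc[-1]), 6),
        },
        "error_vs_dogt": {
            "slopes": {
                r["rank"]: round(r["slope"], 6) for _, r in slopes.iterrows()
            },
            "monotone_decreasing": slopes.attrs.get("monotone_decreasing"),
        },
        "improvement_by_dogt": _round(
            {k: v for k, v in imp.items() if not isinstance(v, pd.DataFrame)}
        ),
        "input_hashes": hashes,
    }
    io.write_json(report, out / "metrics.json")
    _write_markdown(report, out / "report.md")
    return report


def _round(d: dict, nd: int = 6) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, float):
            out[k] = round(v, nd) if np.isfinite(v) else None
        else:
            out[k] = v
    return out


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Pipeline report", ""]
    a = report["composition"]["metrics_all"]
    b = report["composition_genes"]["metrics_all"]
    lines += [
        "## Prediction accuracy (all species)",
        "",
        "| model | R2 | RMSE | MAE | MAE psychrophiles |",
        "|---|---|---|---|---|",
        f"| composition | {a['r2']:.3f} | {a['rmse']:.2f} | {a['mae']:.2f} | {a['mae_psychrophile']} |",
        f"| composition+genes | {b['r2']:.3f} | {b['rmse']:.2f} | {b['mae']:.2f} | {b['mae_psychrophile']} |",
        "",
        "## Phylogenetic signal",
        "",
        f"Blomberg's K (OGT): {report['signal']['blomberg_k']}",
        f"Trait ACF first/last bin: {report['signal']['acf_first_bin']} / {report['signal']['acf_last_bin']}",
        "",
        "## Error vs dOGT* slopes",
        "",
        str(report["error_vs_dogt"]["slopes"]),
        f"(|slope| monotone decreasing genus->phylum: {report['error_vs_dogt']['monotone_decreasing']})",
        "",
        "## Improvement by dOGT group",
        "",
        str(report["improvement_by_dogt"]),
        "",
    ]
    path.write_text("\n".join(lines))
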