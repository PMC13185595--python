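"""OGT-associated ortholog discovery.

Two screens feed the gene-augmented predictor: the *extreme-pair* screen
contrasts the highest- and lowest-OGT species within each genus (pairs
at least 10 °C apart, at most three per genus, so close relatives act as
their own phylogenetic controls), and the *psychrophile* screen
contrasts species with OGT < 20 °C against all others. Both use Fisher's
exact test on presence/absence with Bonferroni correction over the
number of informative genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PairSet",
    "extract_extreme_pairs",
    "fisher_pvalues",
    "fisher_screen",
    "psychrophile_screen",
    "select_top_genes",
    "augment_feature_table",
    "pathway_enrichment",
    "bonferroni_adjust",
]

MIN_PAIR_DELTA = 10.0
MAX_PAIRS_PER_GENUS = 3


@dataclass
class PairSet:
    """Within-genus extreme-OGT species pairs and the two group rosters."""

    pairs: pd.DataFrame  # high, low, genus, delta_ogt
    high_group: list[str]
    low_group: list[str]


def extract_extreme_pairs(
    ogt: pd.Series,
    taxonomy: pd.DataFrame,
    min_delta: float = MIN_PAIR_DELTA,
    max_pairs: int = MAX_PAIRS_PER_GENUS,
) -> PairSet:
    """Iteratively pop (max, min) OGT species per genus while the
    difference stays >= ``min_delta`` °C, up to ``max_pairs`` pairs."""
    genus = taxonomy.set_index("species_id")["genus"]
    rows = []
    for g, members in genus.groupby(genus).groups.items():
        avail = ogt.loc[[m for m in members if m in ogt.index]].sort_values()
        taken = 0
        while taken < max_pairs and len(avail) >= 2:
            lo_id, hi_id = avail.index[0], avail.index[-1]
            delta = float(avail.iloc[-1] - avail.iloc[0])
            if delta < min_delta:
                break
            rows.append(
                {"high": hi_id, "low": lo_id, "genus": g, "delta_ogt": delta}
            )
            avail = avail.drop([lo_id, hi_id])
            taken += 1
    pairs = pd.DataFrame(rows, columns=["high", "low", "genus", "delta_ogt"])
    return PairSet(pairs, list(pairs["high"]), list(pairs["low"]))


def bonferroni_adjust(p, m: int) -> np.ndarray | float:
    """Family-wise correction: ``min(1, p * m)`` over ``m`` tests."""
    arr = np.minimum(1.0, np.asarray(p, dtype=float) * m)
    return arr if arr.ndim else float(arr)


def fisher_pvalues(table) -> tuple[float, float, float]:
    """(two-sided, less, greater) exact p's for one 2x2 table.

    Two-sided sums hypergeometric outcomes with probability <= that of
    the observed table; ``less``/``greater`` are the lower/upper tails
    for the count in cell (0, 0).
    """
    two = stats.fisher_exact(table, alternative="two-sided").pvalue
    less = stats.fisher_exact(table, alternative="less").pvalue
    greater = stats.fisher_exact(table, alternative="greater").pvalue
    return float(two), float(less), float(greater)


def fisher_screen(
    genes: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-gene Fisher's exact tests of presence between two groups.

    ``group_a`` plays the "high OGT" role and ``group_b`` the "low OGT"
    role: ``p_less`` is the one-sided tail for enrichment in group B and
    ``p_greater`` for enrichment in group A. Presence means copy number
    >= 1. Genes present in every species or absent from every species of
    the union are uninformative: they are skipped and excluded from the
    Bonferroni denominator ``m``.
    """
    a = [s for s in group_a]
    b = [s for s in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    sub_a = (genes.loc[a] >= 1).to_numpy()
    sub_b = (genes.loc[b] >= 1).to_numpy()
    pa = sub_a.sum(axis=0)
    pb = sub_b.sum(axis=0)
    na, nb = len(a), len(b)
    informative = ~(((pa == na) & (pb == nb)) | ((pa == 0) & (pb == 0)))
    m = int(informative.sum())
    rows = []
    for j in np.flatnonzero(informative):
        table = [[int(pa[j]), int(pb[j])], [na - int(pa[j]), nb - int(pb[j])]]
        two, less, greater = fisher_pvalues(table)
        rows.append(
            {
                "gene": genes.columns[j],
                "present_a": table[0][0],
                "absent_a": table[1][0],
                "present_b": table[0][1],
                "absent_b": table[1][1],
                "p": float(two),
                "p_less": float(less),
                "p_greater": float(greater),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "present_a", "absent_a", "present_b", "absent_b",
            "p", "p_less", "p_greater",
        ],
    )
    out["p_bonferroni"] = bonferroni_adjust(out["p"].to_numpy(), m) if m else []
    out["m"] = m
    return out.sort_values(["p", "gene"], ignore_index=True)


def psychrophile_screen(
    genes: pd.DataFrame, ogt: pd.Series, threshold: float = 20.0
) -> pd.DataFrame:
    """Fisher screen of psychrophiles (OGT < 20 °C) against all others."""
    ids = [s for s in genes.index if s in ogt.index]
    psych = [s for s in ids if ogt[s] < threshold]
    rest = [s for s in ids if ogt[s] >= threshold]
    if not psych:
        raise ValueError("no psychrophiles (OGT < threshold) in the data")
    if not rest:
        raise ValueError("no non-psychrophiles in the data")
    if len(psych) == 1:
        warnings.warn("only one psychrophile: the screen has very low power")
    # psychrophiles are the 'low OGT' side: enrichment there is p_less
    return fisher_screen(genes, group_a=rest, group_b=psych)


def select_top_genes(
    result_pairs: pd.DataFrame, result_psych: pd.DataFrame, k: int = 50
) -> list[str]:
    """Top ``k`` genes by raw p from each screen, concatenated and
    de-duplicated (order stable by (p, gene id); final length <= 2k)."""
    out: list[str] = []
    for res in (result_pairs, result_psych):
        if k > len(res):
            raise ValueError("k exceeds the number of genes tested")
        top = res.sort_values(["p", "gene"]).head(k)["gene"]
        out.extend(g for g in top if g not in out)
    return out


def augment_feature_table(
    features: pd.DataFrame,
    genes: pd.DataFrame,
    gene_list: list[str],
    manifest=None,
):
    """Append selected genes' copy numbers as extra feature columns."""
    missing_genes = [g for g in gene_list if g not in genes.columns]
    if missing_genes:
        raise KeyError(f"selected genes absent from the matrix: {missing_genes[:5]}")
    missing_sp = [s for s in features.index if s not in genes.index]
    if missing_sp:
        raise KeyError(f"species absent from the gene matrix: {missing_sp[:5]}")
    cols = genes.loc[features.index, gene_list]
    cols.columns = [f"gene_{g}" for g in gene_list]
    out = pd.concat([features, cols], axis=1)
    if manifest is not None:
        from .features import FeatureManifest

        entries = list(manifest.entries) + [
            (f"gene_{g}", "gene_copy", "gene_matrix") for g in gene_list
        ]
        return out, FeatureManifest(entries)
    return out


def pathway_enrichment(
    selected: list[str],
    gene_pathways: pd.DataFrame,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in a gene list.

    ``gene_pathways`` maps genes to pathways (columns ``gene``,
    ``pathway``). Per pathway the upper-tail hypergeometric p of the
    overlap between the selected set and the pathway members within the
    universe is reported, with Benjamini-Hochberg q-values.
    """
    if gene_pathways.empty:
        raise ValueError("empty gene-to-pathway map")
    uni = set(universe)
    if not set(selected) <= uni:
        raise ValueError("universe must contain every selected gene")
    sel = set(selected)
    M = len(uni)
    N = len(sel)
    rows = []
    for pw, grp in gene_pathways.groupby("pathway"):
        members = set(grp["gene"]) & uni
        if not members:
            continue
        n = len(members)
        k = len(members & sel)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {"pathway": pw, "pathway_size": n, "overlap": k, "p": p}
        )
    out = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out.sort_values(["p", "pathway"], ignore_index=True)
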