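"""Synthetic genomes, trees and trait histories for OGT-lag analyses.

The generator emulates the statistical structure the downstream analysis
assumes about real prokaryotic data:

* optimal growth temperature (OGT) evolves on a Yule tree by Brownian
  motion punctuated by rare large jumps (recent habitat shifts);
* genome composition tracks a *lagged* (exponentially smoothed along the
  lineage) OGT, so recently shifted species are composition-discordant;
* a start-codon-proximal guanine depletion responds to *current* OGT
  below 20 °C (a fast-adapting feature);
* ortholog gain/loss rates can couple to the sign of OGT change on a
  branch, planting genes whose presence tracks temperature shifts;
* OGT databases are mesophile-heavy with spurious records at conventional
  incubation temperatures (25/28/30/37 °C).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .tree import Phylogeny

__all__ = [
    "SimConfig",
    "TraitHistory",
    "GenomeBundle",
    "simulate_tree",
    "simulate_ogt",
    "simulate_genomes",
    "simulate_gene_content",
    "simulate_ogt_sources",
    "lagged_ogt",
    "true_dogt",
]

RANKS = ("phylum", "class", "order", "family", "genus")

#: Depth cuts (as fractions of tree height, measured from the root) at
#: which the tree is sliced to define nested taxonomic ranks.
DEFAULT_RANK_FRACTIONS = {
    "phylum": 0.25,
    "class": 0.40,
    "order": 0.55,
    "family": 0.65,
    "genus": 0.72,
}

OGT_MIN, OGT_MAX = 0.0, 105.0
CONVENTIONAL_TEMPERATURES = (25.0, 28.0, 30.0, 37.0)


class InvalidConfigError(ValueError):
    pass


class InconsistentInputError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults are the standard study conditions used across the analysis:
    200 species, Brownian scale 5 °C per sqrt(branch length), ±15 °C
    jumps on 5 % of branches, composition lag half-life of one
    branch-length unit, and 500 orthologs of which 20 couple strongly to
    OGT shifts against a slow baseline turnover (roughly four gain/loss
    events per gene across the tree).
    """

    n_tips: int = 200
    birth_rate: float = 1.0
    seed: int = 0
    bm_sigma: float = 5.0
    jump_prob: float = 0.05
    jump_scale: float = 15.0
    lag_halflife: float = 1.0
    n_genes: int = 500
    gain_rate: float = 0.02
    loss_rate: float = 0.02
    coupling: float = 4.0
    genome_size: int = 60
    # --- secondary knobs -------------------------------------------------
    root_mean: float = 30.0
    root_sd: float = 3.0
    jump_negative_prob: float = 0.5  # 0.8+ mimics a psychrophile-biased regime
    n_coupled_warm: int = 10
    n_coupled_cold: int = 10
    duplication_prob: float = 0.05
    cds_mean_codons: int = 150
    cds_sigma_log: float = 0.25
    cds_min_codons: int = 70
    cds_max_codons: int = 400
    rrna_lengths: dict = field(
        default_factory=lambda: {"5s": 110, "16s": 150, "23s": 200}
    )
    trna_length: int = 76
    rank_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_RANK_FRACTIONS)
    )

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise InvalidConfigError("n_tips must be at least 3")
        if not 0.0 <= self.jump_prob <= 1.0:
            raise InvalidConfigError("jump_prob must lie in [0, 1]")
        for name in (
            "birth_rate",
            "bm_sigma",
            "jump_scale",
            "lag_halflife",
            "gain_rate",
            "loss_rate",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.n_coupled_warm + self.n_coupled_cold > self.n_genes:
            raise InvalidConfigError("more coupled genes than genes")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TraitHistory:
    """True OGT at every node plus the branches that carry jumps."""

    tip_values: dict[str, float]
    node_values: dict[int, float]
    jump_branches: dict[int, float]  # child node id -> jump magnitude (°C)
    clipped_nodes: list[int] = field(default_factory=list)

    def all_values(self, tree: Phylogeny) -> np.ndarray:
        vals = np.empty(tree.n_nodes)
        for lab, i in tree.tip_index.items():
            vals[i] = self.tip_values[lab]
        for node, v in self.node_values.items():
            vals[node] = v
        return vals


@dataclass
class GenomeBundle:
    """One species' annotated genome: CDSs plus structural RNAs."""

    species_id: str
    cds: list[str]
    trna: str | None
    rrna: dict[str, str]  # keys "5s", "16s", "23s"


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


# --------------------------------------------------------------------- #
#  Tree + taxonomy
# --------------------------------------------------------------------- #
def simulate_tree(config: SimConfig) -> tuple[Phylogeny, pd.DataFrame]:
    """Simulate a Yule tree and derive a nested taxonomy from depth cuts.

    Returns the tree (tips ``S0001 ..``) and a taxonomy table with one
    row per species and one column per rank. Taxa are defined by slicing
    the ultrametric tree at fixed fractions of its height, so the
    taxonomy is nested and exactly consistent with the topology.
    """
    rng = _rng(config, 0)
    lam = config.birth_rate
    # grow: each active lineage is (parent_temp_id, birth_time)
    nodes: list[tuple[int, float]] = [(-1, 0.0)]  # temp id 0 = root
    active: list[int] = []
    t = 0.0
    for child in (1, 2):
        nodes.append((0, 0.0))
        active.append(child)
    while len(active) < config.n_tips:
        t += rng.exponential(1.0 / (lam * len(active)))
        u = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            nodes.append((u, t))
            active.append(len(nodes) - 1)
    t_end = t + rng.exponential(1.0 / (lam * len(active)))

    n = config.n_tips
    leaf_order = sorted(active)
    new_id = {tmp: i for i, tmp in enumerate(leaf_order)}
    internals = [i for i in range(len(nodes)) if i not in new_id]
    for k, tmp in enumerate(internals):
        new_id[tmp] = n + k
    size = len(nodes)
    parent = np.full(size, -1, dtype=np.int64)
    lengths = np.zeros(size)
    birth = np.zeros(size)
    for tmp, (par, t0) in enumerate(nodes):
        i = new_id[tmp]
        birth[i] = t0
        if par >= 0:
            parent[i] = new_id[par]
    # a node's branch ends at the birth time of its children, or at t_end
    # for extant tips
    end_time = np.full(size, t_end)
    for i in range(size):
        p = parent[i]
        if p >= 0:
            end_time[p] = birth[i]
    lengths = end_time - birth
    lengths[parent < 0] = 0.0

    tip_labels = [f"S{i + 1:04d}" for i in range(n)]
    tree = Phylogeny(parent, lengths, tip_labels)
    taxonomy = _taxonomy_from_cuts(tree, config.rank_fractions)
    return tree, taxonomy


def _taxonomy_from_cuts(
    tree: Phylogeny, fractions: dict[str, float]
) -> pd.DataFrame:
    depth = tree.depths()
    height = depth[: tree.n_tips].max()
    prefix = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}
    rows: dict[str, dict[str, str]] = {lab: {} for lab in tree.tip_labels}
    for rank in RANKS:
        cut = fractions[rank] * height
        group_of: dict[int, int] = {}
        counter = itertools.count(1)
        names: dict[int, str] = {}
        for tip in range(tree.n_tips):
            node = tip
            while tree.parent[node] >= 0 and depth[tree.parent[node]] >= cut:
                node = int(tree.parent[node])
            if node not in names:
                names[node] = f"{prefix[rank]}{next(counter):03d}"
            group_of[tip] = node
            rows[tree.tip_labels[tip]][rank] = names[node]
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species_id"
    return df.reset_index()


# --------------------------------------------------------------------- #
#  OGT history
# --------------------------------------------------------------------- #
def simulate_ogt(tree: Phylogeny, config: SimConfig) -> TraitHistory:
    """Evolve OGT by Brownian motion plus rare jumps along the tree."""
    rng = _rng(config, 1)
    vals = np.empty(tree.n_nodes)
    vals[tree.root] = rng.normal(config.root_mean, config.root_sd)
    jumps: dict[int, float] = {}
    clipped: list[int] = []
    for node in tree.preorder:
        p = int(tree.parent[node])
        if p < 0:
            continue
        ln = tree.lengths[node]
        step = rng.normal(0.0, config.bm_sigma * np.sqrt(ln))
        if rng.random() < config.jump_prob:
            mag = abs(rng.normal(config.jump_scale, config.jump_scale / 4.0))
            sign = -1.0 if rng.random() < config.jump_negative_prob else 1.0
            jumps[int(node)] = sign * mag
            step += sign * mag
        v = vals[p] + step
        if v < OGT_MIN or v > OGT_MAX:
            clipped.append(int(node))
            v = float(np.clip(v, OGT_MIN, OGT_MAX))
        vals[node] = v
    tips = {lab: float(vals[i]) for lab, i in zip(tree.tip_labels, range(tree.n_tips))}
    internal = {int(i): float(vals[i]) for i in range(tree.n_tips, tree.n_nodes)}
    return TraitHistory(tips, internal, jumps, clipped)


def lagged_ogt(
    tree: Phylogeny, history: TraitHistory, halflife: float
) -> dict[str, float]:
    """Exponentially smoothed OGT along each root-to-tip lineage.

    Per branch of length ``len`` the lagged value closes a fraction
    ``1 - 2**(-len/halflife)`` of its gap to the true end-of-branch OGT.
    ``halflife -> 0`` recovers the current OGT exactly.
    """
    vals = history.all_values(tree)
    lag = np.empty(tree.n_nodes)
    lag[tree.root] = vals[tree.root]
    for node in tree.preorder:
        p = int(tree.parent[node])
        if p < 0:
            continue
        if halflife <= 0:
            w = 1.0
        else:
            w = 1.0 - 2.0 ** (-tree.lengths[node] / halflife)
        lag[node] = lag[p] + w * (vals[node] - lag[p])
    return {lab: float(lag[i]) for lab, i in tree.tip_index.items()}


# --------------------------------------------------------------------- #
#  Genomes
# --------------------------------------------------------------------- #
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
STOP_CODONS = set(_CODON_TABLE.stop_codons)
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]
AA_OF = {c: _CODON_TABLE.forward_table[c] for c in SENSE_CODONS}
AMINO_ACIDS = sorted(set(AA_OF.values()))
IVYWREL = set("IVYWREL")


def _codon_betas() -> np.ndarray:
    """Per-codon log-linear sensitivities to (scaled) OGT.

    GC-rich codons and codons for the IVYWREL residues become more likely
    at high OGT; codons for small polar residues less likely. These fixed
    constants define the monotone composition→temperature map that the
    downstream regression is expected to learn.
    """
    betas = np.empty(len(SENSE_CODONS))
    for k, codon in enumerate(SENSE_CODONS):
        gc = sum(b in "GC" for b in codon) / 3.0
        aa = AA_OF[codon]
        betas[k] = (
            1.5 * (gc - 0.5)
            + 0.7 * (aa in IVYWREL)
            - 0.35 * (aa in set("NQTSH"))
        )
    return betas


_BETAS = _codon_betas()


def _codon_probs(z: float) -> np.ndarray:
    w = np.exp(_BETAS * (z - 30.0) / 40.0)
    return w / w.sum()


def _gc_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with an exact (rounded) GC count."""
    n_gc = int(round(length * gc))
    n_at = length - n_gc
    chars = (
        ["G"] * (n_gc // 2 + n_gc % 2)
        + ["C"] * (n_gc // 2)
        + ["A"] * (n_at // 2 + n_at % 2)
        + ["T"] * (n_at // 2)
    )
    arr = np.array(chars)
    rng.shuffle(arr)
    return "".join(arr)


def _rna_gc_target(z: float) -> float:
    # monotone map from lagged OGT to structural-RNA GC fraction
    return 0.30 + 0.50 * float(np.clip(z, OGT_MIN, OGT_MAX)) / OGT_MAX


def simulate_genomes(
    tree: Phylogeny, history: TraitHistory, config: SimConfig
) -> tuple[dict[str, GenomeBundle], pd.DataFrame]:
    """Emit per-species genome bundles whose composition tracks lagged OGT.

    Returns the bundles plus a ground-truth table with current and lagged
    OGT per species.
    """
    missing = [lab for lab in tree.tip_labels if lab not in history.tip_values]
    if missing:
        raise InconsistentInputError(
            f"history lacks OGT for tips: {missing[:5]}"
        )
    rng = _rng(config, 2)
    lag = lagged_ogt(tree, history, config.lag_halflife)
    codon_arr = np.array(SENSE_CODONS)
    bundles: dict[str, GenomeBundle] = {}
    truth_rows = []
    for lab in tree.tip_labels:
        ogt = history.tip_values[lab]
        z = lag[lab]
        probs = _codon_probs(z)
        lens = rng.lognormal(
            np.log(config.cds_mean_codons), config.cds_sigma_log, config.genome_size
        )
        lens = np.clip(np.round(lens), config.cds_min_codons, config.cds_max_codons)
        lens = lens.astype(int)
        total = int(lens.sum())
        draw = rng.choice(len(codon_arr), size=total, p=probs)
        codons = codon_arr[draw]
        genes: list[str] = []
        pos = 0
        deplete = 0.45 * max(0.0, (20.0 - ogt)) / 20.0
        for L in lens:
            g = codons[pos : pos + L].copy()
            pos += L
            g[0] = "ATG"
            seq = "".join(g)
            if deplete > 0:
                head = list(seq[3:33])
                mask = rng.random(len(head)) < deplete
                head = [
                    "A" if (m and b == "G") else b for b, m in zip(head, mask)
                ]
                seq = seq[:3] + "".join(head) + seq[33:]
            genes.append(seq)
        gc = _rna_gc_target(z)
        rrna = {
            name: _gc_sequence(length, gc, rng)
            for name, length in config.rrna_lengths.items()
        }
        trna = _gc_sequence(config.trna_length, gc, rng)
        bundles[lab] = GenomeBundle(lab, genes, trna, rrna)
        truth_rows.append({"species_id": lab, "ogt": ogt, "ogt_lagged": z})
    truth = pd.DataFrame(truth_rows)
    return bundles, truth


# --------------------------------------------------------------------- #
#  Gene content
# --------------------------------------------------------------------- #
def simulate_gene_content(
    tree: Phylogeny, history: TraitHistory, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Evolve ortholog presence/absence with optional OGT coupling.

    Returns ``(matrix, events, gene_info)``: a species × gene copy-number
    table, the true per-branch gain/loss event list, and a table tagging
    each gene's coupling mode (``warm`` genes are gained on warming and
    lost on cooling branches, ``cold`` genes the reverse).
    """
    rng = _rng(config, 3)
    G = config.n_genes
    gene_ids = [f"G{i + 1:04d}" for i in range(G)]
    mode = np.array(
        ["warm"] * config.n_coupled_warm
        + ["cold"] * config.n_coupled_cold
        + ["none"] * (G - config.n_coupled_warm - config.n_coupled_cold)
    )
    vals = history.all_values(tree)
    gain, loss = config.gain_rate, config.loss_rate
    p_root = 0.5 if gain + loss == 0 else gain / (gain + loss)
    state = np.zeros((tree.n_nodes, G), dtype=np.int8)
    state[tree.root] = (rng.random(G) < p_root).astype(np.int8)
    events: list[dict] = []
    warm = mode == "warm"
    cold = mode == "cold"
    for node in tree.preorder:
        p = int(tree.parent[node])
        if p < 0:
            continue
        ln = tree.lengths[node]
        d = vals[node] - vals[p]
        up = np.exp(config.coupling * max(0.0, d) / 10.0)
        dn = np.exp(config.coupling * max(0.0, -d) / 10.0)
        m_gain = np.ones(G)
        m_loss = np.ones(G)
        m_gain[warm] = up
        m_loss[warm] = dn
        m_gain[cold] = dn
        m_loss[cold] = up
        # exact 2-state chain with branch-constant rates: net transition
        # probabilities (multiple hidden events collapse to one flip)
        g_eff = gain * m_gain
        l_eff = loss * m_loss
        s_eff = g_eff + l_eff
        with np.errstate(divide="ignore", invalid="ignore"):
            decay = np.where(s_eff > 0, 1.0 - np.exp(-s_eff * ln), 0.0)
            p_gain = np.where(s_eff > 0, g_eff / np.maximum(s_eff, 1e-300), 0.0) * decay
            p_loss = np.where(s_eff > 0, l_eff / np.maximum(s_eff, 1e-300), 0.0) * decay
        u = rng.random(G)
        prev = state[p]
        flip = np.where(prev == 1, u < p_loss, u < p_gain)
        state[node] = np.where(flip, 1 - prev, prev)
        for g in np.flatnonzero(flip):
            events.append(
                {
                    "gene": gene_ids[g],
                    "node": int(node),
                    "event": "loss" if prev[g] == 1 else "gain",
                    "delta_ogt": float(d),
                }
            )
    copy = state[: tree.n_tips].astype(np.int64)
    dup = (rng.random(copy.shape) < config.duplication_prob) & (copy == 1)
    copy = copy + dup.astype(np.int64)
    matrix = pd.DataFrame(copy, index=tree.tip_labels, columns=gene_ids)
    matrix.index.name = "species_id"
    events_df = pd.DataFrame(
        events, columns=["gene", "node", "event", "delta_ogt"]
    )
    gene_info = pd.DataFrame({"gene": gene_ids, "coupling_mode": mode})
    return matrix, events_df, gene_info


def true_dogt(
    tree: Phylogeny,
    history: TraitHistory,
    taxonomy: pd.DataFrame,
    rank: str = "genus",
) -> pd.Series:
    """Ground-truth OGT change of each species from its rank ancestor.

    Uses the *simulated* ancestral value at the MRCA of the species'
    clade (no reconstruction), for validating dOGT estimators.
    """
    vals = history.all_values(tree)
    tax = taxonomy.set_index("species_id")[rank]
    out = {}
    for taxon, members in tax.groupby(tax).groups.items():
        tips = [tree.tip_index[m] for m in members]
        node = tree.mrca(tips)
        for m in members:
            out[m] = history.tip_values[m] - float(vals[node])
    return pd.Series(out, name="true_dogt").loc[tree.tip_labels]


# --------------------------------------------------------------------- #
#  OGT databases with curation artifacts
# --------------------------------------------------------------------- #
def simulate_ogt_sources(
    tree: Phylogeny,
    history: TraitHistory,
    config: SimConfig,
    n_sources: int = 3,
    coverage: float = 0.85,
    noise_sd: float = 0.5,
    artifact_prob: float = 0.10,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Emulate noisy OGT databases plus genome-quality metadata.

    Each source covers a random subset of species, reports OGT with small
    measurement noise, and replaces a fraction of records with one of the
    conventional incubation temperatures (25/28/30/37 °C) to mimic
    hand-curated database artifacts. The metadata table carries
    completeness and contamination for quality filtering.
    """
    rng = _rng(config, 4)
    sources = []
    for _ in range(n_sources):
        rows = []
        for lab in tree.tip_labels:
            if rng.random() > coverage:
                continue
            if rng.random() < artifact_prob:
                val = float(rng.choice(CONVENTIONAL_TEMPERATURES))
            else:
                val = round(history.tip_values[lab] + rng.normal(0, noise_sd), 1)
            rows.append({"species_id": lab, "ogt": val})
        sources.append(pd.DataFrame(rows))
    meta = pd.DataFrame(
        {
            "species_id": tree.tip_labels,
            "completeness": np.round(100.0 - rng.exponential(1.5, tree.n_tips), 2),
            "contamination": np.round(rng.exponential(1.5, tree.n_tips), 2),
        }
    )
    meta["completeness"] = meta["completeness"].clip(0, 100)
    meta["contamination"] = meta["contamination"].clip(0, 100)
    return sources, meta
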