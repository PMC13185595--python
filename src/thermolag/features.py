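"""Genome-composition features for OGT regression.

Per species the default inventory covers genome-wide base / codon /
amino-acid / amino-acid-2-mer composition, the IVYWREL sum, structural
RNA base composition and per-length folding energy (tRNA, 5S/16S/23S
rRNA), and 21 start-codon-proximal features: one guanine feature and one
per amino acid, each expressed as ``log2(F_i / F_rep)`` of a
position-specific composition against a representative value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .folding import fold_energy
from .synthetic import AA_OF, AMINO_ACIDS, CODONS, GenomeBundle, IVYWREL, STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureManifest",
    "StartRegionProfile",
    "composition_features",
    "start_region_profile",
    "start_region_features",
    "build_feature_table",
    "minmax_normalize",
    "default_manifest",
]

BASES = ("A", "C", "G", "T")
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_CODON_AA = np.full(64, -1, dtype=np.int64)
for _c, _aa in AA_OF.items():
    i = _CODE[ord(_c[0])] * 16 + _CODE[ord(_c[1])] * 4 + _CODE[ord(_c[2])]
    _CODON_AA[i] = _AA_INDEX[_aa]
_STOP_IDX = {
    _CODE[ord(c[0])] * 16 + _CODE[ord(c[1])] * 4 + _CODE[ord(c[2])]
    for c in STOP_CODONS
}
START_CODONS = {"ATG", "GTG", "TTG"}
_IVYWREL_IDX = np.array([_AA_INDEX[a] for a in sorted(IVYWREL)])


class EmptyInputError(ValueError):
    pass


class MissingProfileError(ValueError):
    pass


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _gene_arrays(seq: str) -> tuple[np.ndarray, np.ndarray] | None:
    """Codon indices and amino-acid indices of one CDS, or None if skipped.

    Genes whose length is not a multiple of 3 are skipped. Ambiguous
    codons are dropped; alternative starts (GTG/TTG) translate as M while
    counting as their literal codon.
    """
    if len(seq) % 3 != 0 or len(seq) == 0:
        return None
    codes = _codes(seq)
    tri = codes.reshape(-1, 3)
    ok = (tri >= 0).all(axis=1)
    cidx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    cidx = np.where(ok, cidx, -1)
    aa = np.where(cidx >= 0, _CODON_AA[cidx], -1)
    if cidx[0] >= 0 and seq[:3].upper() in START_CODONS:
        aa[0] = _AA_INDEX["M"]
    return cidx, aa


# --------------------------------------------------------------------- #
#  Whole-genome composition
# --------------------------------------------------------------------- #
def composition_features(cds_set: list[str]) -> dict[str, float]:
    """Base, codon, amino-acid, 2-mer and IVYWREL fractions of a CDS set.

    Codon fractions are computed over sense codons (stop-codon columns
    are emitted as 0), so each fraction family sums to 1.
    """
    if not cds_set:
        raise EmptyInputError("empty CDS set")
    base_counts = np.zeros(4, dtype=np.int64)
    codon_counts = np.zeros(64, dtype=np.int64)
    aa_counts = np.zeros(20, dtype=np.int64)
    mer_counts = np.zeros(400, dtype=np.int64)
    n_skipped = 0
    for seq in cds_set:
        arrays = _gene_arrays(seq)
        if arrays is None:
            n_skipped += 1
            continue
        cidx, aa = arrays
        codes = _codes(seq)
        base_counts += np.bincount(codes[codes >= 0], minlength=4)[:4]
        valid = cidx[cidx >= 0]
        codon_counts += np.bincount(valid, minlength=64)
        aas = aa[aa >= 0]
        aa_counts += np.bincount(aas, minlength=20)
        if aas.size >= 2:
            mer_counts += np.bincount(aas[:-1] * 20 + aas[1:], minlength=400)
    if n_skipped:
        logger.info("composition_features: skipped %d non-conforming genes", n_skipped)
    if base_counts.sum() == 0:
        raise EmptyInputError("no unambiguous sequence content in CDS set")
    out: dict[str, float] = {}
    bf = base_counts / base_counts.sum()
    for b, v in zip(BASES, bf):
        out[f"base_{b}"] = float(v)
    out["gc"] = float(bf[1] + bf[2])
    for i in _STOP_IDX:
        codon_counts[i] = 0
    ctot = codon_counts.sum()
    if ctot == 0:
        raise EmptyInputError("no sense codons in CDS set")
    for i, codon in enumerate(CODONS):
        out[f"codon_{codon}"] = float(codon_counts[i] / ctot)
    af = aa_counts / aa_counts.sum()
    for a, v in zip(AMINO_ACIDS, af):
        out[f"aa_{a}"] = float(v)
    mtot = mer_counts.sum()
    mf = mer_counts / mtot if mtot else mer_counts.astype(float)
    k = 0
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            out[f"aa2_{a}{b}"] = float(mf[k])
            k += 1
    out["ivywrel"] = float(af[_IVYWREL_IDX].sum())
    return out


# --------------------------------------------------------------------- #
#  Start-codon-proximal profile
# --------------------------------------------------------------------- #
@dataclass
class StartRegionProfile:
    """Position-specific composition near the start codon.

    Base positions are 1-based counting from the first nucleotide after
    the start codon; ``F_i`` averages a 10-nt window ``i .. i+9`` across
    genes, and the base representative is ``F_50``. Amino-acid positions
    1-4 count from the first residue after the initiator, with the
    full-length mean composition as representative.
    """

    base_f: pd.DataFrame
    base_rep: pd.Series
    base_norm: pd.DataFrame
    aa_f: pd.DataFrame
    aa_rep: pd.Series
    aa_norm: pd.DataFrame
    n_genes_base: int
    n_genes_aa: int
    missing: list[tuple[str, object, str]] = field(default_factory=list)


def start_region_profile(
    cds_set: list[str],
    max_pos: int = 50,
    window: int = 10,
    aa_positions: int = 4,
    pseudocount: float = 0.0,
) -> StartRegionProfile:
    """Compute ``F_i`` / ``F_rep`` / ``log2(F_i/F_rep)`` near start codons.

    Genes shorter than ``max_pos + window - 1`` nt after the start codon
    (base windows) or than 60 codons (amino-acid positions) are excluded
    and counted. A small ``pseudocount`` can stabilize rare categories;
    entries whose representative value is 0 (or whose F is 0) are flagged
    missing rather than silently zeroed.
    """
    if not cds_set:
        raise EmptyInputError("empty CDS set")
    span = max_pos + window - 1
    heads = []
    aa_heads = []
    aa_totals = np.zeros(20, dtype=np.int64)
    n_short_base = n_short_aa = 0
    for seq in cds_set:
        arrays = _gene_arrays(seq)
        if arrays is None:
            continue
        _, aa = arrays
        body = _codes(seq)[3:]
        if body.size >= span:
            heads.append(body[:span])
        else:
            n_short_base += 1
        res = aa[1:]  # residues after the initiator
        res = res[res >= 0]
        if aa.size >= 60:
            if res.size >= aa_positions:
                aa_heads.append(res[:aa_positions])
                aa_totals += np.bincount(res, minlength=20)
        else:
            n_short_aa += 1
    if n_short_base or n_short_aa:
        logger.info(
            "start_region_profile: excluded %d genes (base windows), %d (aa)",
            n_short_base,
            n_short_aa,
        )
    if not heads or not aa_heads:
        raise EmptyInputError("no gene long enough for the start-region profile")

    H = np.stack(heads)  # genes x span
    counts = np.zeros((max_pos, 4), dtype=np.int64)
    for b in range(4):
        ind = (H == b).astype(np.int64)
        csum = np.concatenate(
            [np.zeros((ind.shape[0], 1), dtype=np.int64), np.cumsum(ind, axis=1)],
            axis=1,
        )
        # window starting at 1-based position i covers columns i-1 .. i+8
        counts[:, b] = (csum[:, window:] - csum[:, :-window]).sum(axis=0)[:max_pos]
    denom = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    base_f = pd.DataFrame(
        (counts + pseudocount) / denom,
        index=pd.RangeIndex(1, max_pos + 1, name="position"),
        columns=list(BASES),
    )
    base_rep = base_f.loc[max_pos].rename("F_rep")

    A = np.stack(aa_heads)  # genes x aa_positions
    aa_counts = np.zeros((aa_positions, 20), dtype=np.int64)
    for p in range(aa_positions):
        aa_counts[p] = np.bincount(A[:, p], minlength=20)
    aa_f = pd.DataFrame(
        (aa_counts + pseudocount) / (A.shape[0] + 20 * pseudocount),
        index=pd.RangeIndex(1, aa_positions + 1, name="position"),
        columns=AMINO_ACIDS,
    )
    aa_rep = pd.Series(
        (aa_totals + pseudocount) / (aa_totals.sum() + 20 * pseudocount),
        index=AMINO_ACIDS,
        name="F_rep",
    )

    missing: list[tuple[str, object, str]] = []

    def _norm(f: pd.DataFrame, rep: pd.Series, tag: str) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(f / rep)
        bad = ~np.isfinite(out)
        for pos, col in zip(*np.where(bad.to_numpy())):
            missing.append((tag, f.index[pos], f.columns[col]))
        return out.mask(bad)

    base_norm = _norm(base_f, base_rep, "base")
    aa_norm = _norm(aa_f, aa_rep, "aa")
    return StartRegionProfile(
        base_f, base_rep, base_norm, aa_f, aa_rep, aa_norm,
        len(heads), len(aa_heads), missing,
    )


def start_region_features(
    profile: StartRegionProfile, guanine_position: int = 5
) -> dict[str, float]:
    """21 model features: guanine ``F_norm`` at position 5 and, per amino
    acid, the mean ``F_norm`` over residue positions 1-4."""
    g = profile.base_norm.loc[guanine_position, "G"]
    aa_mean = profile.aa_norm.mean(axis=0)
    bad = []
    if not np.isfinite(g):
        bad.append(("base", guanine_position, "G"))
    for tag, pos, col in profile.missing:
        if tag == "aa":
            bad.append((tag, pos, col))
    if bad:
        raise MissingProfileError(f"undefined profile entries at: {bad}")
    out = {"start_G": float(g)}
    for a in AMINO_ACIDS:
        out[f"start_aa_{a}"] = float(aa_mean[a])
    return out


# --------------------------------------------------------------------- #
#  Manifest and table assembly
# --------------------------------------------------------------------- #
@dataclass
class FeatureManifest:
    """Ordered feature inventory: (name, recipe tag, source) triples."""

    entries: list[tuple[str, str, str]]
    normalized: bool = False
    ref_min: pd.Series | None = None
    ref_max: pd.Series | None = None

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def sources(self) -> set[str]:
        return {e[2] for e in self.entries}


def default_manifest(rrnas: tuple[str, ...] = ("5s", "16s", "23s")) -> FeatureManifest:
    """The 531-entry default inventory (configurable, asserted in tests)."""
    entries: list[tuple[str, str, str]] = []
    for b in BASES:
        entries.append((f"base_{b}", "base_fraction", "cds"))
    entries.append(("gc", "gc", "cds"))
    for c in CODONS:
        entries.append((f"codon_{c}", "codon", "cds"))
    for a in AMINO_ACIDS:
        entries.append((f"aa_{a}", "aa", "cds"))
    for a, b in itertools.product(AMINO_ACIDS, AMINO_ACIDS):
        entries.append((f"aa2_{a}{b}", "aa2mer", "cds"))
    entries.append(("ivywrel", "ivywrel", "cds"))
    for b in BASES:
        entries.append((f"trna_base_{b}", "base_fraction", "trna"))
    entries.append(("trna_energy", "energy_per_nt", "trna"))
    for r in rrnas:
        for b in BASES:
            entries.append((f"rrna_{r}_base_{b}", "base_fraction", f"rrna_{r}"))
        entries.append((f"rrna_{r}_energy", "energy_per_nt", f"rrna_{r}"))
    entries.append(("start_G", "start_guanine", "start_region"))
    for a in AMINO_ACIDS:
        entries.append((f"start_aa_{a}", "start_aa", "start_region"))
    return FeatureManifest(entries)


def _as_list(x) -> list[str]:
    if x is None:
        return []
    if isinstance(x, str):
        return [x]
    return list(x)


def _rna_features(seqs: list[str], prefix: str, engine: str, external_cmd) -> dict:
    """Base fractions and per-length energy, averaged across copies."""
    fracs = np.zeros(4)
    energies = []
    for s in seqs:
        codes = _codes(s)
        c = np.bincount(codes[codes >= 0], minlength=4)[:4]
        fracs += c / c.sum()
        energies.append(
            fold_energy(s, engine=engine, external_cmd=external_cmd) / len(s)
        )
    fracs /= len(seqs)
    out = {f"{prefix}_base_{b}": float(v) for b, v in zip(BASES, fracs)}
    out[f"{prefix}_energy"] = float(np.mean(energies))
    return out


def build_feature_table(
    bundles: dict[str, GenomeBundle],
    manifest: FeatureManifest | None = None,
    engine: str = "builtin",
    pseudocount: float = 0.0,
    external_cmd: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the species × feature matrix in manifest order.

    Species missing a tRNA/rRNA source the manifest requires are dropped
    with a reason; the drop log is returned alongside the table.
    """
    manifest = manifest or default_manifest()
    needed = manifest.sources()
    rows: dict[str, dict[str, float]] = {}
    dropped: list[dict[str, str]] = []
    for sid, bundle in bundles.items():
        try:
            feats: dict[str, float] = {}
            if not bundle.cds:
                raise EmptyInputError("no CDS")
            if "cds" in needed:
                feats.update(composition_features(bundle.cds))
            if "trna" in needed:
                seqs = _as_list(bundle.trna)
                if not seqs:
                    dropped.append({"species_id": sid, "reason": "missing trna"})
                    continue
                feats.update(_rna_features(seqs, "trna", engine, external_cmd))
            ok = True
            for key in needed:
                if key.startswith("rrna_"):
                    r = key[5:]
                    seqs = _as_list((bundle.rrna or {}).get(r))
                    if not seqs:
                        dropped.append(
                            {"species_id": sid, "reason": f"missing {r} rRNA"}
                        )
                        ok = False
                        break
                    feats.update(
                        _rna_features(seqs, f"rrna_{r}", engine, external_cmd)
                    )
            if not ok:
                continue
            if "start_region" in needed:
                profile = start_region_profile(bundle.cds, pseudocount=pseudocount)
                feats.update(start_region_features(profile))
            rows[sid] = feats
        except (EmptyInputError, MissingProfileError) as exc:
            dropped.append({"species_id": sid, "reason": str(exc)})
    if not rows:
        raise EmptyInputError("no species retained in the feature table")
    table = pd.DataFrame.from_dict(rows, orient="index")[manifest.names]
    table.index.name = "species_id"
    drop_log = pd.DataFrame(dropped, columns=["species_id", "reason"])
    return table, drop_log


def minmax_normalize(
    table: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Map each feature linearly so the reference min -> 0 and max -> 1.

    The reference defaults to the table itself; for a held-out fold it
    must be the training table only. Constant reference features map to
    0, and out-of-range values are not clipped.
    """
    ref = reference if reference is not None else table
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    out = (table - lo).div(span.where(span != 0, 1.0), axis=1)
    constant = span.index[span == 0]
    out[constant] = 0.0
    return out, (lo, hi)
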