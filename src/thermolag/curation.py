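"""OGT-table curation: source merging, quality filtering, downsampling.

OGT records equal to a conventional laboratory incubation temperature
(25/28/30/37 °C) are treated as database artifacts and removed per
source before cross-source averaging. Genomes must pass completeness
> 95 % and contamination < 5 % (strict). Mesophiles (20 <= OGT < 40 °C)
are downsampled to one species per genus, keeping the genome with the
highest quality score Q = completeness - 5 x contamination.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .synthetic import CONVENTIONAL_TEMPERATURES

logger = logging.getLogger(__name__)

__all__ = [
    "merge_ogt_sources",
    "quality_filter",
    "downsample_mesophiles",
    "quality_score",
    "thermal_class",
    "normalize_species_name",
]

MESO_LO, MESO_HI = 20.0, 40.0


def thermal_class(ogt) -> np.ndarray | str:
    """psychrophile (< 20), mesophile (20-40), other (40-60), thermophile (>= 60)."""
    arr = np.asarray(ogt, dtype=float)
    out = np.where(
        arr < 20.0,
        "psychrophile",
        np.where(arr < 40.0, "mesophile", np.where(arr < 60.0, "other", "thermophile")),
    )
    return out if arr.ndim else str(out)


def quality_score(completeness, contamination):
    return np.asarray(completeness, float) - 5.0 * np.asarray(contamination, float)


def normalize_species_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def merge_ogt_sources(
    tables: list[pd.DataFrame],
    conventional: tuple[float, ...] = CONVENTIONAL_TEMPERATURES,
) -> pd.DataFrame:
    """Merge per-source OGT tables into one species -> OGT table.

    Within each source, records whose OGT equals a conventional
    incubation temperature (compared at 0.1 °C resolution) are removed;
    surviving values for the same species are arithmetic-averaged across
    sources. Species names are matched after whitespace/case
    normalization.
    """
    if not tables:
        raise ValueError("at least one OGT source is required")
    excl = {round(t, 1) for t in conventional}
    kept = []
    for k, tab in enumerate(tables):
        t = tab[["species_id", "ogt"]].copy()
        # species are matched on a normalized key; the original spelling
        # of the first occurrence is reported
        t["_key"] = t["species_id"].map(normalize_species_name)
        mask = t["ogt"].round(1).isin(excl)
        if mask.any():
            logger.info(
                "merge_ogt_sources: source %d drops %d conventional-temperature records",
                k,
                int(mask.sum()),
            )
        kept.append(t[~mask])
    allrec = pd.concat(kept, ignore_index=True)
    if allrec.empty:
        warnings.warn("no OGT records survive the conventional-temperature exclusion")
        return pd.DataFrame(columns=["species_id", "ogt"])
    out = allrec.groupby("_key", as_index=False).agg(
        species_id=("species_id", "first"), ogt=("ogt", "mean")
    )
    return out[["species_id", "ogt"]].sort_values("species_id", ignore_index=True)


def quality_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records with completeness > 95 and contamination < 5 (strict)."""
    mask = (records["completeness"] > 95.0) & (records["contamination"] < 5.0)
    return records[mask].reset_index(drop=True)


def downsample_mesophiles(records: pd.DataFrame) -> pd.DataFrame:
    """One mesophile per genus: the highest-Q genome, ties by species_id.

    Species outside [20, 40) °C are always kept, so no psychrophile or
    thermophile is ever removed. Idempotent.
    """
    rec = records.copy()
    if "genus" not in rec.columns:
        raise ValueError("taxonomy must include a genus column")
    q = quality_score(rec["completeness"], rec["contamination"])
    rec["_q"] = q
    meso = (rec["ogt"] >= MESO_LO) & (rec["ogt"] < MESO_HI)
    keep_always = rec[~meso]
    pick = (
        rec[meso]
        .sort_values(["_q", "species_id"], ascending=[False, True])
        .groupby("genus", as_index=False)
        .head(1)
    )
    out = (
        pd.concat([keep_always, pick])
        .drop(columns="_q")
        .sort_values("species_id", ignore_index=True)
    )
    return out
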