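#!/usr/bin/env python
"""Curate the noisy OGT databases from step 01.

Removes records parked at conventional incubation temperatures
(25/28/30/37 degC), averages the surviving sources, applies the genome
quality filter (completeness > 95, contamination < 5) and downsamples
mesophiles to one species per genus.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermolag import curation, io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic"
SCRATCH = ROOT / "scratch"


def main() -> None:
    sources = [io.read_tsv(SCRATCH / f"ogt_source_{i}.tsv") for i in (1, 2, 3)]
    meta = io.read_tsv(OUT / "metadata.tsv")
    taxonomy = io.read_tsv(OUT / "taxonomy.tsv")
    merged = curation.merge_ogt_sources(sources)
    rec = merged.merge(meta, on="species_id").merge(taxonomy, on="species_id")
    qc = curation.quality_filter(rec)
    kept = curation.downsample_mesophiles(qc)
    io.write_tsv(qc, OUT / "curated.tsv")
    io.write_tsv(kept, OUT / "curated_downsampled.tsv")
    n_src = sum(len(s) for s in sources)
    print(f"{n_src} raw records -> {len(merged)} species after exclusion+merge")
    print(f"{len(qc)} pass the quality filter; {len(kept)} after downsampling")


if __name__ == "__main__":
    main()
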